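"""How the preferential exponent decays with emotion frequency.

Fits alpha(p) across the nine published community/valence points with
three candidate families and ranks them by R² in each family's
linearising space.
"""

from emothreads import fit_alpha_vs_p, reference

points = reference.alpha_vs_p_points()
print("community (p_e, alpha_e) points:")
for c in reference.COMMUNITIES:
    for e, sym in [(1, "+"), (-1, "-"), (0, "0")]:
        print(f"  {c.name:<6} {sym}  p={c.p(e):.2f}  alpha={c.alpha(e):.2f}")

print("\nfits of alpha as a function of p:")
for family in ("exponential", "power_law", "linear"):
    fit = fit_alpha_vs_p(points, family)
    print(
        f"  {family:<12} A={fit.A:.3f}  B={fit.B:.3f}  R²={fit.r_squared:.3f}"
    )
print(
    "\nRarer emotions cluster more strongly (larger alpha at small p);"
    "\nthe exponential decay A*exp(-B*p) describes the trend best."
)
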