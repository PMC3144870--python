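"""Thread lifespan and the "emotional fuel" effect.

Generates threads whose stopping hazard falls with the emotional level of
the recent posts, then shows that threads starting with a stronger
absolute valence live longer, and that long threads burn off emotion
between their start and their end.
"""

import numpy as np

from emothreads import (
    GeneratorSpec,
    fuel_delta,
    generate_fuel_threads,
    length_vs_initial_emotion,
)

spec = GeneratorSpec(
    process="fuel",
    p_vec=(0.19, 0.65, 0.16),
    n_threads=40_000,
    seed=6,
    h0=0.04,          # baseline stopping hazard per post
    fuel_strength=1.0,  # hazard rises as recent |valence| falls
)
corpus = generate_fuel_threads(spec)

print("mean thread length by |mean valence of the first 10 posts|:")
for b in length_vs_initial_emotion(corpus, k=10):
    print(
        f"  |v0| in [{b.bin_low:.2f}, {b.bin_high:.2f})  "
        f"mean L = {b.mean_length:6.1f} +/- {b.std_length:5.1f}  "
        f"({b.n_threads} threads)"
    )

deltas = [fuel_delta(t, 10) for t in corpus if len(t) >= 20]
print(f"\nmean fuel delta |first-10 minus last-10 valence| over long threads:")
print(f"  mean |delta| = {np.mean(np.abs(deltas)):.3f}  (n = {len(deltas)})")
print("\nEmotional starts sustain discussions: the more valenced the first")
print("posts, the longer the thread survives the rising hazard.")
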