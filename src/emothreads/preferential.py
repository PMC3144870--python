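"""Preferential growth of emotional clusters: p(n) = p1 * n**alpha.

The central quantity is the conditional extension probability p(n): the
probability that a run of n consecutive same-valence posts is extended by
the next post.  For independent posts p(n) is flat at the class frequency
p_e; in real discussions it grows as a power of n, and the exponent alpha
measures the strength of the same-valence attraction.

Estimation conventions
----------------------
A context for p(n) at valence e is a within-thread position i such that

* posts i-n+1 .. i all have valence e,
* the run starts exactly there: post i-n has a different valence, or the
  run begins the thread, and
* post i+1 exists (positions ending a thread are excluded from numerator
  and denominator alike).

p1 is estimated from consecutive-pair counts — the frequency of
same-valence (e, e) pairs among all within-thread pairs, divided by p_e —
not from the fitted intercept, which is reported only as a diagnostic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import statsmodels.api as sm
from scipy.optimize import curve_fit

from ._runs import run_structure
from .corpus import VALENCES, Corpus, summarize

__all__ = [
    "ConditionalCurve",
    "PreferentialFit",
    "AlphaVsPFit",
    "pair_joint_probability",
    "conditional_extension_curve",
    "fit_alpha",
    "fit_alpha_vs_p",
]

#: A point is treated as saturated (power law capped at 1) above this value.
SATURATION_TOL = 1e-9


@dataclass(frozen=True)
class CurvePoint:
    n: int
    p_hat: float
    numerator: int
    denominator: int


class ConditionalCurve:
    """Estimated extension probabilities p_hat(n) with their counts."""

    def __init__(self, valence: int, points: Sequence[CurvePoint], p1: float):
        self.valence = int(valence)
        self.points = {pt.n: pt for pt in points}
        self.p1 = float(p1)

    def p_hat(self, n: int) -> float:
        return self.points[n].p_hat

    def ns(self) -> list[int]:
        return sorted(self.points)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "valence": self.valence,
                    "n": pt.n,
                    "p_hat": pt.p_hat,
                    "numerator": pt.numerator,
                    "denominator": pt.denominator,
                }
                for pt in (self.points[n] for n in self.ns())
            ]
        )


@dataclass(frozen=True)
class PreferentialFit:
    """Least-squares fit of log p_hat(n) on log n."""

    valence: int
    alpha: float
    alpha_stderr: float
    p1: float
    intercept: float  # exp(fitted intercept); diagnostic only
    fit_range: tuple[int, int]
    r_squared: float
    n_points: int


@dataclass(frozen=True)
class AlphaVsPFit:
    """Fit of the exponent alpha as a function of emotion frequency p.

    Families: exponential  alpha = A * exp(-B p);
              power_law    alpha = A * p**(-B);
              linear       alpha = A - B p.
    """

    model_family: str
    A: float
    B: float
    r_squared: float
    space: str

    def predict(self, p):
        p = np.asarray(p, dtype=float)
        if self.model_family == "exponential":
            return self.A * np.exp(-self.B * p)
        if self.model_family == "power_law":
            return self.A * p ** (-self.B)
        return self.A - self.B * p


def pair_joint_probability(corpus: Corpus, valence: int) -> tuple[float, float]:
    """Same-valence pair frequency and the derived p1 for one valence class.

    ``joint`` is the number of within-thread consecutive pairs whose two
    posts both have the given valence, divided by the number of all
    within-thread consecutive pairs; ``p1 = joint / p_e``.
    """
    if valence not in VALENCES:
        raise ValueError(f"valence must be one of {VALENCES}")
    values, offsets = corpus.flat()
    has_next = np.ones(values.size, dtype=bool)
    has_next[offsets[1:] - 1] = False
    first = values[:-1][has_next[:-1]]
    second = values[1:][has_next[:-1]]
    n_pairs = first.size
    if n_pairs == 0:
        raise ValueError("corpus has no within-thread consecutive pairs (all threads length 1)")
    joint = float(np.count_nonzero((first == valence) & (second == valence))) / n_pairs
    p_e = summarize(corpus).p(valence)
    if p_e == 0:
        raise ValueError(f"no posts of valence {valence:+d}")
    return joint, joint / p_e


def conditional_extension_curve(corpus: Corpus, valence: int, n_max: int = 10) -> ConditionalCurve:
    """Estimate p(n) for n = 1..n_max from maximal-run prefixes.

    Positions whose run has grown to exactly n posts and which have a
    successor in the same thread form the denominator; those whose successor
    repeats the valence form the numerator.  n values with an empty
    denominator are omitted rather than reported as zero.
    """
    if valence not in VALENCES:
        raise ValueError(f"valence must be one of {VALENCES}")
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    rs = run_structure(corpus)
    values, prefix_len, has_next = rs["values"], rs["prefix_len"], rs["has_next"]

    ctx = (values == valence) & has_next & (prefix_len <= n_max)
    succ_same = np.zeros(values.size, dtype=bool)
    succ_same[:-1] = values[1:] == valence
    den = np.bincount(prefix_len[ctx], minlength=n_max + 1)
    num = np.bincount(prefix_len[ctx & succ_same], minlength=n_max + 1)

    _, p1 = pair_joint_probability(corpus, valence)
    points = [
        CurvePoint(n, num[n] / den[n], int(num[n]), int(den[n]))
        for n in range(1, n_max + 1)
        if den[n] > 0
    ]
    return ConditionalCurve(valence, points, p1)


def fit_alpha(
    curve: ConditionalCurve,
    n_range: tuple[int, int] = (1, 10),
    weighted: bool = True,
) -> PreferentialFit:
    """Fit the preferential exponent: OLS of log p_hat(n) on log n.

    Points are weighted by their denominator counts by default, so the fit
    leans on the run lengths with the best statistics.  Saturated points
    (p_hat at 1, where the power law is capped) and zero points are dropped.
    The slope is alpha; p1 comes from the pair counts, while exp(intercept)
    is kept as a diagnostic.
    """
    n_min, n_max = n_range
    pts = [
        curve.points[n]
        for n in curve.ns()
        if n_min <= n <= n_max and curve.points[n].denominator > 0
    ]
    dropped_zero = [pt for pt in pts if pt.p_hat == 0.0]
    if dropped_zero:
        warnings.warn(
            f"dropping {len(dropped_zero)} point(s) with p_hat = 0 from the log-log fit"
        )
    usable = [
        pt for pt in pts if pt.p_hat > 0.0 and pt.p_hat < 1.0 - SATURATION_TOL
    ]
    if len(usable) < 3:
        raise ValueError(
            f"need at least 3 usable points in n range {n_range}, have {len(usable)}"
        )
    x = np.log([pt.n for pt in usable])
    y = np.log([pt.p_hat for pt in usable])
    w = np.array([pt.denominator for pt in usable], dtype=float) if weighted else None
    X = sm.add_constant(x)
    model = sm.WLS(y, X, weights=w) if w is not None else sm.OLS(y, X)
    res = model.fit()
    if res.centered_tss > 0:
        r_squared = float(res.rsquared)
    else:
        # constant p_hat: a flat line fits exactly
        r_squared = 1.0 if res.ssr < 1e-20 else 0.0
    return PreferentialFit(
        valence=curve.valence,
        alpha=float(res.params[1]),
        alpha_stderr=float(res.bse[1]),
        p1=curve.p1,
        intercept=float(np.exp(res.params[0])),
        fit_range=(n_min, n_max),
        r_squared=r_squared,
        n_points=len(usable),
    )


def fit_alpha_vs_p(
    points: Sequence[tuple[float, float]],
    model_family: Literal["exponential", "power_law", "linear"],
    space: Literal["linearized", "untransformed"] = "linearized",
) -> AlphaVsPFit:
    """Fit alpha as a function of emotion frequency p across communities.

    In the default "linearized" space each family is fitted (and its R^2
    computed) in the space that makes it a straight line: log alpha on p for
    the exponential, log alpha on log p for the power law, alpha on p for
    the linear family.  "untransformed" fits all three by nonlinear least
    squares directly on (p, alpha) and scores them there.
    """
    pts = [(float(p), float(a)) for p, a in points]
    if len(pts) < 3:
        raise ValueError("need at least 3 (p, alpha) points")
    p = np.array([x for x, _ in pts])
    a = np.array([y for _, y in pts])
    if np.allclose(p, p[0]):
        raise ValueError("degenerate points: all p equal")
    if model_family not in ("exponential", "power_law", "linear"):
        raise ValueError(f"unknown model family {model_family!r}")

    def _r2(y, pred):
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        return 1.0 - float(np.sum((y - pred) ** 2)) / ss_tot

    if space == "linearized":
        if model_family == "exponential":
            if np.any(a <= 0):
                raise ValueError("exponential family needs alpha > 0 for the log transform")
            slope, inter = np.polyfit(p, np.log(a), 1)
            A, B = float(np.exp(inter)), float(-slope)
            r2 = _r2(np.log(a), inter + slope * p)
        elif model_family == "power_law":
            if np.any(a <= 0) or np.any(p <= 0):
                raise ValueError("power-law family needs p, alpha > 0 for the log transform")
            slope, inter = np.polyfit(np.log(p), np.log(a), 1)
            A, B = float(np.exp(inter)), float(-slope)
            r2 = _r2(np.log(a), inter + slope * np.log(p))
        else:
            slope, inter = np.polyfit(p, a, 1)
            A, B = float(inter), float(-slope)
            r2 = _r2(a, inter + slope * p)
    elif space == "untransformed":
        if model_family == "exponential":
            (A, B), _ = curve_fit(lambda x, A, B: A * np.exp(-B * x), p, a, p0=(a.max(), 1.0))
            pred = A * np.exp(-B * p)
        elif model_family == "power_law":
            (A, B), _ = curve_fit(lambda x, A, B: A * x ** (-B), p, a, p0=(a.min(), 0.5))
            pred = A * p ** (-B)
        else:
            slope, inter = np.polyfit(p, a, 1)
            A, B, pred = float(inter), float(-slope), inter + slope * p
        r2 = _r2(a, pred)
        A, B = float(A), float(B)
    else:
        raise ValueError(f"unknown fit space {space!r}")
    return AlphaVsPFit(model_family=model_family, A=A, B=B, r_squared=float(r2), space=space)
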