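"""Seeded corpus generators for the four reference processes.

Every analysis stage in this package can be exercised without any real
forum data by generating corpora from one of four stochastic processes:

- ``iid``: each post's valence drawn independently from the marginals;
- ``markov``: first-order Markov chain within each thread, started from
  the stationary distribution of the transition matrix;
- ``preferential``: run-extension process p(n) = min(1, p1 * n**alpha) —
  the generative counterpart of the power-law conditional probability;
- ``fuel``: i.i.d. valences with an emergent stopping rule whose hazard
  falls with the emotional level of the recent posts, so emotionally
  charged starts produce stochastically longer threads.

Thread lengths are drawn up front (fixed, or geometric with a configurable
mean) except for the fuel process, where lengths are emergent.  All draws
flow from a single ``numpy`` generator seeded per corpus, so every corpus
is reproducible bit for bit from its spec.

Defaults mirror the published community statistics: the marginals default
to the BBC message-board values (p_plus, p_minus, p_zero) = (0.19, 0.65,
0.16) and the geometric mean thread length to 25 (BBC comments/threads);
use mean 13 for a Digg-like corpus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .corpus import VALENCES, Corpus, Thread

__all__ = [
    "GeneratorSpec",
    "generate",
    "generate_iid",
    "generate_markov",
    "generate_preferential",
    "generate_fuel_threads",
]

#: Class order used for p_vec, p1_vec and alpha_vec: (+1, -1, 0).
PVEC_ORDER = (1, -1, 0)

#: Default marginals: BBC message boards (p_plus, p_minus, p_zero).
BBC_PVEC = (0.19, 0.65, 0.16)

#: Hard cap on emergent thread length in the fuel process.
MAX_FUEL_LENGTH = 100_000


@dataclass
class GeneratorSpec:
    """Parameters of a synthetic corpus.

    ``p_vec``, ``p1_vec`` and ``alpha_vec`` are ordered (positive,
    negative, neutral); ``T`` is row-stochastic with states ordered
    (-1, 0, +1) on both axes.  ``thread_length_law`` is ``("fixed", L)``
    or ``("geometric", mean)``; the geometric law is on {1, 2, ...} with
    success probability 1/mean.
    """

    process: str = "iid"
    p_vec: tuple[float, float, float] = BBC_PVEC
    n_threads: int = 1000
    seed: int = 0
    thread_length_law: tuple[str, float] = ("geometric", 25.0)
    T: Sequence[Sequence[float]] | None = None
    p1_vec: tuple[float, float, float] | None = None
    alpha_vec: tuple[float, float, float] | None = None
    h0: float | None = None
    fuel_strength: float | None = None  # c in the hazard h0 * exp(c * (1 - |m|))
    fuel_window: int = 10
    provenance: str = field(default="", repr=False)

    def __post_init__(self) -> None:
        p = np.asarray(self.p_vec, dtype=float)
        if p.shape != (3,) or np.any(p < 0) or not np.isclose(p.sum(), 1.0, atol=1e-9):
            raise ValueError(f"p_vec must be 3 non-negative probabilities summing to 1, got {self.p_vec}")
        if self.process not in ("iid", "markov", "preferential", "fuel"):
            raise ValueError(f"unknown process {self.process!r}")
        if self.n_threads < 1:
            raise ValueError("n_threads must be >= 1")
        law, par = self.thread_length_law
        if law == "fixed":
            if int(par) < 1:
                raise ValueError("fixed thread length must be >= 1")
        elif law == "geometric":
            if par < 1:
                raise ValueError("geometric mean thread length must be >= 1")
        else:
            raise ValueError(f"unknown thread length law {law!r}")
        if self.process == "markov":
            T = np.asarray(self.T, dtype=float) if self.T is not None else None
            if T is None or T.shape != (3, 3) or not np.allclose(T.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError("markov process needs a 3x3 row-stochastic T")
        if self.process == "preferential":
            for name, vec in (("p1_vec", self.p1_vec), ("alpha_vec", self.alpha_vec)):
                if vec is None or len(vec) != 3:
                    raise ValueError(f"preferential process needs a 3-element {name}")
            if np.any((np.asarray(self.p1_vec) <= 0) | (np.asarray(self.p1_vec) > 1)):
                raise ValueError("p1 values must be in (0, 1]")
            if np.any(np.asarray(self.alpha_vec) < 0):
                raise ValueError("alpha values must be >= 0")
        if self.process == "fuel":
            if self.h0 is None or not 0.0 < self.h0 <= 1.0:
                raise ValueError("fuel process needs h0 in (0, 1]")
            if self.fuel_strength is None:
                raise ValueError("fuel process needs fuel_strength (c)")


def _thread_lengths(spec: GeneratorSpec, rng: np.random.Generator) -> np.ndarray:
    law, par = spec.thread_length_law
    if law == "fixed":
        return np.full(spec.n_threads, int(par), dtype=np.int64)
    return rng.geometric(1.0 / par, size=spec.n_threads).astype(np.int64)


def _to_corpus(spec: GeneratorSpec, columns: np.ndarray, lengths: np.ndarray, label: str) -> Corpus:
    """Assemble a (n_threads, max_len) valence matrix into a Corpus."""
    threads = [
        Thread(f"t{j:07d}", columns[j, : lengths[j]]) for j in range(spec.n_threads)
    ]
    return Corpus(threads, provenance=label or spec.provenance)


def generate(spec: GeneratorSpec) -> Corpus:
    """Dispatch on ``spec.process``."""
    return {
        "iid": generate_iid,
        "markov": generate_markov,
        "preferential": generate_preferential,
        "fuel": generate_fuel_threads,
    }[spec.process](spec)


def generate_iid(spec: GeneratorSpec) -> Corpus:
    """Independent posts: every valence drawn from the marginals."""
    rng = np.random.default_rng(spec.seed)
    lengths = _thread_lengths(spec, rng)
    values = rng.choice(
        np.array(PVEC_ORDER, dtype=np.int8), size=int(lengths.sum()), p=spec.p_vec
    )
    offsets = np.concatenate([[0], np.cumsum(lengths)])
    threads = [
        Thread(f"t{j:07d}", values[offsets[j] : offsets[j + 1]])
        for j in range(spec.n_threads)
    ]
    return Corpus(threads, provenance=f"iid(p_vec={tuple(spec.p_vec)}, seed={spec.seed})")


def _stationary(T: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eig(T.T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def generate_markov(spec: GeneratorSpec) -> Corpus:
    """First-order Markov chains, started from the stationary distribution of T.

    Starting at stationarity makes the pooled marginals equal the
    stationary probabilities, matching how marginals are estimated from
    pooled posts.  Threads are simulated column-wise (one vectorised step
    per post position across all still-active threads).
    """
    rng = np.random.default_rng(spec.seed)
    T = np.asarray(spec.T, dtype=float)
    lengths = _thread_lengths(spec, rng)
    max_len = int(lengths.max())
    states = np.array(VALENCES, dtype=np.int8)  # T axes ordered (-1, 0, +1)
    cum = np.cumsum(T, axis=1)
    pi = _stationary(T)

    columns = np.zeros((spec.n_threads, max_len), dtype=np.int8)
    cur = (rng.random(spec.n_threads)[:, None] > np.cumsum(pi)[None, :]).sum(axis=1)
    columns[:, 0] = states[cur]
    for pos in range(1, max_len):
        active = np.flatnonzero(lengths > pos)
        if active.size == 0:
            break
        u = rng.random(active.size)
        nxt = (u[:, None] > cum[cur[active]]).sum(axis=1)
        cur[active] = nxt
        columns[active, pos] = states[nxt]
    return _to_corpus(spec, columns, lengths, f"markov(seed={spec.seed})")


def generate_preferential(spec: GeneratorSpec) -> Corpus:
    """Run-extension process: repeat the current valence with min(1, p1 * n**alpha).

    The first post of a thread is drawn from the marginals.  Given a current
    run of n posts with valence e, the next post repeats e with probability
    ``min(1, p1_e * n**alpha_e)``; on a break, the new valence is drawn from
    the other two classes proportionally to their marginals.
    """
    rng = np.random.default_rng(spec.seed)
    lengths = _thread_lengths(spec, rng)
    max_len = int(lengths.max())
    classes = np.array(PVEC_ORDER, dtype=np.int8)
    p_vec = np.asarray(spec.p_vec, dtype=float)
    p1 = np.asarray(spec.p1_vec, dtype=float)
    alpha = np.asarray(spec.alpha_vec, dtype=float)

    # break_cum[c] = cumulative probs over the class indices != c
    other_idx = np.array([[j for j in range(3) if j != c] for c in range(3)])
    break_probs = np.array(
        [p_vec[other_idx[c]] / p_vec[other_idx[c]].sum() for c in range(3)]
    )
    break_cum = np.cumsum(break_probs, axis=1)

    columns = np.zeros((spec.n_threads, max_len), dtype=np.int8)
    cur = (rng.random(spec.n_threads)[:, None] > np.cumsum(p_vec)[None, :]).sum(axis=1)
    run = np.ones(spec.n_threads, dtype=np.int64)
    columns[:, 0] = classes[cur]
    for pos in range(1, max_len):
        active = np.flatnonzero(lengths > pos)
        if active.size == 0:
            break
        ca = cur[active]
        p_ext = np.minimum(1.0, p1[ca] * run[active].astype(float) ** alpha[ca])
        extend = rng.random(active.size) < p_ext
        # breaks: pick one of the two other classes proportionally to marginals
        brk = active[~extend]
        if brk.size:
            cb = cur[brk]
            pick = (rng.random(brk.size) > break_cum[cb, 0]).astype(np.int64)
            cur[brk] = other_idx[cb, pick]
            run[brk] = 1
        ext = active[extend]
        run[ext] += 1
        columns[active, pos] = classes[cur[active]]
    return _to_corpus(
        spec, columns, lengths,
        f"preferential(p1={tuple(p1)}, alpha={tuple(alpha)}, seed={spec.seed})",
    )


def generate_fuel_threads(spec: GeneratorSpec) -> Corpus:
    """I.i.d. valences with an emotion-dependent stopping rule.

    After each post the thread ends with hazard
    ``h = min(1, h0 * exp(c * (1 - |m|)))`` where ``m`` is the mean valence
    of the last ``min(i, fuel_window)`` posts.  With c = 0 lengths are
    geometric(h0); with c > 0 emotionally neutral stretches raise the hazard,
    so threads that start strongly valenced live stochastically longer.
    Thread lengths are emergent; ``thread_length_law`` is ignored.
    """
    rng = np.random.default_rng(spec.seed)
    c = float(spec.fuel_strength)
    h0 = float(spec.h0)
    w = int(spec.fuel_window)
    classes = np.array(PVEC_ORDER, dtype=np.int8)
    p_cum = np.cumsum(spec.p_vec)

    n = spec.n_threads
    alive = np.ones(n, dtype=bool)
    lengths = np.zeros(n, dtype=np.int64)
    buf = np.zeros((n, w), dtype=np.int8)  # circular buffer of recent valences
    seqs: list[list[int]] = [[] for _ in range(n)]

    pos = 0
    while alive.any() and pos < MAX_FUEL_LENGTH:
        act = np.flatnonzero(alive)
        v = classes[(rng.random(act.size)[:, None] > p_cum[None, :]).sum(axis=1)]
        buf[act, pos % w] = v
        lengths[act] += 1
        for j, val in zip(act, v):
            seqs[j].append(int(val))
        filled = np.minimum(lengths[act], w)
        sums = buf[act].astype(float).sum(axis=1)  # slots beyond `filled` are still 0
        m = np.abs(sums / filled)
        h = np.minimum(1.0, h0 * np.exp(c * (1.0 - m)))
        alive[act[rng.random(act.size) < h]] = False
        pos += 1

    threads = [Thread(f"t{j:07d}", np.array(s, dtype=np.int8)) for j, s in enumerate(seqs)]
    return Corpus(threads, provenance=f"fuel(h0={h0}, c={c}, seed={spec.seed})")
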