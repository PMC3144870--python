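"""Emotional clusters: maximal same-valence runs and their length distributions.

An emotional cluster is a maximal chain of consecutive posts in a thread
sharing one valence: the posts immediately before and after the chain (when
they exist) carry a different valence.  Runs truncated by a thread boundary
count as clusters; this uses all of every thread at the price of a small
bias toward short clusters in short threads.

Three reference models for the cluster-length distribution are provided as
complementary cumulative distributions P(L >= n):

- i.i.d. posts with class frequency p_e  ->  geometric law p_e**(n-1)
- first-order Markov chain with transition matrix T  ->  T[e,e]**(n-1)
- preferential growth, where a run of length k is extended with probability
  min(1, p1 * k**alpha)  ->  the product of those extension probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._runs import run_structure
from .corpus import VALENCES, Corpus, Thread

__all__ = [
    "Cluster",
    "ClusterLengthDistribution",
    "extract_clusters",
    "cluster_length_distribution",
    "iid_cluster_ccdf",
    "preferential_cluster_ccdf",
    "markov_cluster_ccdf",
    "compare_distributions",
    "DistributionComparison",
]


@dataclass(frozen=True)
class Cluster:
    """A maximal same-valence run inside one thread."""

    valence: int
    length: int
    thread_id: str
    start_index: int  # 0-based position of the first post in the flattened thread


class ClusterLengthDistribution:
    """Empirical length distribution of the clusters of one valence class.

    ``counts[n]`` is the number of clusters of length n; ``pmf`` and ``ccdf``
    are over clusters (not posts), so ``ccdf(1) == 1`` and
    ``ccdf(n) = P(L >= n)``.
    """

    def __init__(self, valence: int, counts: Mapping[int, int]):
        if not counts:
            raise ValueError(f"no clusters of valence {valence:+d}")
        self.valence = int(valence)
        self.counts = {int(n): int(c) for n, c in sorted(counts.items()) if c > 0}
        self.n_clusters = sum(self.counts.values())
        self._max_n = max(self.counts)
        arr = np.zeros(self._max_n + 2, dtype=np.int64)
        for n, c in self.counts.items():
            arr[n] = c
        self._count_arr = arr
        # ccdf_arr[n] = #clusters with length >= n, n = 1.._max_n+1
        self._tail = np.cumsum(arr[::-1])[::-1]

    @property
    def max_length(self) -> int:
        return self._max_n

    def pmf(self, n: int) -> float:
        if n < 1:
            raise ValueError("cluster length must be >= 1")
        if n > self._max_n:
            return 0.0
        return self._count_arr[n] / self.n_clusters

    def ccdf(self, n: int) -> float:
        """P(L >= n) among clusters of this valence."""
        if n < 1:
            raise ValueError("cluster length must be >= 1")
        if n > self._max_n:
            return 0.0
        return self._tail[n] / self.n_clusters

    def total_posts(self) -> int:
        """Number of posts covered by these clusters (sum of n * counts[n])."""
        return sum(n * c for n, c in self.counts.items())

    def to_frame(self, model_ccdf: Callable[[int], float] | None = None) -> pd.DataFrame:
        """Tidy table with columns valence, n, count, pmf, ccdf[, model_ccdf]."""
        ns = np.arange(1, self._max_n + 1)
        df = pd.DataFrame(
            {
                "valence": self.valence,
                "n": ns,
                "count": self._count_arr[1 : self._max_n + 1],
                "pmf": self._count_arr[1 : self._max_n + 1] / self.n_clusters,
                "ccdf": self._tail[1 : self._max_n + 1] / self.n_clusters,
            }
        )
        if model_ccdf is not None:
            df["model_ccdf"] = [model_ccdf(int(n)) for n in ns]
        return df


def extract_clusters(thread: Thread) -> list[Cluster]:
    """Run-length encode one thread into its maximal same-valence clusters.

    Cluster lengths concatenate back to the thread length; runs touching the
    thread's first or last post are included.
    """
    v = thread.valences
    change = np.flatnonzero(v[1:] != v[:-1]) + 1
    starts = np.concatenate([[0], change])
    lengths = np.diff(np.append(starts, v.size))
    return [
        Cluster(int(v[s]), int(L), thread.thread_id, int(s))
        for s, L in zip(starts, lengths)
    ]


def cluster_length_distribution(corpus: Corpus, valence: int) -> ClusterLengthDistribution:
    """Pool clusters of one valence class across all threads of a corpus."""
    if valence not in VALENCES:
        raise ValueError(f"valence must be one of {VALENCES}, got {valence!r}")
    rs = run_structure(corpus)
    lengths = rs["run_lengths"][rs["run_values"] == valence]
    if lengths.size == 0:
        raise ValueError(f"corpus contains no clusters of valence {valence:+d}")
    binc = np.bincount(lengths)
    counts = {int(n): int(c) for n, c in enumerate(binc) if n >= 1 and c > 0}
    return ClusterLengthDistribution(valence, counts)


# ---------------------------------------------------------------------------
# Model ccdfs

def iid_cluster_ccdf(p_e: float, n: int | np.ndarray) -> float | np.ndarray:
    """Geometric run-length law P(L >= n) = p_e**(n-1) for i.i.d. posts.

    Under independent posts a run of one valence continues with probability
    p_e at every step, so cluster lengths are geometric.
    """
    if not 0.0 < p_e < 1.0:
        raise ValueError(f"p_e must be in (0, 1), got {p_e}")
    n = np.asarray(n)
    if np.any(n < 1):
        raise ValueError("cluster length must be >= 1")
    out = p_e ** (n - 1)
    return float(out) if out.ndim == 0 else out


def preferential_cluster_ccdf(p1: float, alpha: float, n: int) -> float:
    """P(L >= n) under preferential growth: prod_{k=1}^{n-1} min(1, p1 * k**alpha).

    With alpha = 0 this reduces exactly to the geometric law with p_e = p1.
    Extension probabilities are capped at 1 (saturation of the power law).
    Negative alpha is admitted so that noisy fitted exponents near zero can
    still be turned into a model curve.
    """
    if not 0.0 < p1 <= 1.0:
        raise ValueError(f"p1 must be in (0, 1], got {p1}")
    if n < 1:
        raise ValueError("cluster length must be >= 1")
    k = np.arange(1, n, dtype=float)
    return float(np.prod(np.minimum(1.0, p1 * k**alpha)))


def markov_cluster_ccdf(T: np.ndarray, valence: int, n: int) -> float:
    """P(L >= n) for a first-order Markov chain: T[e,e]**(n-1).

    ``T`` is the 3x3 row-stochastic transition matrix with states ordered
    (-1, 0, +1) on both axes.
    """
    T = np.asarray(T, dtype=float)
    if T.shape != (3, 3):
        raise ValueError(f"T must be 3x3, got shape {T.shape}")
    if not np.allclose(T.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("rows of T must sum to 1")
    if valence not in VALENCES:
        raise ValueError(f"valence must be one of {VALENCES}")
    if n < 1:
        raise ValueError("cluster length must be >= 1")
    i = VALENCES.index(valence)
    return float(T[i, i] ** (n - 1))


# ---------------------------------------------------------------------------
# Goodness of fit

@dataclass(frozen=True)
class DistributionComparison:
    """Observed vs expected cluster counts under a model ccdf.

    ``chi_square`` sums (O-E)^2/E over lengths with expected count >= 5
    (``dof`` such lengths); ``max_expected_n`` is the largest length at which
    the model still expects at least one cluster — the scale beyond which any
    observed cluster is a long-cluster excess.
    """

    valence: int
    table: pd.DataFrame  # columns: n, observed, expected
    chi_square: float
    dof: int
    max_expected_n: int
    n_clusters: int

    def long_cluster_excess(self) -> float:
        """Observed minus expected number of clusters longer than max_expected_n."""
        tail = self.table[self.table["n"] > self.max_expected_n]
        return float(tail["observed"].sum() - tail["expected"].sum())


def compare_distributions(
    empirical: ClusterLengthDistribution,
    model_ccdf: Callable[[int], float],
    n_max: int | None = None,
) -> DistributionComparison:
    """Compare an empirical cluster-length distribution with a model ccdf.

    Expected counts derive from the model pmf
    ``ccdf(n) - ccdf(n+1)`` times the number of clusters; the last row at
    ``n_max`` pools the model tail so expected counts sum to n_clusters.
    """
    N = empirical.n_clusters
    if n_max is None:
        n_max = empirical.max_length
    ns = np.arange(1, n_max + 1)
    ccdf_vals = np.array([model_ccdf(int(n)) for n in np.arange(1, n_max + 2)])
    pmf = ccdf_vals[:-1] - ccdf_vals[1:]
    pmf[-1] += ccdf_vals[-1]  # pool the tail into the last bin
    expected = N * pmf
    observed = np.array(
        [empirical.counts.get(int(n), 0) for n in ns[:-1]]
        + [sum(c for n, c in empirical.counts.items() if n >= n_max)]
    )
    mask = expected >= 5
    with np.errstate(divide="ignore", invalid="ignore"):
        chi = float(np.sum((observed[mask] - expected[mask]) ** 2 / expected[mask]))
    exp_ge1 = np.flatnonzero(expected >= 1)
    max_exp_n = int(ns[exp_ge1[-1]]) if exp_ge1.size else 0
    table = pd.DataFrame({"n": ns, "observed": observed, "expected": expected})
    return DistributionComparison(
        valence=empirical.valence,
        table=table,
        chi_square=chi,
        dof=int(mask.sum()),
        max_expected_n=max_exp_n,
        n_clusters=N,
    )
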