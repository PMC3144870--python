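"""Thread life-span analysis: valence trajectories and "emotional fuel".

The guiding observation: threads that start with a strong (positive or
negative) average valence tend to live longer, and the emotional level
declines toward a common terminal value as a discussion winds down.  The
tools here quantify that pattern on any corpus:

- moving-average valence trajectories, grouped by exact thread length;
- the "fuel delta": mean valence of the first k posts minus the last k;
- thread length binned by the absolute initial emotional level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .corpus import Corpus, Thread

__all__ = [
    "LifespanProfile",
    "FuelBin",
    "moving_average_valence",
    "grouped_lifespan_profiles",
    "fuel_delta",
    "length_vs_initial_emotion",
    "default_bin_edges",
]


@dataclass(frozen=True)
class LifespanProfile:
    """Mean moving-average valence trajectory over threads of one length.

    ``curve[j]`` is the across-thread mean of the moving average ending at
    post position ``positions[j]`` (1-based, starting at the window size).
    """

    group_length: int
    window: int
    positions: np.ndarray
    curve: np.ndarray
    n_threads: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group_length": self.group_length,
                "position": self.positions,
                "mean_valence": self.curve,
                "n_threads": self.n_threads,
            }
        )


@dataclass(frozen=True)
class FuelBin:
    """Thread-length statistics for one bin of |initial valence|."""

    bin_low: float
    bin_high: float
    mean_length: float
    std_length: float
    n_threads: int


def moving_average_valence(thread: Thread, window: int = 10) -> np.ndarray:
    """Moving average of the previous ``window`` posts' valences.

    Entry j is the mean valence of posts j..j+window-1 (0-based), i.e. the
    average of the window ending at 1-based position window + j.  Threads
    shorter than the window are rejected; exclude them upstream.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if len(thread) < window:
        raise ValueError(
            f"thread {thread.thread_id!r} has {len(thread)} posts, fewer than window={window}"
        )
    c = np.concatenate([[0.0], np.cumsum(thread.valences, dtype=float)])
    return (c[window:] - c[:-window]) / window


def grouped_lifespan_profiles(
    corpus: Corpus,
    target_lengths: Sequence[int] = (20, 40, 60, 80),
    window: int = 10,
) -> list[LifespanProfile]:
    """Average moving-average trajectories for threads of exactly each target length.

    Threads of the same size are grouped together and the moving-average
    curves are averaged pointwise across the group.  Empty groups are
    omitted with a warning.
    """
    by_length: dict[int, list[np.ndarray]] = {L: [] for L in target_lengths}
    for t in corpus:
        if len(t) in by_length:
            by_length[len(t)].append(moving_average_valence(t, window))
    profiles = []
    for L in target_lengths:
        curves = by_length[L]
        if not curves:
            warnings.warn(f"no threads of length {L}; group omitted")
            continue
        stacked = np.vstack(curves)
        profiles.append(
            LifespanProfile(
                group_length=L,
                window=window,
                positions=np.arange(window, L + 1),
                curve=stacked.mean(axis=0),
                n_threads=len(curves),
            )
        )
    return profiles


def fuel_delta(thread: Thread, k: int = 10) -> float:
    """Mean valence of the first k posts minus the mean of the last k.

    A positive-magnitude delta on a long thread means the discussion burnt
    off emotional intensity between its start and its end.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(thread) < 2 * k:
        raise ValueError(
            f"thread {thread.thread_id!r} has {len(thread)} posts; fuel delta needs >= {2 * k}"
        )
    v = thread.valences.astype(float)
    return float(v[:k].mean() - v[-k:].mean())


def default_bin_edges(k: int = 10) -> np.ndarray:
    """k + 1 equal bins partitioning [0, 1].

    With k posts the absolute mean valence is a multiple of 1/k, and k + 1
    equal bins keep each attainable level in its own bin (the last bin is
    closed at 1).
    """
    return np.linspace(0.0, 1.0, k + 2)


def length_vs_initial_emotion(
    corpus: Corpus,
    k: int = 10,
    bin_edges: Sequence[float] | None = None,
) -> list[FuelBin]:
    """Thread length statistics per bin of |mean valence of the first k posts|.

    Threads shorter than k are excluded.  Bins with no threads are omitted.
    Standard deviations are population (ddof=0) over the threads in the bin.
    """
    if bin_edges is None:
        bin_edges = default_bin_edges(k)
    edges = np.asarray(bin_edges, dtype=float)
    if edges.ndim != 1 or edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin_edges must be a strictly increasing 1-d sequence")
    v0, lengths = [], []
    for t in corpus:
        if len(t) >= k:
            v0.append(abs(float(t.valences[:k].mean())))
            lengths.append(len(t))
    if not v0:
        raise ValueError(f"no threads of length >= {k}")
    v0 = np.array(v0)
    lengths = np.array(lengths, dtype=float)
    idx = np.digitize(v0, edges[1:-1], right=False)
    bins = []
    for b in range(edges.size - 1):
        sel = idx == b
        if not sel.any():
            continue
        bins.append(
            FuelBin(
                bin_low=float(edges[b]),
                bin_high=float(edges[b + 1]),
                mean_length=float(lengths[sel].mean()),
                std_length=float(lengths[sel].std()),
                n_threads=int(sel.sum()),
            )
        )
    return bins
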