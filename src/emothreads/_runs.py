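"""Vectorised run-length machinery shared by the cluster and conditional-probability code."""

from __future__ import annotations

import numpy as np

from .corpus import Corpus


def run_structure(corpus: Corpus):
    """Decompose the corpus into maximal same-valence runs.

    Returns a dict with, over the concatenated post array of length N:

    - ``values``: int8 valence per post
    - ``offsets``: thread boundaries (n_threads + 1 entries)
    - ``run_starts``: indices where a new run begins (thread starts always do)
    - ``run_lengths``: length of each run
    - ``run_values``: valence of each run
    - ``run_thread``: thread index of each run
    - ``prefix_len``: per post, the number of consecutive same-valence posts
      ending at it within its thread (so ``prefix_len[i] == n`` means the
      run containing post i started exactly n-1 posts earlier)
    - ``has_next``: per post, whether the next post exists in the same thread
    """
    values, offsets = corpus.flat()
    n = values.size
    new_run = np.ones(n, dtype=bool)
    if n > 1:
        new_run[1:] = values[1:] != values[:-1]
    new_run[offsets[:-1]] = True  # runs never cross thread boundaries

    run_starts = np.flatnonzero(new_run)
    run_lengths = np.diff(np.append(run_starts, n))
    run_values = values[run_starts]
    run_thread = np.searchsorted(offsets, run_starts, side="right") - 1

    idx = np.arange(n, dtype=np.int64)
    start_of_run = np.repeat(run_starts, run_lengths)
    prefix_len = idx - start_of_run + 1

    has_next = np.ones(n, dtype=bool)
    has_next[offsets[1:] - 1] = False

    return {
        "values": values,
        "offsets": offsets,
        "run_starts": run_starts,
        "run_lengths": run_lengths,
        "run_values": run_values,
        "run_thread": run_thread,
        "prefix_len": prefix_len,
        "has_next": has_next,
    }
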