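"""Brute-force reference implementations used as independent oracles.

Everything here is written as a direct transcription of the definitions —
explicit scans with maximality checked at every index — and stays
independent of the vectorised code paths it is used to verify.
"""

from __future__ import annotations


def clusters_bruteforce(seq):
    """All maximal same-valence runs of a sequence as (valence, length, start)."""
    out = []
    L = len(seq)
    for start in range(L):
        v = seq[start]
        if start > 0 and seq[start - 1] == v:
            continue  # not maximal on the left
        end = start
        while end + 1 < L and seq[end + 1] == v:
            end += 1
        out.append((v, end - start + 1, start))
    return out


def conditional_counts_bruteforce(sequences, valence, n_max):
    """Numerator/denominator counts for the extension probability p(n).

    A position i of a sequence is a context for n if posts i-n+1..i all
    have the given valence, the post at i-n (when it exists) does not, and
    post i+1 exists.  Returns {n: (numerator, denominator)}.
    """
    counts = {n: [0, 0] for n in range(1, n_max + 1)}
    for seq in sequences:
        L = len(seq)
        for i in range(L - 1):  # successor must exist
            for n in range(1, n_max + 1):
                j = i - n + 1
                if j < 0:
                    break
                if any(seq[k] != valence for k in range(j, i + 1)):
                    break
                if j - 1 >= 0 and seq[j - 1] == valence:
                    continue  # run started earlier than n posts back
                counts[n][1] += 1
                if seq[i + 1] == valence:
                    counts[n][0] += 1
    return {n: (num, den) for n, (num, den) in counts.items()}


def pair_counts_bruteforce(sequences, valence):
    """(# same-valence consecutive pairs, # all consecutive pairs)."""
    same = total = 0
    for seq in sequences:
        for a, b in zip(seq, seq[1:]):
            total += 1
            if a == valence and b == valence:
                same += 1
    return same, total


def moving_average_bruteforce(seq, window):
    """Windowed means, one per window ending at positions window..len(seq)."""
    return [
        sum(seq[i : i + window]) / window for i in range(len(seq) - window + 1)
    ]


def fuel_delta_bruteforce(seq, k):
    first = sum(seq[:k]) / k
    last = sum(seq[-k:]) / k
    return first - last


def ccdf_bruteforce(lengths, n):
    """P(L >= n) over a list of cluster lengths."""
    return sum(1 for L in lengths if L >= n) / len(lengths)
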