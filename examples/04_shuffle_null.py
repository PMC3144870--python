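"""The within-thread shuffle surrogate as an interaction-free control.

Shuffling each thread's valences preserves every marginal (thread lengths,
per-thread valence counts, pooled frequencies) but destroys the sequential
ordering, so any clustering that survives shuffling is compositional, not
interactional.  On a corpus with genuine sequential attraction (here a
sticky Markov chain), clusters in the surrogate are markedly shorter.
"""

import numpy as np

from emothreads import (
    GeneratorSpec,
    cluster_length_distribution,
    generate_markov,
    shuffle_corpus,
    summarize,
)

# sticky transition matrix, states ordered (-1, 0, +1)
T = np.array(
    [
        [0.85, 0.06, 0.09],
        [0.30, 0.58, 0.12],
        [0.35, 0.08, 0.57],
    ]
)
spec = GeneratorSpec(
    process="markov", T=T, n_threads=3_000, seed=4,
    thread_length_law=("fixed", 200),
)
corpus = generate_markov(spec)
surrogate = shuffle_corpus(corpus, seed=5)
assert summarize(surrogate).to_dict() == summarize(corpus).to_dict()

print(f"pooled negative-post frequency p_- = {summarize(corpus).p_minus:.3f}\n")
print("negative-cluster tail P(L >= n): original vs within-thread shuffle")
d_orig = cluster_length_distribution(corpus, -1)
d_shuf = cluster_length_distribution(surrogate, -1)
print(f"{'n':>3} {'original':>10} {'shuffled':>10}")
for n in (2, 4, 6, 8, 10, 14):
    print(f"{n:>3} {d_orig.ccdf(n):>10.4f} {d_shuf.ccdf(n):>10.4f}")
print(
    f"\nclusters of length >= 10: {sum(c for L, c in d_orig.counts.items() if L >= 10)}"
    f" original vs {sum(c for L, c in d_shuf.counts.items() if L >= 10)} shuffled"
)
print("\nMarginals are identical by construction; the long-cluster excess")
print("lives entirely in the within-thread ordering.")
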