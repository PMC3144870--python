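# emothreads

Statistics of collective emotion in online discussion threads.

Discussions on forums, social-news sites and blogs can be labelled post by
post with a ternary emotional valence e ∈ {−1, 0, +1} (negative, neutral,
positive).  `emothreads` asks whether the emotions expressed in such a
thread are independent of each other or whether participants pull each
other toward the mood of the recent posts — and whether that emotional
level predicts how long a discussion survives.  It is a library for
researchers in computational social science and affective dynamics who
have (or want to simulate) valence-labelled thread sequences.

## The model

Within a thread, an **emotional cluster** is a maximal run of consecutive
posts with the same valence.  If posts were independent with class
frequency p_e, cluster lengths would be geometric:

    P(L ≥ n) = p_e^(n−1)                                   (i.i.d. null)

Real discussions show far more long clusters than this law predicts.  The
package quantifies the effect through the **conditional extension
probability** p(n) — the probability that a run of n same-valence posts is
extended by the next post — which empirically grows as a power law,

    p(n) = p1 · n^α     (capped at 1),

where p1 is the same-valence consecutive-pair probability divided by p_e
and the **preferential exponent α ≥ 0** measures the strength of the
same-valence attraction (α = 0 recovers the i.i.d. process).  The implied
cluster distribution is P(L ≥ n) = Π_{k<n} min(1, p1·k^α).  Competing
nulls are a first-order Markov chain (P(L ≥ n) = T_ee^(n−1)) and a
within-thread shuffle surrogate that preserves all marginals.  A second
strand of analysis tracks the moving-average valence over a thread's life
and the "emotional fuel" effect: threads that start with a stronger
absolute valence tend to live longer, while the emotional level declines
toward a common terminal value.

Everything is testable without proprietary forum data: seeded generators
produce corpora from the i.i.d., Markov, preferential and fuel-stopping
processes, with defaults taken from published summary statistics of three
real communities (BBC message boards, Digg, Blogs06).

## Worked example

Generate a corpus with the published BBC exponents and recover the
positive-valence exponent from the conditional extension curve
(`examples/02_preferential_exponent.py`):

```text
extension probability of positive runs, p_hat(n):
  n= 1  p_hat=0.5024  (contexts: 76519)
  n= 2  p_hat=0.6534  (contexts: 36957)
  n= 3  p_hat=0.7610  (contexts: 23192)
  n= 4  p_hat=0.8461  (contexts: 16940)
  n= 5  p_hat=0.9188  (contexts: 13762)
  n= 6  p_hat=0.9872  (contexts: 12115)
  n= 7  p_hat=1.0000  (contexts: 11488)
  ...
fitted alpha = 0.376 +/- 0.001 (generator used 0.38)
fit intercept = 0.503 (the growth-law prefactor; generator used 0.5)
```

The curve rises as n^0.38 until the capped law saturates at p(n) = 1;
saturated points are excluded from the log-log fit, and the weighted
least-squares slope recovers the generator's exponent.  The other
examples cover cluster distributions against the geometric law
(`01`), the α-versus-frequency fit across the nine published community
points (`03`), the shuffle surrogate (`04`) and the emotional-fuel
lifespan analysis (`05`); each prints a short table and a one-line
interpretation.

A thin CLI wraps the same pipeline for shell use:

```bash
emothreads simulate --config gen.yaml --seed 1 --out corpus.csv
emothreads analyze --input corpus.csv --seed 1 --out report/
```

`analyze` writes tidy CSVs (summary, cluster distributions with model
overlays, conditional curves with α fits, shuffle-null curves, lifespan
tables) plus a `manifest.json` with the seed and config hash; reruns are
byte-identical.

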