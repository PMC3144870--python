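# Methods

## Data model and conventions

A corpus is a set of threads; a thread is an ordered chain of posts, each
carrying a valence in {−1, 0, +1}.  Reply trees are flattened to a single
chronological chain before any sequence statistic is computed — the
sequential analyses are defined on the order in which posts appeared, not
on who replied to whom; parent links are retained as metadata only.  Ties
in the order key are broken by post id, so a given file always yields the
same chain.  Threads of length 1 are kept everywhere except where a
statistic's own window excludes them (they carry cluster-length-1
information).

Class frequencies p_e are pooled over all posts of the corpus.  The
cumulative cluster distribution is standardised as P(L ≥ n), so
ccdf(1) = 1 for every valence.

## Clusters

A cluster is a maximal run of consecutive same-valence posts.  Runs
truncated by a thread boundary are counted as clusters.  The alternative —
requiring an opposite-valence post on both borders — discards most of every
short thread; the cost of keeping them is a small bias toward short
clusters, noticeable when threads are short: on i.i.d. corpora with mean
thread length 25 the empirical P(L ≥ 2) for a frequent class sits visibly
below the geometric law, while with threads of several hundred posts the
agreement is within Monte-Carlo error (the closed-form tests therefore use
100 threads of 10,000 posts, i.e. 10⁶ posts).

Model comparison (`compare_distributions`) converts a model ccdf into
expected counts, pools the model tail into the last bin, sums
(O−E)²/E over lengths with expected count ≥ 5, and reports the largest
length at which the model still expects one cluster — beyond it, observed
clusters constitute the long-cluster excess.

## Conditional extension probabilities and the exponent fit

A context for p(n) at valence e is a position i whose run has grown to
exactly n posts (the run starts n−1 posts earlier, either after an
opposite-valence post or at the thread start) and which has a successor in
the same thread.  Thread-final positions are excluded from numerator and
denominator alike; n values with an empty denominator are omitted rather
than reported as zero.  Thread-initial runs count as contexts: this uses
all data and keeps the curve flat on shuffled i.i.d. corpora.

The exponent is the slope of a least-squares line of log p̂(n) on log n
over n = 1..10 (where counts are largest), each point weighted by its
denominator count; an unweighted variant is available.  Points with
p̂(n) = 0 are dropped with a warning; points with p̂(n) ≥ 1 − 10⁻⁹ are
treated as saturated (the capped law min(1, p1·n^α) has reached 1) and
excluded, since they carry no information about α.  p1 is always reported
from pair counts — same-valence consecutive-pair frequency divided by
p_e — and the fitted intercept is kept only as a diagnostic.  The two
differ by construction in non-i.i.d. corpora: the pair-based p1 pools runs
of every depth (it is the denominator-weighted average of p(n) over n),
whereas the intercept estimates the growth-law prefactor at n = 1.

### α as a function of emotion frequency

Across communities the exponent falls with the frequency p of the emotion.
Three families are fitted: exponential α = A·e^(−Bp), power law
α = A·p^(−B), and linear α = A − Bp.  The default fitting space is each
family's linearising space (log α on p, log α on log p, α on p), with R²
computed in that space; this is the convention under which the published
ranking of the three families (exponential best, then power law, then
linear) holds on the nine community points.  Fitting all three by
nonlinear least squares in untransformed (p, α) space is available via
`space="untransformed"`; on the nine points it reverses the first two
ranks, which is why it is not the default.  R² values computed from the
two-decimal published (p, α) table are lower than the published ones
(0.90/0.86/0.77 versus 0.96/0.94/0.90); the published values are only
reproducible from unrounded data, so the package treats the ranking, not
the printed R², as the robust property.

## Lifespan analysis

Moving averages use a trailing window of 10 posts by default; a thread
must be at least as long as the window.  Profiles group threads of exactly
the target lengths (20, 40, 60, 80 by default — an exact match, with a
tolerance option) and average the moving-average curves pointwise across
the group.  The fuel delta is the mean valence of the first k posts minus
the last k (k = 10), defined for threads of length ≥ 2k.  Thread length
versus initial emotion bins |mean valence of the first k posts| into k+1
equal bins partitioning [0, 1], so each attainable multiple of 1/k falls
in its own bin; threads of length ≥ k are eligible.  Reported spreads are
population standard deviations of thread length within a bin.

## Generators

All generators draw every random number from one `numpy` PCG64 generator
seeded per corpus, so corpora are reproducible bit for bit.  Thread
lengths are fixed or geometric on {1, 2, ...}; the geometric means default
to 25 (BBC-like: 2,474,781 comments / 97,946 threads) and 13 suits a
Digg-like corpus.  No published thread-length distribution exists, so the
geometric law is a stand-in chosen for its memoryless simplicity.

- **iid**: valences drawn independently from (p_plus, p_minus, p_zero).
- **markov**: first-order chain with transition matrix T (states ordered
  −1, 0, +1), started from the stationary distribution of T so pooled
  marginals are well defined.
- **preferential**: the first post is drawn from the marginals; a run of
  n posts with valence e is extended with probability min(1, p1_e·n^α_e),
  and on a break the new valence is drawn from the other two classes
  proportionally to their marginals (the growth law does not constrain the
  break target; this convention keeps the marginals close to p_vec).
  Note the saturated law is absorbing: once min(1, p1·n^α) reaches 1 a run
  can only end with its thread, so per-thread valence compositions drift
  toward consensus in long threads.  This is a property of the capped
  power law itself, not of the implementation.
- **fuel**: valences i.i.d.; after post i the thread dies with hazard
  min(1, h0·exp(c·(1−|m_i|))) where m_i is the mean valence of the last
  min(i, 10) posts.  With c = 0 lengths are geometric(h0); with c > 0
  neutral stretches raise the hazard, so emotionally charged starts yield
  stochastically longer threads — the generative counterpart of the
  emotional-fuel observation.  A hard cap of 10⁵ posts guarantees
  termination.

## What the synthetic corpora do and do not show

The generators emulate the *statistical mechanisms* (independence, Markov
memory, preferential run growth, fuel-dependent stopping) at the
published marginals and exponents.  They do not model authors, reply
networks, topics, diurnal rhythms, or classifier noise; thread-length laws
are an assumption.  Passing tests therefore demonstrate that the
estimators recover the parameters of the stated processes at realistic
scale — not that any particular real community follows those processes.

Two estimator subtleties surfaced by the surrogates are worth knowing.
First, within-thread shuffling preserves per-thread valence composition,
so on corpora with strong between-thread heterogeneity the pooled extension
curve of the surrogate sits above the pooled p_e and even rises with n —
flatness at p_e is the signature of a shuffled *homogeneous* (i.i.d.)
corpus only; the composition-robust shuffle comparison is the cluster-tail
contrast.  Second, the pair-based p1 exceeds the growth-law prefactor
whenever α > 0 (see above).

## Numerical choices

- Run extraction, extension-curve counting and shuffling are vectorised
  over a concatenated post array with thread offsets; the Markov,
  preferential and fuel generators simulate all threads in parallel one
  post-position at a time, so million-post corpora take seconds.
- Exponent recovery tests run at 2×10⁵ threads (the scale at which the
  ±0.05 recovery tolerance is comfortably met); closed-form ccdf checks
  use 10⁶ posts and 3 Monte-Carlo standard errors with binomial error
  estimates.
- Weighted-fit standard errors and R² come from `statsmodels` WLS; for a
  perfectly flat curve (zero centred sum of squares) R² is defined as 1
  when residuals vanish.
- Degenerate inputs fail loudly: empty corpora, non-stochastic transition
  matrices, probabilities outside (0, 1), threads shorter than an
  analysis window, and fits with fewer than three usable points all raise
  `ValueError` with the offending quantity named.

## Known limitations

- Real-corpus headline numbers that require the original proprietary data
  (e.g. terminal BBC valence ≈ −0.42, absolute long-cluster counts) are
  out of reach by construction; the package reproduces mechanisms, not
  datasets.
- The capped growth law's absorbing saturation makes the preferential
  generator unrealistic for very long threads (real p(n) bends down again
  at large n).
- Cluster-tail comparisons treat cluster lengths as independent samples
  when computing Monte-Carlo standard errors; adjacent clusters are
  weakly dependent, so the stated errors are slightly optimistic.
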