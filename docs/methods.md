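# Methods

## The model

A corpus is a multiset of bigram tokens — ordered pairs of categorised
call types — optionally grouped into longer sequences. All inference
happens on the cross-tabulated pair matrix `c[a][b]` with pair total `N`
and call-token total `2N`. Both statistics compare each pair's observed
count with a chance baseline derived from the marginals of that same
matrix; neither models within-sequence dynamics (no Markov structure),
and both assume call categorisation is already done and error-free.

### Distinctive (binomial) statistic

For an ordered pair `(a, b)` the trials are the `n = f1(a)` bigram tokens
led by `a`; each trial "succeeds" if its second slot is `b`, with success
probability estimated by the global second-slot share `p = f2(b)/N`. The
score is the signed −log10 cumulative binomial tail:
`−log10 P(X ≥ k)` when the pair is over-represented, `+log10 P(X ≤ k)`
(negative) when under-represented, zero when `k = np` exactly. The
cumulative tail rather than the point mass is the standard choice in
distinctive collexeme analysis; on fully exclusive corpora (`k = n`) the
two coincide, since the upper tail collapses to the single term `p^n`.

Orientation of the binomial (trials from the first call's first-slot
marginal, success probability from the second call's second-slot share)
is pinned by the exclusive benchmark columns, which it reproduces to all
printed digits; fully exclusive data cannot distinguish it from the
transposed orientation, so the convention is fixed here and documented.

Scores carry no multiplicity correction: the banding thresholds
(|pbin| > 1.3 / 2 / 3 → p < 0.05 / 0.01 / 0.001, strict inequalities)
apply to raw per-pair tails. Because a full matrix scores every ordered
pair, `mdca_frame` additionally emits a `band_holm` column — bands
recomputed after Holm step-down adjustment of the per-pair p-values —
for users who want family-wise control. The unadjusted column is the
primary output; the benchmark values are unadjusted.

Degenerate inputs: a first call with `f1(a) = 0` has no trials and is
unscorable (an error for the single-pair call, silently skipped in the
matrix); `p = 1` forces `k = n`, hence independence with score 0; `p = 0`
with `k > 0` cannot arise from a consistent table and is flagged as an
internal error.

### Mutual-information statistic

The unordered pair count `obs = c[a][b] + c[b][a]` is compared with the
expectation `E = f(a)·f(b)/2N` under independent token frequencies, and
the score is `log2(obs/E)` bits. The denominator is the *call-token*
total `2N`, not the pair total — the choice is pinned by the benchmark
values (4·4/32 = 0.5 expected Huff-Puff pairings; the pair-total
alternative would halve the score). Binary logarithms are used so the
score reads as bits of shared information; the same band labels as the
binomial statistic are attached to |score| as a reading convention only —
for an information measure they are not a calibrated test.

An unobserved pair has no finite log-ratio and is reported as NaN with
direction `not-observed` (never −inf); no pseudo-count smoothing is
applied, so downstream consumers must treat NA explicitly. Self-pairs
use `obs = c[a][a]` and `E = f(a)²/2N`.

The `E = f(a)f(b)/2N` baseline is the large-sample form of the exact
mean pair count under exhaustive random re-pairing of the `2N` call
tokens, which is `f(a)f(b)/(2N−1)`; the discrepancy,
`f(a)f(b)/(2N(2N−1))`, vanishes as the corpus grows. The permutation
tests verify both facts rather than assuming them.

### Order asymmetry

A pair is classified `ordered` when exactly one direction is a
significant attraction (attraction direction and band better than NS),
`bidirectional` when both are, `none` otherwise. Significance is
deliberately restricted to *attractions*: a significantly repulsive
order says the calls avoid that order, which is not evidence for an
ordered combination. A direction whose first call never leads any
bigram has no trials and counts as not significant.

## Synthetic corpora

The generator emulates planted-bigram benchmark designs: a 10-type
repertoire (Huff, Puff, Peep, Howl, Whistle, Twitter, Bark, Cough,
Grunt, Trill — names chosen to span tonal-to-noisy primate-like call
types), three planted bigrams Huff-Puff ×4 (rare, strictly ordered) and
Peep-Howl ×5 / Howl-Peep ×7 (frequent, order-flexible), crossed with
corpus size (×1 / ×10) and recombination (none, or background pairs
filling the totals to 49 / 490). Planting is exact — counts are placed
verbatim, never sampled — because the designs fix counts, not rates.

The exclusive sets (SE, LE) are fully determined by the design and are
reconstructed without randomness. The recombinatorial sets (SR, LR) fix
only the planted counts and the totals; the reference background
composition lives in a supplementary distribution file that is not
machine-readable here, so the background is drawn uniformly at random
over ordered pairs of distinct calls outside the planted bigrams, with
the seed recorded in the corpus provenance. A user-supplied
`background_table` pair list reproduces a reference background exactly
(validated against the expected totals). Uniform background is a
deliberate neutral choice: it recombines every call type, including the
planted ones, which is the property the R data sets exercise. The
optional `background_labels` field restricts the background support
(e.g. to the non-planted labels) for designs where planted bigrams must
stay exclusive, as in the parameter-recovery checks. Self-pairs are
excluded from backgrounds since the benchmark bigrams are pairs of
distinct calls.

`shuffle_null` permutes all `2N` call tokens and re-pairs them
sequentially: token frequencies are preserved exactly, pair structure is
destroyed. It underpins the false-positive-rate and baseline checks.

### What passing tests do and do not show

Synthetic corpora have exact planted counts, i.i.d. uniform backgrounds
and perfect call labels. Real corpora have observation effort varying by
context, non-uniform call-type frequencies, temporal autocorrelation
within bouts, and classification error — none of which the generator
emulates. Passing tests therefore demonstrate correctness of the
statistics and their documented contrasts (size scaling, scale
invariance, low-frequency salience, recombination sensitivity,
linearisation detection), not robustness of scientific conclusions drawn
from field data.

## Numerical choices

- Binomial tails come from `scipy.stats.binom.sf/cdf`; property tests
  hold them to < 1e−12 relative error against explicit term-by-term pmf
  summation for `n ≤ 25` (observed worst error ≈ 2e−15).
- Ties `k = np` are classified independent with score exactly 0; the
  comparison is on the float product `n·p`, exact for the rational
  marginal ratios that arise from integer tables.
- Band thresholds use strict inequalities, so a score of exactly 1.3
  is NS.
- Holm adjustment can drive an adjusted p to 0 for extreme scores; the
  −log10 magnitude is capped (at 350, near the float underflow limit)
  before banding, which cannot change any band.
- Output ordering is deterministic everywhere: score descending, then
  lexicographic; report reruns are byte-identical.
- Labels are case-sensitive and trimmed of surrounding whitespace.

## Problem sizes

Default verification sizes: 2000 token reshuffles for the permutation
baseline, 200 reshuffles for the false-positive-rate check, 100 seeds
for parameter recovery (count-5 exclusive bigram over 200 background
pairs), 50 seeds × 1000 pairs for background-sampling bounds. These
sizes give Monte-Carlo standard errors comfortably inside the asserted
tolerances (e.g. ≈ 0.015 pairs on the reshuffle mean, checked at 4
standard errors plus the known finite-size bias of the baseline).

## Known limitations

- Bigrams only; no trigram or skip-gram extension, and no sequence-level
  (Markovian) modelling.
- The binomial orientation and tail convention are pinned by exclusive
  benchmarks; corpora that could distinguish alternatives (heavy
  recombination with a reference background) would be the definitive
  check once a reference background table is supplied.
- MICA bands are labels, not tests; treat them as presentation.
- The temporal criterion that makes two calls "a combination" is out of
  scope: the package consumes pre-segmented pair lists or sequences and
  leaves segmentation to the user.
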