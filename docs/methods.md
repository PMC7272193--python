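# Methods

This note documents the models implemented in `lettercode`, the
assumptions behind them, the synthetic-data generator that stands in for
behavioral and imaging data, and the numerical and design choices made
where the procedure was genuinely open.

## From search times to perceptual distance

Oddball search time for a stimulus pair indexes the pair's similarity:
finding a `T` among `A`s is fast, finding an `I` among `T`s is slow. The
pipeline's dissimilarity is the reciprocal of the mean correct RT,
`d = 1/RT`, pooled over subjects, trials and target/distractor
assignments. The reciprocal is used because it behaves like a distance
and tracks the rate of evidence accumulation; it combines approximately
linearly across factors. The reciprocal-of-mean convention (not
mean-of-reciprocals) is the default; the alternative is exposed via
`statistic="mean_of_reciprocals"` for sensitivity analysis.

**Outliers.** Within each search pair (or each string, for lexical
trials), trials farther than `k = 3` scaled median absolute deviations
from the group median are removed; the scale constant is 1.4826 (normal
consistency, the convention of the common `isoutlier`-style routines).
Incorrect trials are dropped before everything. A single pass of this
rule is *not* idempotent in general — removing points shrinks the MAD
and can expose further points (we observed second passes removing ~1%
more on lognormal RT groups). The default is the faithful single pass;
`iterate=True` repeats to a fixed point, which is idempotent by
construction. Groups of size 1 are kept unchanged (MAD undefined).

**Reliability.** Any model's fit is bounded by the data's own
consistency. Subjects are split into random halves `n_splits` times
(default 100); the per-pair statistic (mean RT by default) is Pearson-
correlated between halves, giving `r_sh ± sd`; the deterministic
odd/even split is reported separately because conventions differ across
experiments. The Spearman–Brown correction
`r_data = 2·r_sh/(r_sh + 1)` estimates the reliability of the full data
set and is the ceiling for a model trained on all of it.

## The letter space

Classical (Torgerson) MDS embeds the single-letter dissimilarity matrix:
double-centre the squared distances, eigendecompose, take the top
`n_dims` eigenvectors scaled by the root eigenvalues. Classical scaling
is used rather than SMACOF because it is deterministic and exact for
Euclidean inputs — properties the test suite and the recovery
benchmarks rely on; an optional SMACOF refinement initialised from the
classical solution is available for strongly non-Euclidean data.
Negative eigenvalues (possible for 1/RT data) are clipped to zero and
their mass is reported as a diagnostic.

The default is 10 dimensions. On simulated letter data this choice puts
the distance-level fit near `r ≈ 0.99` with a cumulative eigenvalue
share near 0.95; both conventions of "variance explained" are computed
and reported because they differ numerically
(`variance_explained_curve` returns both).

Axes are defined only up to rotation/reflection; a rotated code is an
equally valid set of neurons. All tests and comparisons therefore
operate on distances, never on raw coordinates; axis signs are fixed by
a largest-element convention purely for reproducibility of serialized
output.

## The compositional string model

Neuron *k* responds to string *s* with
`resp_k(s) = Σ_p w[k,p] · r_k(s[p])`: a weighted sum of its single-letter
responses, with one spatial weight per position. Dissimilarity between
equal-length strings is the Euclidean norm of the response-vector
difference (default) or the mean absolute per-neuron difference; both
appear in the literature and both are implemented (`metric=`). For one
neuron the two coincide.

Two exact symmetries matter. (1) Scaling all weights by `c > 0` scales
every dissimilarity by `c`; the data's absolute scale pins the fit. (2)
Flipping the sign of one neuron's entire weight row leaves every
dissimilarity unchanged; recovery is therefore assessed up to per-row
sign. The letter code's scale is *not* normalized before fitting — the
weights absorb it.

**Fitting.** Weights minimise the squared error between observed and
predicted dissimilarities (on `d` directly, not `1/d` or `log d`), via
`scipy.optimize.least_squares` from random standard-normal
initialisations, best of `n_restarts` (default 10) to guard against
local minima. Weights are unconstrained reals. For bigrams with 10
neurons this is 20 free parameters against 1176 pairs; the
identifiability check (pairs ≥ parameters) is enforced.

**Shuffle control.** Shuffling the observed dissimilarities destroys
the fit (`r` collapses to ≈ 0) and changes the fitted weights
significantly — the fitted structure is a property of the data, not the
fitter. One caution discovered in simulation: on structureless targets
the least-squares optimum tends toward *winner-take-all* weights
(asymmetry ≈ |w₁+w₂|), because identical-letter pairs (`AA` vs `BB`)
require `|w₁+w₂|` large while transposed pairs now carry
typical-magnitude targets requiring `|w₁−w₂|` large. So a shuffle
control should not be expected to produce *more symmetric* weights than
structured data whose generating weights are near-symmetric.

**Jumble ranking.** `rank_jumbles` orders permutations (or supplied
candidates) of a word by model distance, ascending — a difficulty
ranking for jumbled reading. Ties break lexicographically for
determinism; the identity permutation is always rank 1 at `d = 0`.

## The part-sum model

A linear alternative: `d(s, t) ≈ Σ_{i,j} c_ij · d_letters(s[i], t[j])`
over all location pairs, plus an optional intercept (included by
default; the convention is unstated in the literature this follows, so
it is toggleable). Because the model is linear in `c`, OLS estimates it
uniquely when the design has full column rank; rank deficiency raises
an error carrying a null-space basis. With fewer pairs than
coefficients the fit falls back to the reduced model with a warning.

The reduced variant ties coefficients into classes by location
separation `|i−j|`, giving `L` classes for length-`L` strings (2 for
bigrams). The tying rule is a parameter: the exact reduction used in
prior work for six-letter strings (five free parameters) is not
recoverable from available sources, and a plain `|i−j|` tying gives six
classes there — the class rule can be swapped without code changes.
Because the tied design sums full-design columns, the reduced model is
nested: its in-sample fit can never exceed the full model's (tested).

The part-sum and letter models coincide exactly in the single-neuron,
mean-absolute case only when one position carries all the weight
(`d = w₁·|r_{s0} − r_{t0}|`); for generic two-position weights
`|w₁a + w₂b|` is not separable into `|a|` and `|b|` terms and the
linear fit is close (r ≈ 0.8–0.95 in simulation) but not exact.

## Lexical decision

Lexical decision is treated as comparison against stored words:

- **words**: `RT = a − b·log(frequency)` plus lexical covariates
  (mean log bigram frequency, mean log letter frequency, Coltheart's N —
  same-length neighbours differing in exactly one position). Zero or
  missing frequencies are floored at half the smallest positive
  observed frequency before logs; single-letter strings have no bigram
  feature and are reported missing, never silently zero. Word models
  regress RT; nonword models regress 1/RT (both switchable per
  `RTModelSpec`).
- **nonwords**: `1/RT = α·d_nearest + β`, where `d_nearest` is the
  letter-model distance to the nearest *same-length* word (the string
  model requires equal lengths; OLD covers cross-length checks). Ties
  break to the lexicographically smallest word.
- **OLD baseline**: dynamic-programming edit distance with insertions
  and deletions at cost 1 and substitutions at cost 2. At that cost
  ratio `OLD(s,t) = |s| + |t| − 2·LCS(s,t)`, which the tests verify
  against a brute-force LCS oracle; the distance satisfies the metric
  axioms. A Damerau variant (adjacent transposition as one operation)
  exists behind a flag but is off by default.

**Model comparison.** Models with different parameter counts are
compared out of sample: each split trains every model on the per-string
mean RTs of a random half of subjects and correlates its predictions
with the other half's means; repeated `n_boot` times (default 1000).
The exceedance probability `p(A < B)` is the fraction of splits where A
lost, with exact ties counted half so that identical models calibrate
to `p = 0.5`. Strings with accuracy below 20% are excluded up front
(threshold configurable).

**Category summary.** For each transposition/substitution category,
the percent RT change `100·(RT_nonword − RT_word)/RT_word` against the
source word, with rank-sum tests between categories. Only orderings are
meaningful; the sign and magnitude depend on the generator's word and
nonword RT scales.

## RSA statistics

**Crossnobis.** For runs `m`, conditions `a, b`:
`d_m = (x_a,m − x_b,m)ᵀ W (x̄_a,−m − x̄_b,−m)`, averaged over folds.
The two factors carry independent noise, so `E[d] = 0` under identical
condition means — estimates can be legitimately negative, unlike plain
Euclidean/Mahalanobis distances, which are noise-inflated (both facts
are tested by simulation). With zero noise `d` equals the squared
`W`-norm of the mean difference exactly. `W` defaults to the identity
(cross-validated squared Euclidean distance) because a proper noise
covariance comes from GLM residuals that are out of scope here; a
positive-definite `W` can be supplied for full Mahalanobis whitening.

**Aggregation.** Across subjects, each pair's dissimilarities pass the
same scaled-MAD outlier rule (applied across subjects, per pair) and
the median of the survivors is taken.

**Correlations.** RSA correlation is Pearson `r` over the shared pair
set, with pairs resampled with replacement `n_boot` times for an error
bar; the bootstrap p is one-sided (`fraction of resamples with r ≤ 0`),
matching directional hypotheses. Partial correlation uses the standard
formula `(r_xy − r_xz·r_yz)/√((1−r_xz²)(1−r_yz²))` and is verified
against the residual-regression route to 1e-10; conditioning variables
correlated with a target at |r| ≥ 1 − 1e-12 are rejected as degenerate.

## The synthetic-study generator

`lettercode.synth` emulates the statistical structure the analyses
assume:

- **search trials**: `RT = rt_scale/d × exp(σ·z)` — the reciprocal link
  `1/RT ∝ d` taken as exact, with multiplicative lognormal trial noise
  (RTs are positive and right-skewed; the literature does not specify a
  trial-noise family, so it is a parameter, and σ = 0 gives exact
  recovery of the generating dissimilarities up to one global scale — a
  tested invariant). An optional additive baseline `1/RT = d/s + t₀` is
  available (default `t₀ = 0`). Each pair appears `n_reps` times per
  subject with either member as target equally often; accuracy is fixed
  at ceiling.
- **letter codes**: uniform [0, 1] responses, mean-centred per neuron
  (any distribution with per-neuron variance would do).
- **summation weights**: uniform [0.5, 1.5] per position, optionally
  multiplied by a convex (exponential) U-shaped position profile
  (`edge_bias`). The convexity matters: it concentrates
  adjacent-position weight *differences* at the edges, which is what
  makes edge manipulations of a string change the model response more
  than middle manipulations (the first/last-letter advantage). A linear
  profile would leave adjacent differences equal across positions and
  fail to emulate that structure.
- **lexica**: unique random strings with Zipf frequencies
  (`freq ∝ rank^−s`, default exponent 1 — the canonical value for word
  frequency distributions).
- **nonwords**: the standard 8-category plan (edge/middle/two-step/
  random transpositions; edge/middle/random substitutions), one nonword
  per distinct source word, each differing from its source exactly as
  the category prescribes and guaranteed not to be a word. Two-step
  categories require length ≥ 5 and raise on 4-letter requests. Random
  categories sample uniformly from the admissible strings, excluding
  real words.
- **lexical trials**: `RT_word = a − b·log f + ε`,
  `RT_nonword = c/(α·d_nearest + β) + ε`, truncated positive.
- **patterns/embeddings**: condition means plus i.i.d. Gaussian voxel
  noise; embeddings as orthonormal cluster centres plus noise (zero
  noise ⇒ within-cluster cosine dissimilarity 0, across-cluster 1).

Every generator is a pure function of its inputs and seed.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: subject-level effects (all subjects share
one ground truth; only trial noise differs), accuracy below ceiling,
RT sequential effects or fatigue, letter-frequency and case/font
structure of real letter confusability, morphology or phonology in the
lexicon, and spatially correlated fMRI noise (voxel noise is i.i.d., so
identity whitening is exactly right in simulation, which real data
would not be). Recovery results demonstrate correctness of the
estimators under the model's own assumptions, not robustness to their
violation.

## Problem sizes and defaults

The shipped demo configuration (`RunConfig`) runs a small complete
study — 9 letters, 49 bigrams from 7 of them, 40 words per length at
lengths 4–5, 6 search and 8 lexical subjects, 8 pattern runs, a few
hundred bootstrap iterations — completing all seven stages in a few
seconds on one CPU. The recovery and calibration benchmarks use the
published design sizes where those are the point (62 characters / 3782
trials, 49 bigrams / 1176 pairs / 2352 trials, the 450-nonword table,
74 conditions × 8 runs) and 1000 iterations for the null and
calibration simulations. Tolerances: exact assertions for
combinatorics and closed-form identities; 1e-6–1e-8 for noiseless
linear-algebra recoveries; 1e-3 for nonlinear weight recovery (limited
by optimizer convergence, not identifiability); ±3 sem for the
crossnobis null; [0.4, 0.6] for exceedance calibration at 1000 splits.

## Known limitations

- Equal-length strings only in the compositional model; cross-length
  comparisons go through OLD.
- The part-sum reduction achieving exactly five parameters for
  six-letter strings is not reproduced (see above); the tying rule is
  pluggable.
- The crossnobis default is identity whitening; supplying a realistic
  noise covariance is the caller's responsibility.
- The pipeline's per-length lexical weights default to equal weights
  rather than re-fitting per length against reciprocal RTs; the re-fit
  path exists in the library (`fit_weights` on a 1/RT target) but is a
  heavier computation than the demo warrants.
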