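# Methods

## The model

`dcseq` identifies *differentially correlated* (DC) feature pairs — pairs
whose association differs between two biological groups — in sequencing
count data.  For every feature pair the correlation is computed separately
in each group and Fisher-transformed, `z = atanh(r)`, giving an
approximately normal score whose null standard deviation is
`1 / sqrt(n - 3)`.

Within each group the z-scores are modelled as a k-component normal
mixture.  With `k = 3` the components represent negative (−), absent (0)
and positive (+) association; with `k = 5` two further components (−−, ++)
capture *elevated* association — the same sign but stronger in one group.
A pair's joint class is the component pair `(a, b)` it occupies in the two
groups, giving `k²` classes (9 or 25) with a `k × k` probability table π.
The class posterior of pair `i` is

    P(a, b | z) ∝ π[a,b] · φ(z1; μ1[a], σ1[a]) · φ(z2; μ2[b], σ2[b])

and the DC posterior probability is the pair's posterior mass summed over
the off-diagonal classes (those where `a ≠ b`).  Means and SDs are
per-group; the null component's mean is pinned at 0 in both groups.  With
this parameterisation the free-parameter count is `k² − 1 + 2(k − 1) + 2k`
(18 for k = 3, 42 for k = 5); it is reported alongside BIC in the params
JSON.  BIC is a convenience statistic only — the package never selects k
automatically.

### EM fitting

Parameters are fit by EM over all pairs.  The E-step runs in log-space
(log-sum-exp), so extreme z-scores cannot produce NaN.  The M-step sets
π to the mean class posterior, and the component means/SDs to
responsibility-weighted moments, with three safeguards:

* **SD floor** `1e-2` (variance `1e-4`) on every component, preventing
  singular components on near-duplicate z-values;
* **empty components** (total responsibility < 1e-8) keep their previous
  parameters, with a warning;
* **order restoration**: if an update breaks the ascending order of means
  within a group, components are re-sorted and π's rows/columns permuted.
  This prevents label switching, to which the 5-component model is prone
  because − vs −− (and + vs ++) are weakly separated.

Convergence is declared when the relative log-likelihood change falls
below `1e-6` (default; `max_iter` 500).  The log-likelihood trace is
retained so monotonicity can be audited.

### Initialization and restarts

The mixture likelihood is multimodal.  Because truly correlated pairs are
usually a small minority, initializing μ(+) at the mean of all positive
z-scores places it inside the null bulk, and EM then tends to collapse
every component onto the null — a demonstrably inferior optimum on
mostly-null data.  The deterministic initialization therefore seeds the
outer components from the extreme tails: μ(+) starts at the mean of
z-scores above the 95th percentile (μ(−) symmetrically below the 5th);
for k = 5 each tail is split at its median.  All SDs start at the pooled
SD and π starts diagonal-heavy (80% concordant mass).  By default two
additional seeded random-jitter initializations are tried and the best
final log-likelihood kept (`restarts=2`); the selection criterion is the
log-likelihood only.  Given identical inputs and seed, results are
bit-identical.

### Subsampling EM

The likelihood above falsely treats pairs as independent: a feature occurs
in many pairs.  The subsampling variant draws, per round, a random pair
set in which no feature is reused (a random matching; `floor(p/2)` pairs
within one dataset, `min(p_x, p_y)` pairs between two), fits EM on that
subset, repeats for 100 rounds (default), averages μ, σ and π elementwise
over the converged rounds (renormalising π), and finally runs a single
E-step over *all* pairs with the averaged parameters.  Non-converging
rounds are dropped; more than half dropping is an error.

**Known limitation.**  The independent-set size is bounded by the data's
dimensions.  In a between-omics analysis with 30 features on the small
side, each round sees at most 30 pairs — far below the ~10·k² pairs the
fit realistically needs — and per-round maximum-likelihood estimates then
overfit the null tails (small means, small SDs, inflated off-diagonal π).
Averaging over rounds does not remove this bias, so at such scales the
subsampled posteriors rank pairs differently from the standard fit (rank
correlation ~0.5–0.7 in our default-scale study), though they still
detect DC far better than chance.  With ≥ 100 independent pairs per round
the two variants agree closely (rank correlation > 0.95 in the
property-test conditions).  Subsampling is therefore recommended only
when both feature sets are reasonably large.

## Correlation metrics

* **Pearson** and **biweight midcorrelation (bicor/BWMC)** expect
  variance-stabilised input (e.g. the provided log-CPM transform).  bicor
  weights samples by `(1 − u²)²` for `|u| < 1`, `u = (x − med)/(9·MAD)`;
  a zero-MAD feature falls back to Pearson for its pairs, with a warning.
  On strongly discretised data (low counts) the MAD can be degenerate or
  tiny, which visibly degrades bicor — a property of the metric itself.
* **Spearman** is Pearson on average ranks (ties handled by mid-ranks).
* **SparCC** estimates correlations for compositional counts: fractions
  with pseudocount 0.5, log-ratio variances `t_ij = var(log(f_i/f_j))`,
  basis variances solved from `Σ_j t_ij = |N(i)|·ω_i² + Σ_{j∈N(i)} ω_j²`
  under the sparsity assumption, then `ρ_ij = (ω_i² + ω_j² − t_ij) /
  (2 ω_i ω_j)`.  The strongest pair with `|ρ|` above 0.1 is excluded from
  the system and the solve repeated, up to 10 rounds (both configurable).
  The default is a single deterministic pass; `resamples > 0` averages ρ
  over per-sample Dirichlet draws.  For a between-omics analysis the two
  matrices are concatenated feature-wise before SparCC (log-ratio
  variances need a common composition) and the cross block extracted.
  Negative solved basis variances are clamped to a small positive floor
  with a warning.

Correlations of |r| ≥ 1 − 1e-7 are clamped before the Fisher transform
(keeping |z| ≲ 8.4) and flagged.  Pairs involving a zero-variance feature
are recorded as missing, excluded from the fit, and reported as NaN
posteriors — imputing them would fabricate evidence.

## MAD outlier screen

Sequencing data stay right-skewed after normalisation, and a single
extreme library can dominate a feature's correlations.  For each feature,
values strictly below the feature median form the lower set and strictly
above the upper set (ties with the median contribute zero).  Each side's
spread is its own unscaled MAD (no 1.4826 consistency factor — the
thresholds are calibrated as raw multiples), measured around the side's
median, while the outlier distance `|x − m|` is measured from the feature
median.  The feature's score is the maximum distance-to-MAD ratio over
both sides; features scoring above the threshold are dropped.  Defaults:
7 for variance-stabilised data, 20 for raw counts (heavier tails).  A
side with fewer than 2 values contributes 0 (its MAD is degenerate); a
constant side (MAD 0) yields an infinite score, since any strict-side
value differs from the median and a point infinitely many MADs out is the
canonical outlier.

## Fisher z-test baseline

The frequentist comparator tests each pair with

    T = (atanh(r1) − atanh(r2)) / sqrt(1/(n1−3) + 1/(n2−3))

against a standard normal (two-sided).  q-values are Benjamini–Hochberg
by default; a Storey variant (π₀ estimated at λ = 0.5) is available
behind a flag.

## Synthetic studies

The generator emulates a paired-omics sequencing experiment: `n_x`
miRNA-like and `n_y` mRNA-like features with negative-binomial marginals
(variance `μ + μ²·d`), in two groups.  Dependence comes from a Gaussian
copula: each y-feature draws one joint class; a non-null class is planted
against exactly one designated x partner with the class's latent
correlation in each group, and the correlated y inherits its partner's NB
mean while keeping its own dispersion (mimicking a transcript tracking
its regulator's abundance).  All other pairs are independent by
construction, so the per-pair truth table is exactly realisable.  The NB
quantile transform preserves the marginals exactly; the latent
correlation ρ maps to a Spearman correlation of `6/π·asin(ρ/2)`.

Default conditions (fixed once, used by the test suite and the acceptance
analysis): 30 × 300 features, 20 samples per group (9000 pairs — EM-stable
yet fast on one CPU), latent targets 0/±0.7 (±0.95 elevated), NB means
uniform on (10, 1000), dispersions uniform on (0.05, 0.5) — typical bulk
RNA-seq magnitudes — and a mostly-null class distribution (70% of
y-features unplanted; classic DC, concordant and, for k = 5, elevated
classes share the rest).

**What the emulation does not capture.**  Real sequencing data add
library-size variation, many very-low-count features with zero inflation,
batch effects and feature-feature dependence beyond designated partners.
Two consequences observed in our own runs: (i) log-CPM of these NB counts
is nearly Gaussian, so Pearson-on-log-CPM performs on par with Spearman
here — differences between the two metrics across generator seeds are
within Monte-Carlo noise, and rank-based metrics' documented advantage on
real, messier data should not be inferred from these simulations alone;
(ii) the planted DC fraction (~1% of pairs) makes the subsampling variant
operate far below its recommended round size, as discussed above.
Passing tests demonstrate internal correctness and the stated qualitative
orderings under these conditions, not field performance.

## Numerical and design choices

* Pair enumeration is deterministic row-major; within-omics results fill
  the strict lower triangle of output matrices (upper triangle and
  diagonal are NA), between-omics results fill the full x-by-y rectangle.
* The subsampling matching is drawn fresh per round, uniformly at random,
  without cross-round bookkeeping.
* `transform=True` (Fisher) is the default; with `transform=False` raw
  correlation values are modelled directly — only advisable if the inputs
  are already variance-stabilised scores.
* ROC curves group tied scores into a single vertex (Mann–Whitney
  convention), so the trapezoidal AUC equals the probability that a
  random positive outranks a random negative; the rank curve reports
  sensitivity and 1 − specificity after calling the top-r pairs DC.
* Elevated-class evaluation: under the 3-component convention, −−/++ are
  collapsed to −/+ before the diagonal test, so elevated DC pairs count
  as negatives; under the 5-component convention they are positives.
* Matrix file dialect: delimiter inferred from the extension (`.tsv`
  tab, `.csv` comma), overridable; missing cells in output matrices are
  empty fields.

## Problem sizes used in the checks

The acceptance analysis (`scripts/acceptance.py`) uses the default 30 ×
300 / 20 + 20 study (9000 pairs) for the metric comparison and the
subsampling agreement, 5000 pairs for EM parameter recovery, and 2000
complete-null pairs at n = 25 per group for the baseline's type-I error —
sizes chosen to keep a full run around a minute on one CPU while leaving
Monte-Carlo error well inside the tolerances quoted in the tests.
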