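# dcseq — differential correlation for sequencing count data

`dcseq` finds *differentially correlated* (DC) molecular feature pairs —
pairs whose association differs between two biological groups (sign flips,
gains/losses, or changes in strength) — in sequencing count data such as
RNA-Seq and miRNA-Seq, within one dataset (gene–gene) or between two
(miRNA–gene).

Standard DC tests assume continuous, Gaussian-like measurements.  Counts
are neither, so `dcseq` combines correlation metrics suited to counts
(Spearman, SparCC) and to variance-stabilised data (Pearson, biweight
midcorrelation) with a mixture-model scoring of the per-pair evidence:

1. For each feature pair, compute the correlation `r1` in group 1 and `r2`
   in group 2, and Fisher-transform them, `z = atanh(r)`.
2. Model each group's z-scores with a k-component normal mixture
   (k = 3: −/0/+; k = 5 adds −−/++ for *elevated* association), so each
   pair occupies one of k² joint classes with class table π.  Fit
   μ, σ, π by EM — either over all pairs, or with a subsampling variant
   that repeatedly fits independent (non-feature-sharing) pair sets and
   averages the parameters.
3. Report each pair's **DC posterior probability**: its posterior mass on
   the off-diagonal classes, `P(a ≠ b | z1, z2)`.

The package also provides the MAD-based outlier screen for sequencing
features, the classical Fisher z-test baseline
`(atanh r1 − atanh r2)/sqrt(1/(n1−3) + 1/(n2−3))` with FDR q-values, a
negative-binomial Gaussian-copula simulator with planted DC classes, and
ROC/rank-curve evaluation.  See `docs/methods.md` for the model details
and design choices.

## Worked example

Simulate a two-group miRNA-like × mRNA-like study, score all 9000 pairs,
and evaluate against the planted truth:

```python
import numpy as np
from dcseq import (SimulationDesign, simulate_study, correlate,
                   fisher_z_pairs, fit_em, ModelSpec, roc, truth_collapse)

study = simulate_study(SimulationDesign(seed=1))        # 30 x 300 features, 20+20 samples
corr = correlate(study.x_counts, study.y_counts, study.groups, "spearman")
fit = fit_em(fisher_z_pairs(corr), ModelSpec(3), seed=1)

dc = fit.posterior.dc_posterior
truth = truth_collapse(study.truth)
print("pairs:", dc.size)
print("top pair DC posterior: %.3f" % np.nanmax(dc))
print("planted DC pairs:", int(truth.sum()))
print("AUC: %.3f" % roc(dc, truth).auc)
```

```
pairs: 9000
top pair DC posterior: 1.000
planted DC pairs: 76
AUC: 0.976
```

9000 pairs are scored; 76 of them were planted with a correlation class
that differs between the groups, and ranking pairs by DC posterior
separates them from the null pairs with AUC 0.976.  The same analysis is
available from the shell:

```bash
dcseq simulate --outdir sim --seed 1
dcseq correlate --x sim/x.tsv --y sim/y.tsv --groups sim/groups.tsv \
      --metric spearman --output corr.tsv
dcseq fit --corr corr.tsv --components 3 --seed 1 \
      --output posteriors.tsv --params params.json
dcseq evaluate --scores posteriors.tsv --truth sim/truth.tsv --output eval.json
```

Other subcommands: `filter` (MAD outlier screen), `baseline` (Fisher
z-test), `run` (whole pipeline from a JSON config).  Pearson and BWMC
expect variance-stabilised input — either pass `--log-cpm` or supply your
own transformed matrices; Spearman and SparCC work on counts directly.

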