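"""Fisher z-test baseline for the difference of two correlations.

The classical test for whether a pair's correlation differs between groups:
both correlations are Fisher z-transformed and their difference divided by
its standard error ``sqrt(1/(n1-3) + 1/(n2-3))``, giving an approximately
standard-normal statistic under the null of equal population correlations.
This is the comparison method implemented in differential-correlation tools
built on Fisher's method, and serves as the frequentist counterpart to the
mixture model's DC posteriors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .correlation import FISHER_CLIP, CorrelationVectors, fisher_z
from .errors import ValidationError


@dataclass
class FisherTestResult:
    statistic: np.ndarray
    p_value: np.ndarray
    q_value: np.ndarray
    clipped: np.ndarray


def _storey_q(p: np.ndarray, lam: float = 0.5) -> np.ndarray:
    """Storey q-values: BH scaled by the estimated null proportion pi0."""
    pi0 = min(1.0, float(np.mean(p > lam)) / (1.0 - lam))
    _, q_bh, _, _ = multipletests(p, method="fdr_bh")
    return np.minimum(pi0 * q_bh, 1.0)


def compcorr(corr: CorrelationVectors, method: str = "bh") -> FisherTestResult:
    """Two-sided Fisher z-test per pair with FDR-adjusted q-values.

    ``method`` selects the q-value procedure: ``"bh"`` (Benjamini-Hochberg,
    default) or ``"storey"``.  Correlations with |r| at 1 are clamped as in
    the Fisher transform and flagged.  Pairs with missing correlations get
    NaN statistics and are excluded from the FDR adjustment.
    """
    if corr.n1 < 4 or corr.n2 < 4:
        raise ValidationError("Fisher z-test needs at least 4 samples per group")
    if method not in ("bh", "storey"):
        raise ValidationError(f"unknown q-value method {method!r}")
    z1, c1 = fisher_z(corr.r1, FISHER_CLIP)
    z2, c2 = fisher_z(corr.r2, FISHER_CLIP)
    se = np.sqrt(1.0 / (corr.n1 - 3) + 1.0 / (corr.n2 - 3))
    stat = (z1 - z2) / se
    p = 2.0 * norm.sf(np.abs(stat))
    q = np.full_like(p, np.nan)
    valid = np.isfinite(p)
    if valid.any():
        pv = p[valid]
        q[valid] = _storey_q(pv) if method == "storey" else multipletests(pv, method="fdr_bh")[1]
    return FisherTestResult(stat, p, q, c1 | c2)
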