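"""Scoring DC callers against simulation truth: ROC, AUC and rank curves.

Pairs are ranked by a score (a DC posterior probability, or ``1 - p`` for
the Fisher-test baseline) and compared with the planted per-pair truth.
Ties share a single ROC vertex (Mann-Whitney convention), so the trapezoidal
AUC equals the probability that a random positive outranks a random
negative.  The rank curve reports sensitivity and 1 - specificity after
calling the top-r pairs DC, for every rank r.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_curve

from .errors import ValidationError
from .mixture import collapse_component_label

VALID_LABELS = {"--", "-", "0", "+", "++"}


@dataclass
class EvaluationResult:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    rank_sensitivity: np.ndarray
    rank_one_minus_specificity: np.ndarray


def roc(scores: np.ndarray, truth: np.ndarray) -> EvaluationResult:
    """ROC curve, trapezoidal AUC and the per-rank sensitivity curve.

    ``truth`` is a boolean per-pair DC indicator; ``scores`` rank pairs with
    larger meaning more likely DC.  NaN scores are not accepted — drop
    missing pairs before calling.
    """
    scores = np.asarray(scores, float)
    truth = np.asarray(truth, bool)
    if scores.shape != truth.shape or scores.ndim != 1:
        raise ValidationError("scores and truth must be equal-length 1-D arrays")
    if not np.all(np.isfinite(scores)):
        raise ValidationError("scores contain non-finite values; drop missing pairs first")
    n_pos = int(truth.sum())
    n_neg = truth.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("truth needs at least one positive and one negative")
    if np.ptp(scores) == 0:
        warnings.warn("constant scores: degenerate ROC, AUC 0.5")
        fpr = np.array([0.0, 1.0])
        tpr = np.array([0.0, 1.0])
    else:
        fpr, tpr, _ = roc_curve(truth.astype(int), scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))

    order = np.argsort(-scores, kind="stable")
    cum_tp = np.cumsum(truth[order])
    ranks = np.arange(1, truth.size + 1)
    cum_fp = ranks - cum_tp
    return EvaluationResult(fpr, tpr, auc, cum_tp / n_pos, cum_fp / n_neg)


def truth_collapse(
    truth: list[tuple[str, str]] | np.ndarray, count_elevated_as_dc: bool = False
) -> np.ndarray:
    """Map per-pair joint class labels to a boolean DC indicator.

    Under the 5-component convention (``count_elevated_as_dc=True``) any
    off-diagonal class — including elevated DC like (+, ++) — is a positive.
    Under the 3-component convention the elevated labels are first collapsed
    (-- to -, ++ to +), so elevated DC classes land on the diagonal and count
    as negatives.
    """
    out = np.empty(len(truth), dtype=bool)
    for k, (a, b) in enumerate(truth):
        if a not in VALID_LABELS or b not in VALID_LABELS:
            raise ValidationError(f"unknown class label ({a}, {b})")
        if count_elevated_as_dc:
            out[k] = a != b
        else:
            out[k] = collapse_component_label(a) != collapse_component_label(b)
    return out


def plot_roc(results: dict[str, EvaluationResult], path: str) -> None:
    """Write a PNG with the ROC curves of one or more callers."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for name, res in results.items():
        ax.plot(res.fpr, res.tpr, label=f"{name} (AUC {res.auc:.3f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
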