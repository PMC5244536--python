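"""Pairwise correlation between molecular features, per biological group.

Feature pairs are enumerated either *within* one dataset (gene-gene style,
strict lower triangle) or *between* two datasets (miRNA-gene style, full
rectangle).  For each pair the chosen metric is computed separately on the
group-1 and group-2 samples, yielding two correlation vectors that feed the
mixture model after Fisher's variance-stabilising z-transform.

Four metrics are supported:

``pearson``
    Ordinary product-moment correlation; expects continuous,
    variance-stabilised data.
``spearman``
    Pearson on average ranks; rank-based, suited to counts.
``bwmc``
    Biweight midcorrelation — a median/MAD-based robust analogue of Pearson
    with Tukey biweight downweighting of outlying samples.
``sparcc``
    Sparse compositional correlation for count data: basis variances are
    solved from log-ratio variances under the assumption that most pairs are
    uncorrelated, with iterative exclusion of strongly correlated pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .errors import SingularSystemError, ValidationError
from .preprocess import CountMatrix, GroupAssignment

METRICS = ("pearson", "spearman", "bwmc", "sparcc")
#: Metrics designed for raw count input.
COUNT_METRICS = ("spearman", "sparcc")
#: Largest |r| passed to atanh; keeps z below ~8.4.
FISHER_CLIP = 1.0 - 1e-7


@dataclass
class PairIndex:
    """Bookkeeping for an ordered list of feature-index pairs."""

    mode: str  # "within" | "between"
    pairs: np.ndarray  # (n_pairs, 2) int
    n_x: int
    n_y: int | None = None

    @property
    def n_pairs(self) -> int:
        return self.pairs.shape[0]

    def positions(self, i: np.ndarray, j: np.ndarray) -> np.ndarray:
        """Row-major position of pair (i, j) in the enumeration order."""
        i = np.asarray(i)
        j = np.asarray(j)
        if self.mode == "within":
            p = self.n_x
            return i * (2 * p - i - 1) // 2 + (j - i - 1)
        return i * self.n_y + j


@dataclass
class CorrelationVectors:
    """Per-pair correlations for the two groups under one metric."""

    r1: np.ndarray
    r2: np.ndarray
    metric: str
    n1: int
    n2: int
    index: PairIndex
    feature_ids_x: list[str] | None = None
    feature_ids_y: list[str] | None = None

    @property
    def valid(self) -> np.ndarray:
        """Pairs with a defined correlation in both groups."""
        return np.isfinite(self.r1) & np.isfinite(self.r2)

    def pair_labels(self) -> tuple[list[str], list[str]]:
        ids_x = self.feature_ids_x or [str(i) for i in range(self.index.n_x)]
        ids_y = self.feature_ids_y if self.index.mode == "between" else ids_x
        fi = [ids_x[i] for i in self.index.pairs[:, 0]]
        fj = [ids_y[j] for j in self.index.pairs[:, 1]]
        return fi, fj


@dataclass
class ZScorePairs:
    """Fisher z-scores for the two groups, with clipping flags."""

    z1: np.ndarray
    z2: np.ndarray
    clipped: np.ndarray

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.z1) & np.isfinite(self.z2)

    @property
    def n_pairs(self) -> int:
        return self.z1.shape[0]


def enumerate_pairs(n_x: int, n_y: int | None = None) -> PairIndex:
    """Enumerate feature pairs in deterministic row-major order.

    Within mode (``n_y is None``): all i < j, giving n_x(n_x-1)/2 pairs.
    Between mode: the full n_x * n_y rectangle.
    """
    if n_y is None:
        if n_x < 2:
            raise ValidationError("within mode needs at least 2 features")
        i, j = np.triu_indices(n_x, k=1)
        return PairIndex("within", np.column_stack([i, j]), n_x)
    if n_x < 1 or n_y < 1:
        raise ValidationError("between mode needs at least 1 feature on each side")
    i, j = np.divmod(np.arange(n_x * n_y), n_y)
    return PairIndex("between", np.column_stack([i, j]), n_x, n_y)


# ---------------------------------------------------------------------------
# metric kernels: all take row-feature matrices and return a correlation
# matrix (cross A-vs-B), with NaN where a feature has zero variance


def _pearson_cross(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    a0 = a - a.mean(axis=1, keepdims=True)
    b0 = b - b.mean(axis=1, keepdims=True)
    na = np.sqrt((a0**2).sum(axis=1))
    nb = np.sqrt((b0**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        c = (a0 @ b0.T) / np.outer(na, nb)
    return np.clip(c, -1.0, 1.0)


def _spearman_cross(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return _pearson_cross(rankdata(a, axis=1), rankdata(b, axis=1))


def _biweight_transform(a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Tukey-biweight-centred rows and a mask of MAD-degenerate features."""
    med = np.median(a, axis=1, keepdims=True)
    mad = np.median(np.abs(a - med), axis=1, keepdims=True)
    degenerate = (mad == 0).ravel()
    with np.errstate(divide="ignore", invalid="ignore"):
        u = (a - med) / (9.0 * mad)
    w = np.where(np.abs(u) < 1.0, (1.0 - u**2) ** 2, 0.0)
    w[degenerate] = 0.0
    return (a - med) * w, degenerate


def bicor(x: np.ndarray, y: np.ndarray) -> float:
    """Biweight midcorrelation of two sample vectors.

    Samples are weighted by ``(1 - u^2)^2`` for ``|u| < 1`` with
    ``u = (x - med) / (9 MAD)``, so points beyond 9 MADs are ignored.  When
    either vector has zero MAD the pair falls back to Pearson (warning).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("bicor expects two equal-length 1-D vectors")
    if x.size < 4:
        raise ValidationError("bicor needs at least 4 samples")
    xt, dx = _biweight_transform(x[None, :])
    yt, dy = _biweight_transform(y[None, :])
    if dx[0] or dy[0]:
        warnings.warn("zero MAD in bicor; falling back to Pearson for this pair")
        return float(_pearson_cross(x[None, :], y[None, :])[0, 0])
    return float(_pearson_cross_raw(xt, yt)[0, 0])


def _pearson_cross_raw(a0: np.ndarray, b0: np.ndarray) -> np.ndarray:
    """Normalized cross products of already-centred rows."""
    na = np.sqrt((a0**2).sum(axis=1))
    nb = np.sqrt((b0**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        c = (a0 @ b0.T) / np.outer(na, nb)
    return np.clip(c, -1.0, 1.0)


def _bwmc_cross(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    at, da = _biweight_transform(a)
    bt, db = _biweight_transform(b)
    c = _pearson_cross_raw(at, bt)
    if da.any() or db.any():
        n_bad = int(da.sum() + db.sum())
        warnings.warn(f"{n_bad} feature(s) with zero MAD; Pearson fallback for their pairs")
        p = _pearson_cross(a, b)
        bad = np.logical_or.outer(da, db)
        c = np.where(bad, p, c)
    return c


# ---------------------------------------------------------------------------
# SparCC


def solve_basis_variances(
    t: np.ndarray, excluded: set[tuple[int, int]] | None = None, floor: float = 1e-10
) -> np.ndarray:
    """Solve for basis variances from a log-ratio variation matrix.

    Under the sparsity assumption (most pairs uncorrelated) the variation
    matrix entries satisfy ``t_ij ~= w_i + w_j`` with ``w_i`` the basis
    variance of feature i, giving per-feature linear equations
    ``sum_j t_ij = |N(i)| w_i + sum_{j in N(i)} w_j`` over the non-excluded
    partners N(i).  Negative solutions are clamped to a small positive floor.
    """
    t = np.asarray(t, float)
    p = t.shape[0]
    if p < 4:
        raise ValidationError("basis-variance system needs at least 4 features")
    m = np.ones((p, p))
    np.fill_diagonal(m, p - 1.0)
    tt = t.copy()
    np.fill_diagonal(tt, 0.0)
    if excluded:
        for i, j in excluded:
            m[i, j] = m[j, i] = 0.0
            m[i, i] -= 1.0
            m[j, j] -= 1.0
            tt[i, j] = tt[j, i] = 0.0
    rhs = tt.sum(axis=1)
    try:
        w = np.linalg.solve(m, rhs)
    except np.linalg.LinAlgError as exc:
        raise SingularSystemError(f"basis-variance system singular: {exc}") from exc
    if np.any(w <= 0):
        warnings.warn("negative basis variance solved; clamping to floor")
        w = np.maximum(w, floor)
    return w


def _rho_from_basis(t: np.ndarray, w: np.ndarray) -> np.ndarray:
    denom = 2.0 * np.sqrt(np.outer(w, w))
    rho = (w[:, None] + w[None, :] - t) / denom
    np.fill_diagonal(rho, 1.0)
    return np.clip(rho, -1.0, 1.0)


def sparcc(
    counts: np.ndarray,
    pseudocount: float = 0.5,
    exclusion_threshold: float = 0.1,
    max_exclusion_rounds: int = 10,
    resamples: int = 0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """SparCC correlation matrix for one group's count matrix (features x samples).

    Counts are converted to per-sample fractions with a pseudocount, log-ratio
    variances ``t_ij = var(log(f_i / f_j))`` are computed, basis variances are
    solved under the sparsity assumption, and the strongest-correlated pair is
    iteratively excluded from the system and the solve repeated (default up to
    10 rounds, exclusion threshold 0.1).

    With ``resamples > 0`` fractions are drawn from per-sample Dirichlet
    posteriors and the correlation matrix averaged over the draws; the default
    is a single deterministic pass.
    """
    counts = np.asarray(counts, float)
    p, n = counts.shape
    if p < 4:
        raise ValidationError("SparCC needs at least 4 features")
    if n < 4:
        raise ValidationError("SparCC needs at least 4 samples")
    if np.any(counts < 0):
        raise ValidationError("SparCC requires non-negative counts")

    def one_pass(frac: np.ndarray) -> np.ndarray:
        logf = np.log(frac)
        # t_ij = var(log f_i - log f_j), computed via the covariance matrix
        cov = np.cov(logf)
        v = np.diag(cov)
        t = v[:, None] + v[None, :] - 2.0 * cov
        np.fill_diagonal(t, 0.0)
        excluded: set[tuple[int, int]] = set()
        w = solve_basis_variances(t)
        rho = _rho_from_basis(t, w)
        for _ in range(max_exclusion_rounds):
            a = np.abs(rho)
            np.fill_diagonal(a, 0.0)
            for i, j in excluded:
                a[i, j] = a[j, i] = 0.0
            i, j = np.unravel_index(np.argmax(a), a.shape)
            if a[i, j] <= exclusion_threshold:
                break
            excluded.add((min(i, j), max(i, j)))
            w = solve_basis_variances(t, excluded)
            rho = _rho_from_basis(t, w)
        return rho

    if resamples > 0:
        rng = rng or np.random.default_rng()
        acc = np.zeros((p, p))
        for _ in range(resamples):
            frac = np.empty_like(counts)
            for s in range(n):
                frac[:, s] = rng.dirichlet(counts[:, s] + pseudocount)
            acc += one_pass(frac)
        return acc / resamples
    frac = (counts + pseudocount) / (counts + pseudocount).sum(axis=0, keepdims=True)
    return one_pass(frac)


# ---------------------------------------------------------------------------


def _metric_cross(metric: str, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    if metric == "pearson":
        return _pearson_cross(a, b)
    if metric == "spearman":
        return _spearman_cross(a, b)
    if metric == "bwmc":
        return _bwmc_cross(a, b)
    raise ValidationError(f"unknown metric {metric!r}")


def correlate(
    x: CountMatrix,
    y: CountMatrix | None,
    groups: GroupAssignment,
    metric: str = "pearson",
    sparcc_kwargs: dict | None = None,
) -> CorrelationVectors:
    """Per-pair correlations in each group for a within- or between-omics analysis.

    Pearson and biweight midcorrelation expect variance-stabilised data while
    Spearman and SparCC accept raw counts; a mismatch between the metric and
    the matrix mode triggers a warning, not an error.  Pairs touching a
    zero-variance feature get NaN and are excluded downstream.
    """
    if metric not in METRICS:
        raise ValidationError(f"metric must be one of {METRICS}, got {metric!r}")
    if groups.labels.shape[0] != x.n_samples:
        raise ValidationError("group vector length does not match sample count")
    if y is not None and y.sample_ids != x.sample_ids:
        raise ValidationError("x and y must share sample ids in identical order")
    if metric in COUNT_METRICS and x.mode != "counts" and metric == "sparcc":
        raise ValidationError("SparCC requires raw counts")
    if metric in ("pearson", "bwmc") and x.mode == "counts":
        warnings.warn(f"{metric} expects transformed data but matrix is in count mode")
    if metric == "spearman" and x.mode == "transformed":
        warnings.warn("spearman is intended for count data; got transformed mode")

    index = enumerate_pairs(x.n_features, None if y is None else y.n_features)
    i_idx, j_idx = index.pairs[:, 0], index.pairs[:, 1]
    rs = []
    for mask in (groups.mask1, groups.mask2):
        if metric == "sparcc":
            stacked = x.values[:, mask] if y is None else np.vstack(
                [x.values[:, mask], y.values[:, mask]]
            )
            rho = sparcc(stacked, **(sparcc_kwargs or {}))
            if y is None:
                r = rho[i_idx, j_idx]
            else:
                r = rho[i_idx, x.n_features + j_idx]
        else:
            a = x.values[:, mask]
            b = a if y is None else y.values[:, mask]
            c = _metric_cross(metric, a, b)
            r = c[i_idx, j_idx]
        rs.append(np.asarray(r, float))
    r1, r2 = rs
    n_missing = int(np.sum(~(np.isfinite(r1) & np.isfinite(r2))))
    if n_missing:
        warnings.warn(f"{n_missing} pair(s) with undefined correlation (zero variance)")
    return CorrelationVectors(
        r1,
        r2,
        metric,
        groups.n1,
        groups.n2,
        index,
        list(x.feature_ids),
        None if y is None else list(y.feature_ids),
    )


def fisher_z(r: np.ndarray, clip: float = FISHER_CLIP) -> tuple[np.ndarray, np.ndarray]:
    """Fisher z-transform ``z = atanh(r)`` with clamping of |r| near 1.

    Returns the z array (NaN preserved for missing correlations) and a
    boolean array marking where clamping occurred.
    """
    if not 0.0 < clip < 1.0:
        raise ValidationError("clip must be in (0, 1)")
    r = np.asarray(r, float)
    clipped = np.abs(r) > clip
    z = np.arctanh(np.clip(r, -clip, clip))
    return z, clipped & np.isfinite(r)


def fisher_z_pairs(corr: CorrelationVectors, clip: float = FISHER_CLIP) -> ZScorePairs:
    """Transform both groups' correlation vectors to paired z-scores."""
    z1, c1 = fisher_z(corr.r1, clip)
    z2, c2 = fisher_z(corr.r2, clip)
    return ZScorePairs(z1, z2, c1 | c2)
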