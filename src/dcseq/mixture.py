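"""Per-group normal mixture model over paired Fisher z-scores, fit by EM.

Each feature pair contributes a pair of z-transformed correlations
``(z1, z2)``, one per biological group.  Within each group the z-scores are
modelled as a k-component normal mixture whose components represent absent
(0), positive (+) and negative (-) association — and, with k = 5, the
strongly positive (++) and strongly negative (--) variants.  A pair's *joint
class* is the pair of components ``(a, b)`` it occupies in the two groups,
giving k^2 classes with a k x k probability table pi.  Off-diagonal classes
are differentially correlated (DC): the association differs between groups.
The DC posterior probability of a pair is the sum of its posterior mass over
the off-diagonal classes.

The likelihood treats feature pairs as independent, which is false whenever
one feature occurs in many pairs.  The subsampling variant addresses this by
repeatedly fitting EM on a random *independent* pair set (no feature reused
within a round), averaging the fitted parameters over rounds, and running a
single E-step over all pairs with the averaged parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp
from scipy.stats import norm

from .correlation import PairIndex, ZScorePairs
from .errors import ConvergenceError, ValidationError

LABELS_3 = ("-", "0", "+")
LABELS_5 = ("--", "-", "0", "+", "++")

#: Smallest allowed component standard deviation (variance floor 1e-4).
SD_FLOOR = 1e-2


@dataclass(frozen=True)
class ModelSpec:
    """Choice of 3- or 5-component mixture (9 or 25 joint classes)."""

    components: int = 3
    transform: bool = True

    def __post_init__(self) -> None:
        if self.components not in (3, 5):
            raise ValidationError("components must be 3 or 5")

    @property
    def component_labels(self) -> tuple[str, ...]:
        return LABELS_3 if self.components == 3 else LABELS_5

    @property
    def n_classes(self) -> int:
        return self.components**2

    @property
    def zero_index(self) -> int:
        return self.components // 2

    def class_labels(self) -> list[str]:
        """Joint-class labels 'a/b' in row-major (group1, group2) order."""
        labels = self.component_labels
        return [f"{a}/{b}" for a in labels for b in labels]


@dataclass
class MixtureParams:
    """Component means/SDs per group plus the joint class-probability table."""

    mu1: np.ndarray
    mu2: np.ndarray
    sigma1: np.ndarray
    sigma2: np.ndarray
    pi: np.ndarray  # (k, k), pi[a, b] = P(class a in group 1, b in group 2)
    spec: ModelSpec = field(default_factory=ModelSpec)

    def __post_init__(self) -> None:
        k = self.spec.components
        for name in ("mu1", "mu2", "sigma1", "sigma2"):
            arr = np.asarray(getattr(self, name), float)
            if arr.shape != (k,):
                raise ValidationError(f"{name} must have length {k}")
            setattr(self, name, arr)
        self.pi = np.asarray(self.pi, float)
        if self.pi.shape != (k, k):
            raise ValidationError(f"pi must be {k}x{k}")
        if np.any(self.pi < -1e-12) or abs(self.pi.sum() - 1.0) > 1e-8:
            raise ValidationError("pi entries must be non-negative and sum to 1")
        if np.any(self.sigma1 <= 0) or np.any(self.sigma2 <= 0):
            raise ValidationError("all component SDs must be positive")

    @property
    def n_free_params(self) -> int:
        """Free parameters: pi (k^2 - 1) + per-group means (k - 1 each, the
        null component pinned at 0) + per-group SDs (k each)."""
        k = self.spec.components
        return (k * k - 1) + 2 * (k - 1) + 2 * k


@dataclass
class PosteriorResult:
    """Per-pair class posteriors, DC posteriors and model log-likelihood.

    ``class_posteriors`` has one row per pair and k^2 columns in row-major
    (group1 component, group2 component) order; rows for pairs with missing
    correlations are NaN and ``class_assignment`` is -1 there.
    """

    class_posteriors: np.ndarray
    dc_posterior: np.ndarray
    class_assignment: np.ndarray
    loglik: float
    spec: ModelSpec = field(default_factory=ModelSpec)


@dataclass
class SubsamplingConfig:
    """Settings for the subsampling EM variant."""

    iterations: int = 100
    subsample_size: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValidationError("iterations must be positive")


@dataclass
class FitResult:
    params: MixtureParams
    posterior: PosteriorResult
    converged: bool
    n_iter: int
    loglik_trace: np.ndarray
    bic: float


# ---------------------------------------------------------------------------


def _log_class_densities(z: ZScorePairs, params: MixtureParams) -> np.ndarray:
    """(n, k, k) array of log pi[a,b] + log phi(z1; a) + log phi(z2; b)."""
    with np.errstate(divide="ignore"):
        logpi = np.log(np.maximum(params.pi, 1e-300))
    l1 = norm.logpdf(z.z1[:, None], params.mu1[None, :], params.sigma1[None, :])
    l2 = norm.logpdf(z.z2[:, None], params.mu2[None, :], params.sigma2[None, :])
    return logpi[None, :, :] + l1[:, :, None] + l2[:, None, :]


def e_step(z: ZScorePairs, params: MixtureParams) -> PosteriorResult:
    """Posterior class probabilities for every pair, plus the log-likelihood.

    The posterior of joint class (a, b) is proportional to
    ``pi[a,b] * phi(z1; mu1[a], sigma1[a]) * phi(z2; mu2[b], sigma2[b])``;
    the computation runs in log-space so extreme z-scores never produce NaN.
    """
    k = params.spec.components
    n = z.n_pairs
    valid = z.valid
    gamma = np.full((n, k, k), np.nan)
    dc = np.full(n, np.nan)
    assign = np.full(n, -1, dtype=int)
    loglik = 0.0
    if valid.any():
        zv = ZScorePairs(z.z1[valid], z.z2[valid], np.zeros(valid.sum(), bool))
        logd = _log_class_densities(zv, params)
        flat = logd.reshape(valid.sum(), k * k)
        lse = logsumexp(flat, axis=1)
        g = np.exp(flat - lse[:, None]).reshape(-1, k, k)
        gamma[valid] = g
        diag = g[:, np.arange(k), np.arange(k)].sum(axis=1)
        dc[valid] = np.clip(1.0 - diag, 0.0, 1.0)
        assign[valid] = np.argmax(flat, axis=1)
        loglik = float(lse.sum())
    return PosteriorResult(gamma.reshape(n, k * k), dc, assign, loglik, params.spec)


def m_step(
    z: ZScorePairs,
    posteriors: PosteriorResult,
    spec: ModelSpec,
    prev: MixtureParams,
    sd_floor: float = SD_FLOOR,
) -> MixtureParams:
    """Maximisation step: update pi, the component means and the SDs.

    Group-1 component responsibilities are row sums of the class posteriors
    over the group-2 index (and vice versa); means and SDs are the
    responsibility-weighted moments, with the null component's mean pinned at
    0 (its SD still updated).  An empty component (total responsibility below
    1e-8) keeps its previous parameters.  If an update breaks the ascending
    ordering of means within a group, components are re-sorted and pi's
    rows/columns permuted accordingly, preventing label switching.
    """
    k = spec.components
    valid = z.valid
    gamma = posteriors.class_posteriors[valid].reshape(-1, k, k)
    n = gamma.shape[0]
    if n == 0:
        raise ValidationError("no valid pairs for the M-step")
    pi = gamma.mean(axis=0)
    pi = np.maximum(pi, 0.0)
    pi /= pi.sum()

    def update_group(zg: np.ndarray, resp: np.ndarray, mu_prev, sg_prev):
        mu = np.empty(k)
        sg = np.empty(k)
        tot = resp.sum(axis=0)
        for a in range(k):
            if tot[a] < 1e-8:
                warnings.warn(f"empty mixture component {a}; parameters frozen")
                mu[a], sg[a] = mu_prev[a], sg_prev[a]
                continue
            mu[a] = float(resp[:, a] @ zg) / tot[a]
            if a == spec.zero_index:
                mu[a] = 0.0
            var = float(resp[:, a] @ (zg - mu[a]) ** 2) / tot[a]
            sg[a] = max(np.sqrt(var), sd_floor)
        return mu, sg

    r1 = gamma.sum(axis=2)  # (n, k): responsibility of group-1 components
    r2 = gamma.sum(axis=1)
    mu1, sigma1 = update_group(z.z1[valid], r1, prev.mu1, prev.sigma1)
    mu2, sigma2 = update_group(z.z2[valid], r2, prev.mu2, prev.sigma2)

    # re-impose ascending mean order per group (relabel if violated)
    order1 = np.argsort(mu1, kind="stable")
    order2 = np.argsort(mu2, kind="stable")
    if not (np.array_equal(order1, np.arange(k)) and np.array_equal(order2, np.arange(k))):
        mu1, sigma1 = mu1[order1], sigma1[order1]
        mu2, sigma2 = mu2[order2], sigma2[order2]
        pi = pi[np.ix_(order1, order2)]
        mu1[spec.zero_index] = 0.0
        mu2[spec.zero_index] = 0.0
    return MixtureParams(mu1, mu2, sigma1, sigma2, pi, spec)


#: Tail quantile used to seed the non-null components.
INIT_TAIL_QUANTILE = 0.95


def _initial_params(z: ZScorePairs, spec: ModelSpec, jitter_rng=None) -> MixtureParams:
    """Deterministic tail-based initialization.

    Correlated pairs are usually a small minority, so seeding mu(+)/mu(-) at
    the mean of *all* positive/negative z-scores places them inside the null
    bulk, from where EM tends to collapse every component onto the null.
    Instead the outer components are seeded from the extreme tails: mu(+)
    starts at the mean of the z-scores above the 95th percentile (mu(-)
    symmetrically below the 5th); for k = 5 each tail is split at its median
    to seed the moderate and elevated components separately.  SDs start at
    the pooled SD; pi starts diagonal-heavy (80% concordant mass), matching
    the prior belief that most pairs are not DC.
    """
    k = spec.components
    q = INIT_TAIL_QUANTILE

    def group_means(zg: np.ndarray) -> np.ndarray:
        hi = zg[zg >= np.quantile(zg, q)]
        lo = zg[zg <= np.quantile(zg, 1.0 - q)]
        if k == 3:
            mp = max(float(hi.mean()), 0.05) if hi.size else 0.5
            mn = min(float(lo.mean()), -0.05) if lo.size else -0.5
            mu = np.array([mn, 0.0, mp])
        else:
            def split(tail, sign):
                if tail.size < 2:
                    return sign * 0.5, sign * 1.0
                med = np.median(tail)
                inner = tail[np.abs(tail) <= abs(med)]
                outer = tail[np.abs(tail) > abs(med)]
                a = float(inner.mean()) if inner.size else med
                b = float(outer.mean()) if outer.size else 2.0 * med
                return sign * max(sign * a, 0.05), sign * max(sign * b, 0.10)
            p1, p2 = split(hi, +1.0)
            n1, n2 = split(lo, -1.0)
            mu = np.array([n2, n1, 0.0, p1, p2])
        mu = np.sort(mu)
        mu[k // 2] = 0.0
        return mu

    valid = z.valid
    z1, z2 = z.z1[valid], z.z2[valid]
    mu1, mu2 = group_means(z1), group_means(z2)
    s1 = max(float(np.std(z1)), SD_FLOOR)
    s2 = max(float(np.std(z2)), SD_FLOOR)
    sigma1 = np.full(k, s1)
    sigma2 = np.full(k, s2)
    pi = np.full((k, k), 0.2 / (k * k - k))
    np.fill_diagonal(pi, 0.8 / k)
    if jitter_rng is not None:
        mu1 = np.sort(mu1 + jitter_rng.normal(0, 0.05, k))
        mu2 = np.sort(mu2 + jitter_rng.normal(0, 0.05, k))
        mu1[spec.zero_index] = 0.0
        mu2[spec.zero_index] = 0.0
    return MixtureParams(mu1, mu2, sigma1, sigma2, pi, spec)


def fit_em(
    z: ZScorePairs,
    spec: ModelSpec | None = None,
    tol: float = 1e-6,
    max_iter: int = 500,
    seed: int = 0,
    restarts: int = 2,
    sd_floor: float = SD_FLOOR,
) -> FitResult:
    """Fit the mixture by EM from a deterministic initialization.

    Iterates E/M steps until the relative log-likelihood change drops below
    ``tol`` or ``max_iter`` is reached.  The mixture likelihood is
    multimodal, so ``restarts`` additional seeded random-jitter
    initializations are tried (default 2) and the best final log-likelihood
    kept.  Same inputs and seed give bit-identical output.
    """
    spec = spec or ModelSpec()
    n_valid = int(z.valid.sum())
    if n_valid < 2:
        raise ValidationError("need at least 2 valid z-score pairs")
    if n_valid < 10 * spec.n_classes:
        warnings.warn(
            f"only {n_valid} valid pairs for {spec.n_classes} classes; "
            "parameter estimates may be unstable"
        )
    rng = np.random.default_rng(seed)
    inits = [_initial_params(z, spec)]
    inits += [_initial_params(z, spec, jitter_rng=rng) for _ in range(restarts)]

    best: FitResult | None = None
    for params in inits:
        trace: list[float] = []
        converged = False
        post = e_step(z, params)
        trace.append(post.loglik)
        it = 0
        for it in range(1, max_iter + 1):
            params = m_step(z, post, spec, params, sd_floor)
            post = e_step(z, params)
            trace.append(post.loglik)
            rel = abs(trace[-1] - trace[-2]) / max(1.0, abs(trace[-2]))
            if rel < tol:
                converged = True
                break
        bic = -2.0 * post.loglik + params.n_free_params * np.log(n_valid)
        result = FitResult(params, post, converged, it, np.array(trace), bic)
        if best is None or result.posterior.loglik > best.posterior.loglik:
            best = result
    if not best.converged:
        warnings.warn(f"EM did not converge within {max_iter} iterations")
    return best


# ---------------------------------------------------------------------------
# subsampling variant


def independent_pair_sample(
    index: PairIndex, rng: np.random.Generator, size: int | None = None
) -> np.ndarray:
    """Positions of a random pair set in which no feature is reused.

    Within mode: a random matching of the features (floor(p/2) pairs).
    Between mode: a random pairing of distinct x-features with distinct
    y-features (min(p_x, p_y) pairs).  ``size`` may shrink the sample.
    """
    if index.mode == "within":
        perm = rng.permutation(index.n_x)
        m = index.n_x // 2
        a = perm[: 2 * m : 2]
        b = perm[1 : 2 * m : 2]
        i = np.minimum(a, b)
        j = np.maximum(a, b)
    else:
        m = min(index.n_x, index.n_y)
        i = rng.permutation(index.n_x)[:m]
        j = rng.permutation(index.n_y)[:m]
    if size is not None:
        i, j = i[:size], j[:size]
    return index.positions(i, j)


def fit_em_subsampled(
    z: ZScorePairs,
    index: PairIndex,
    spec: ModelSpec | None = None,
    config: SubsamplingConfig | None = None,
    tol: float = 1e-6,
    max_iter: int = 500,
    sd_floor: float = SD_FLOOR,
) -> FitResult:
    """Subsampling EM: average parameters over independent-pair rounds.

    Each round draws a fresh independent pair set, runs :func:`fit_em` on
    that subset, and the component means, SDs and (renormalised) class table
    are averaged over the converged rounds.  A final E-step with the averaged
    parameters yields posteriors for *all* pairs.  Rounds that fail to
    converge are dropped; more than half dropping is an error.
    """
    spec = spec or ModelSpec()
    config = config or SubsamplingConfig()
    if index.n_pairs != z.n_pairs:
        raise ValidationError("pair index and z-scores disagree in length")
    rng = np.random.default_rng(config.seed)
    max_indep = index.n_x // 2 if index.mode == "within" else min(index.n_x, index.n_y)
    size = config.subsample_size or max_indep
    if size < 10 * spec.n_classes:
        warnings.warn(
            f"subsample of {size} independent pairs is small for "
            f"{spec.n_classes} classes; averaged estimates may be noisy"
        )
    mus1, mus2, sgs1, sgs2, pis = [], [], [], [], []
    dropped = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # per-round small-sample warnings
        for _ in range(config.iterations):
            pos = independent_pair_sample(index, rng, size)
            sub = ZScorePairs(z.z1[pos], z.z2[pos], np.zeros(pos.size, bool))
            if int(sub.valid.sum()) < spec.n_classes:
                dropped += 1
                continue
            fit = fit_em(sub, spec, tol=tol, max_iter=max_iter, sd_floor=sd_floor)
            if not fit.converged:
                dropped += 1
                continue
            mus1.append(fit.params.mu1)
            mus2.append(fit.params.mu2)
            sgs1.append(fit.params.sigma1)
            sgs2.append(fit.params.sigma2)
            pis.append(fit.params.pi)
    if dropped > config.iterations // 2:
        raise ConvergenceError(
            f"{dropped}/{config.iterations} subsampling rounds failed to converge"
        )
    if dropped:
        warnings.warn(f"{dropped} subsampling round(s) dropped")
    mu1 = np.mean(mus1, axis=0)
    mu2 = np.mean(mus2, axis=0)
    mu1[spec.zero_index] = 0.0
    mu2[spec.zero_index] = 0.0
    pi = np.mean(pis, axis=0)
    pi /= pi.sum()
    params = MixtureParams(mu1, mu2, np.mean(sgs1, axis=0), np.mean(sgs2, axis=0), pi, spec)
    post = e_step(z, params)
    n_valid = int(z.valid.sum())
    bic = -2.0 * post.loglik + params.n_free_params * np.log(max(n_valid, 2))
    return FitResult(params, post, True, config.iterations, np.array([post.loglik]), bic)


# ---------------------------------------------------------------------------
# output shaping


def dc_posterior_summary(
    result: PosteriorResult, index: PairIndex
) -> tuple[np.ndarray, np.ndarray]:
    """Materialise the DC-posterior and class matrices.

    Within mode returns square matrices with results in the strict lower
    triangle (pair (i, j), i < j stored at row j, column i) and NaN / empty
    elsewhere; between mode fills the full x-by-y rectangle (x features in
    rows).  The class matrix holds 'a/b' joint-class labels.
    """
    labels = np.array(result.spec.class_labels(), dtype=object)
    if index.mode == "within":
        p = index.n_x
        pp = np.full((p, p), np.nan)
        cls = np.full((p, p), "", dtype=object)
        rows, cols = index.pairs[:, 1], index.pairs[:, 0]
    else:
        pp = np.full((index.n_x, index.n_y), np.nan)
        cls = np.full((index.n_x, index.n_y), "", dtype=object)
        rows, cols = index.pairs[:, 0], index.pairs[:, 1]
    pp[rows, cols] = result.dc_posterior
    assigned = result.class_assignment >= 0
    cls[rows[assigned], cols[assigned]] = labels[result.class_assignment[assigned]]
    return pp, cls


def elevated_dc_classes(spec: ModelSpec) -> set[tuple[int, int]]:
    """Joint classes where the two groups share a sign but differ in strength.

    Only the 5-component model can represent these 'elevated DC' classes:
    (-, --), (--, -), (+, ++), (++, +).  Under the 3-component convention
    they collapse onto the diagonal and count as non-DC.
    """
    if spec.components != 5:
        raise ValidationError("elevated DC classes exist only for the 5-component model")
    return {(0, 1), (1, 0), (3, 4), (4, 3)}


def collapse_component_label(label: str) -> str:
    """Map a 5-component label onto the 3-component vocabulary (-- -> -, ++ -> +)."""
    return {"--": "-", "++": "+"}.get(label, label)
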