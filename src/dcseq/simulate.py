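"""Two-group negative-binomial count simulation with planted DC classes.

The generator emulates a paired-omics sequencing study: a small set of
x-features (miRNA-like) and a larger set of y-features (mRNA-like), each
with negative-binomial marginals (variance ``mu + mu^2 * dispersion``), in
two sample groups.  Dependence is introduced through a Gaussian copula: each
y-feature draws one joint correlation class; if the class is not (0, 0) the
y-feature is generated against exactly one designated x partner with the
class's latent correlation in each group, and — mimicking how correlated
transcripts track their regulator's abundance — inherits that partner's NB
mean while keeping its own dispersion.  All remaining pairs are independent
by construction, so the per-pair ground-truth class table is exactly
realisable.

The defaults define the study conditions used throughout the test-suite and
the acceptance analysis: 30 x-features, 300 y-features, 20 samples per
group, latent correlation targets 0 / ±0.7 (±0.95 for the elevated
components), NB means uniform on (10, 1000) and dispersions on (0.05, 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import nbinom, norm

from .correlation import PairIndex, enumerate_pairs
from .errors import ValidationError
from .mixture import LABELS_3, LABELS_5
from .preprocess import CountMatrix, GroupAssignment

#: Latent (Gaussian-copula) correlation for each component label.
DEFAULT_TARGETS = {"--": -0.95, "-": -0.7, "0": 0.0, "+": 0.7, "++": 0.95}


def default_class_proportions(components: int = 3) -> dict[tuple[str, str], float]:
    """Per-y-feature probabilities of each joint class.

    Mostly-null mixtures with a mix of classic DC (sign/presence changes),
    concordant correlation and — for the 5-component vocabulary — elevated
    DC classes.
    """
    if components == 3:
        return {
            ("0", "0"): 0.70,
            ("+", "+"): 0.05,
            ("-", "-"): 0.05,
            ("+", "0"): 0.04,
            ("0", "+"): 0.04,
            ("-", "0"): 0.04,
            ("0", "-"): 0.04,
            ("+", "-"): 0.02,
            ("-", "+"): 0.02,
        }
    if components == 5:
        return {
            ("0", "0"): 0.66,
            ("+", "+"): 0.04,
            ("-", "-"): 0.04,
            ("++", "++"): 0.02,
            ("--", "--"): 0.02,
            ("+", "0"): 0.03,
            ("0", "+"): 0.03,
            ("-", "0"): 0.03,
            ("0", "-"): 0.03,
            ("+", "-"): 0.015,
            ("-", "+"): 0.015,
            ("+", "++"): 0.0175,
            ("++", "+"): 0.0175,
            ("-", "--"): 0.0175,
            ("--", "-"): 0.0175,
        }
    raise ValidationError("components must be 3 or 5")


@dataclass
class SimulationDesign:
    """Parameters of one synthetic two-group study."""

    n_x: int = 30
    n_y: int = 300
    n1: int = 20
    n2: int = 20
    components: int = 3
    class_proportions: dict[tuple[str, str], float] | None = None
    target_correlations: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_TARGETS))
    nb_mu_range: tuple[float, float] = (10.0, 1000.0)
    nb_dispersion_range: tuple[float, float] = (0.05, 0.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.class_proportions is None:
            self.class_proportions = default_class_proportions(self.components)
        labels = LABELS_3 if self.components == 3 else LABELS_5
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-8:
            raise ValidationError(f"class proportions sum to {total}, expected 1")
        for (a, b), prob in self.class_proportions.items():
            if a not in labels or b not in labels:
                raise ValidationError(f"class ({a}, {b}) not in the {self.components}-component vocabulary")
            if prob < 0:
                raise ValidationError("class proportions must be non-negative")
        t = self.target_correlations
        if not (0 <= t["+"] < t.get("++", 1.0) <= 1 and -1 <= t.get("--", -1.0) < t["-"] <= 0):
            raise ValidationError("target correlations must ascend in magnitude from + to ++")
        if t["0"] != 0.0:
            raise ValidationError("the null component's target correlation must be 0")
        lo, hi = self.nb_mu_range
        dlo, dhi = self.nb_dispersion_range
        if not (0 < lo <= hi and 0 < dlo <= dhi):
            raise ValidationError("NB mean and dispersion ranges must be positive")
        if min(self.n1, self.n2) < 4 or self.n_x < 1 or self.n_y < 1:
            raise ValidationError("need >= 4 samples per group and >= 1 feature per set")


@dataclass
class SimulatedStudy:
    """Synthetic counts plus per-pair ground truth."""

    x_counts: CountMatrix
    y_counts: CountMatrix
    groups: GroupAssignment
    truth: list[tuple[str, str]]  # per pair, row-major over (x, y)
    index: PairIndex
    design: SimulationDesign

    def truth_labels(self) -> list[str]:
        return [f"{a}/{b}" for a, b in self.truth]


def _nb_quantile(u: np.ndarray, mu: float, dispersion: float) -> np.ndarray:
    """NB quantile with mean/dispersion parameterisation (var = mu + mu^2 d)."""
    size = 1.0 / dispersion
    prob = size / (size + mu)
    u = np.clip(u, 1e-12, 1.0 - 1e-12)
    return nbinom.ppf(u, size, prob)


def simulate_study(design: SimulationDesign) -> SimulatedStudy:
    """Generate one two-group study from the design (seeded, deterministic).

    For each feature an NB mean and dispersion are drawn uniformly from the
    design ranges.  Latent standard normals carry the planted correlations
    (per group, via each class component's target), and counts are the NB
    quantile transform of their normal CDF values, so marginals are exactly
    negative binomial.
    """
    rng = np.random.default_rng(design.seed)
    nx, ny = design.n_x, design.n_y
    n1, n2 = design.n1, design.n2
    targets = design.target_correlations

    mu_x = rng.uniform(*design.nb_mu_range, nx)
    disp_x = rng.uniform(*design.nb_dispersion_range, nx)
    mu_y = rng.uniform(*design.nb_mu_range, ny)
    disp_y = rng.uniform(*design.nb_dispersion_range, ny)

    classes = list(design.class_proportions.keys())
    probs = np.array([design.class_proportions[c] for c in classes])
    probs = probs / probs.sum()
    y_class = [classes[c] for c in rng.choice(len(classes), size=ny, p=probs)]
    partner = rng.integers(0, nx, size=ny)

    x_blocks, y_blocks = [], []
    for n_g, group_pos in ((n1, 0), (n2, 1)):
        zx = rng.standard_normal((nx, n_g))
        zy = np.empty((ny, n_g))
        for jy in range(ny):
            label = y_class[jy][group_pos]
            rho = targets[label]
            eps = rng.standard_normal(n_g)
            if rho == 0.0:
                zy[jy] = eps
            else:
                zy[jy] = rho * zx[partner[jy]] + np.sqrt(1.0 - rho**2) * eps
        xc = np.empty_like(zx)
        for ix in range(nx):
            xc[ix] = _nb_quantile(norm.cdf(zx[ix]), mu_x[ix], disp_x[ix])
        yc = np.empty_like(zy)
        for jy in range(ny):
            # correlated y inherits its partner's mean, keeps its own dispersion
            planted = y_class[jy] != ("0", "0")
            mu = mu_x[partner[jy]] if planted else mu_y[jy]
            yc[jy] = _nb_quantile(norm.cdf(zy[jy]), mu, disp_y[jy])
        x_blocks.append(xc)
        y_blocks.append(yc)

    sample_ids = [f"s{i + 1}" for i in range(n1 + n2)]
    groups = GroupAssignment(np.array([1] * n1 + [2] * n2))
    x_counts = CountMatrix(
        np.hstack(x_blocks), [f"x{i + 1}" for i in range(nx)], sample_ids, "counts"
    )
    y_counts = CountMatrix(
        np.hstack(y_blocks), [f"y{j + 1}" for j in range(ny)], sample_ids, "counts"
    )

    index = enumerate_pairs(nx, ny)
    truth: list[tuple[str, str]] = []
    for ix, jy in index.pairs:
        if jy < ny and partner[jy] == ix and y_class[jy] != ("0", "0"):
            truth.append(y_class[jy])
        else:
            truth.append(("0", "0"))
    return SimulatedStudy(x_counts, y_counts, groups, truth, index, design)
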