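"""Input handling and outlier screening for feature-by-sample count matrices.

Sequencing data remain strongly right-skewed even after normalisation: most
values sit near zero with a long upper tail, so a single extreme library can
dominate a feature's correlations.  The screen implemented here splits each
feature's values at its median, measures how far the most extreme value on
each side lies in units of that side's own median absolute deviation (MAD),
and flags the feature when that distance exceeds a threshold.  Empirically
useful thresholds for sequencing data are much larger than the classical
2-3 MAD rule: 7 for variance-stabilised (log-like) data and 20 for raw
counts, both exposed as configuration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import EmptyResultError, FormatError, ParseError, ValidationError

#: Default MAD-distance threshold for variance-stabilised (continuous) data.
DEFAULT_THRESHOLD_TRANSFORMED = 7.0
#: Default MAD-distance threshold for raw counts (heavier tails).
DEFAULT_THRESHOLD_COUNTS = 20.0

_DELIMITERS = {".tsv": "\t", ".txt": "\t", ".csv": ","}


@dataclass
class CountMatrix:
    """A feature-by-sample matrix of counts or transformed intensities.

    Parameters
    ----------
    values
        2-D array, one row per feature, one column per sample.
    feature_ids, sample_ids
        Unique row / column identifiers.
    mode
        ``"counts"`` (non-negative values required) or ``"transformed"``
        (any finite values, e.g. log-CPM).
    """

    values: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]
    mode: str = "counts"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.values.ndim != 2:
            raise FormatError("matrix values must be 2-dimensional")
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise FormatError(
                f"shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise FormatError("duplicate feature identifiers")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise FormatError("duplicate sample identifiers")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("matrix contains non-finite values")
        if self.mode not in ("counts", "transformed"):
            raise ValidationError(f"unknown mode {self.mode!r}")
        if self.mode == "counts" and np.any(self.values < 0):
            raise ValidationError("negative value in count-mode matrix")

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)

    def subset_features(self, keep: np.ndarray) -> "CountMatrix":
        keep = np.asarray(keep)
        ids = [self.feature_ids[i] for i in np.flatnonzero(keep)] if keep.dtype == bool \
            else [self.feature_ids[i] for i in keep]
        return CountMatrix(self.values[keep], ids, list(self.sample_ids), self.mode)

    def subset_samples(self, keep: np.ndarray) -> "CountMatrix":
        keep = np.asarray(keep)
        ids = [self.sample_ids[i] for i in np.flatnonzero(keep)] if keep.dtype == bool \
            else [self.sample_ids[i] for i in keep]
        return CountMatrix(self.values[:, keep], list(self.feature_ids), ids, self.mode)


@dataclass
class GroupAssignment:
    """Per-sample labels splitting the samples into groups 1 and 2."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        bad = set(np.unique(self.labels)) - {1, 2}
        if bad:
            raise ValidationError(f"group labels must be 1 or 2, found {sorted(bad)}")
        # n - 3 > 0 is needed for a defined Fisher-z variance in each group
        if self.n1 < 4 or self.n2 < 4:
            raise ValidationError("each group needs at least 4 samples")

    @property
    def mask1(self) -> np.ndarray:
        return self.labels == 1

    @property
    def mask2(self) -> np.ndarray:
        return self.labels == 2

    @property
    def n1(self) -> int:
        return int(np.sum(self.labels == 1))

    @property
    def n2(self) -> int:
        return int(np.sum(self.labels == 2))


@dataclass
class OutlierReport:
    """Result of the MAD outlier screen."""

    feature_scores: np.ndarray
    flagged: np.ndarray
    threshold: float
    feature_ids: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"score": self.feature_scores, "flagged": self.flagged},
            index=self.feature_ids or None,
        )


def _detect_delimiter(path: str | Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return _DELIMITERS.get(Path(path).suffix.lower(), "\t")


def read_count_matrix(
    path: str | Path, delimiter: str | None = None, mode: str = "counts"
) -> CountMatrix:
    """Read a feature-by-sample matrix from a delimited text file.

    The first row holds sample ids, the first column feature ids.  The
    delimiter is inferred from the extension (``.tsv``/``.txt`` tab,
    ``.csv`` comma) unless given explicitly.  Row and column order are
    preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = _detect_delimiter(path, delimiter)
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"duplicate feature id(s): {dupes}")
    if pd.Index(df.columns).duplicated().any():
        raise FormatError("duplicate sample ids in header")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any() or numeric.isna().to_numpy().any():
        isna = numeric.isna().to_numpy()
        i, j = np.argwhere(isna)[0]
        raise ParseError(
            f"non-numeric cell at feature {df.index[i]!r}, sample {df.columns[j]!r}: "
            f"{df.iat[i, j]!r}"
        )
    try:
        return CountMatrix(numeric.to_numpy(float), list(df.index), list(df.columns), mode)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_count_matrix(matrix: CountMatrix, path: str | Path, delimiter: str | None = None) -> None:
    sep = _detect_delimiter(path, delimiter)
    matrix.to_frame().to_csv(path, sep=sep, index_label="feature")


def read_groups(path: str | Path, sample_ids: list[str] | None = None) -> GroupAssignment:
    """Read a two-column (sample id, group in {1,2}) table, header optional.

    If ``sample_ids`` is given the labels are reordered to match it.
    """
    df = pd.read_csv(path, sep=None, engine="python", header=None, dtype=str)
    if df.shape[1] < 2:
        raise FormatError("group file needs two columns: sample_id, group")
    try:
        int(df.iloc[0, 1])
    except ValueError:
        df = df.iloc[1:]
    ids = df.iloc[:, 0].astype(str).tolist()
    try:
        labels = df.iloc[:, 1].astype(int).to_numpy()
    except ValueError as exc:
        raise ParseError(f"group column not integer: {exc}") from exc
    if sample_ids is not None:
        mapping = dict(zip(ids, labels))
        missing = [s for s in sample_ids if s not in mapping]
        if missing:
            raise ValidationError(f"samples missing from group file: {missing[:5]}")
        labels = np.array([mapping[s] for s in sample_ids])
    return GroupAssignment(labels)


def mad_outlier_scores(matrix: CountMatrix) -> np.ndarray:
    """Per-feature maximum MAD-distance from the feature median.

    For each feature the values are split into the set strictly below the
    feature median and the set strictly above it (ties with the median
    contribute a distance of zero).  Each side's spread is its own unscaled
    MAD — the median of absolute deviations from the side's median.  The
    score is the largest ``|x - median| / MAD_side`` over both sides.

    Degenerate cases: a side with fewer than 2 values contributes 0 (its MAD
    is undefined); a side whose MAD is 0 yields an infinite score, since any
    value on a strict side differs from the feature median and a point
    infinitely many MADs out is the canonical outlier.
    """
    if matrix.n_samples < 4:
        raise ValidationError("MAD outlier scoring needs at least 4 samples per feature")
    scores = np.zeros(matrix.n_features)
    for k, row in enumerate(matrix.values):
        m = np.median(row)
        best = 0.0
        for side in (row[row < m], row[row > m]):
            if side.size < 2:
                continue
            mad = np.median(np.abs(side - np.median(side)))
            dev = float(np.max(np.abs(side - m)))
            if mad == 0.0:
                best = np.inf  # strict side => dev > 0 by construction
            else:
                best = max(best, dev / mad)
        scores[k] = best
    return scores


def filter_outliers(
    matrix: CountMatrix, threshold: float | None = None
) -> tuple[CountMatrix, OutlierReport]:
    """Drop features whose MAD outlier score exceeds ``threshold``.

    Default thresholds are 7 for transformed matrices and 20 for raw counts.
    """
    if threshold is None:
        threshold = (
            DEFAULT_THRESHOLD_COUNTS if matrix.mode == "counts" else DEFAULT_THRESHOLD_TRANSFORMED
        )
    if threshold <= 0:
        raise ValidationError("threshold must be positive")
    scores = mad_outlier_scores(matrix)
    flagged = scores > threshold
    report = OutlierReport(scores, flagged, float(threshold), list(matrix.feature_ids))
    if flagged.all():
        raise EmptyResultError(
            f"all {matrix.n_features} features flagged at threshold {threshold}; "
            "consider a higher threshold"
        )
    return matrix.subset_features(~flagged), report


def log_cpm_transform(matrix: CountMatrix, pseudocount: float = 0.5) -> CountMatrix:
    """log2 counts-per-million: ``log2((count + pseudocount) / libsize * 1e6)``.

    A light-weight variance-stabilising transform for metrics that expect
    continuous data (Pearson, biweight midcorrelation).
    """
    if matrix.mode != "counts":
        warnings.warn("log_cpm_transform applied to a matrix not in count mode")
    if pseudocount <= 0:
        raise ValidationError("pseudocount must be positive")
    libsize = matrix.values.sum(axis=0)
    zero = np.flatnonzero(libsize == 0)
    if zero.size:
        raise ValidationError(f"zero library size for sample {matrix.sample_ids[zero[0]]!r}")
    transformed = np.log2((matrix.values + pseudocount) / libsize * 1e6)
    return CountMatrix(transformed, list(matrix.feature_ids), list(matrix.sample_ids), "transformed")
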