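"""Dataset reading/writing, feature normalization, PCA variants and the
synthetic physiological-pattern generator.

The on-disk format is an 8-column CSV, one row per sample, in presentation
order: user number; five physiological features (pulse rate, skin
conductance level, skin conductance response, respiration rate, skin
temperature); the supervision label; and the difficulty level of the
activity the sample was recorded under.  The reference shape is 7 users x 15
samples = 105 rows over 3 classes.

The generator emulates that shape: per user, a baseline offset (inter-
subject variability) plus, per class, Gaussian scatter around a class centre
in [0, 1]^F.  Class centres follow the expected physiological direction of
increasing stress — pulse, skin conductance and respiration rise, skin
temperature falls.  Label noise is applied with a nested construction: one
uniform draw and one alternative label are fixed per sample, and a sample's
label is flipped whenever its draw falls below the noise probability, so the
set of flipped samples grows monotonically with the noise level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Hashable, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .core import InputPattern

__all__ = [
    "FEATURE_COLUMNS",
    "RawDataset",
    "FormatError",
    "read_dataset",
    "write_dataset",
    "MinMaxStats",
    "normalize",
    "PcaBasis",
    "pca_reduce",
    "SyntheticSpec",
    "generate_synthetic",
]

FEATURE_COLUMNS = [
    "pulse_rate",
    "scl",
    "scr",
    "respiration_rate",
    "skin_temperature",
]
COLUMNS = ["user"] + FEATURE_COLUMNS + ["label", "difficulty"]


class FormatError(ValueError):
    """The CSV does not match the expected 8-column layout."""


@dataclass
class RawDataset:
    """Tabular samples in file order (file order = presentation order)."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.frame.columns) != COLUMNS:
            raise FormatError(
                f"expected columns {COLUMNS}, got {list(self.frame.columns)}"
            )
        if len(self.frame) == 0:
            raise FormatError("empty dataset")

    @property
    def n_samples(self) -> int:
        return len(self.frame)

    @property
    def n_users(self) -> int:
        return self.frame["user"].nunique()

    @property
    def class_labels(self) -> list:
        seen: list = []
        for lab in self.frame["label"]:
            if lab not in seen:
                seen.append(lab)
        return seen

    def features(self) -> np.ndarray:
        return self.frame[FEATURE_COLUMNS].to_numpy(dtype=float)

    def labels(self) -> list:
        return list(self.frame["label"])


def read_dataset(path) -> RawDataset:
    """Read an 8-column CSV (optional header) preserving row order."""
    try:
        head = pd.read_csv(path, header=None, nrows=1)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty dataset") from None
    if head.shape[1] != len(COLUMNS):
        raise FormatError(
            f"{path}: expected {len(COLUMNS)} columns, found {head.shape[1]} in row 1"
        )
    # header row detection: feature cells must be numeric in a data row
    has_header = False
    try:
        head.iloc[0, 1:6].astype(float)
    except (ValueError, TypeError):
        has_header = True
    frame = pd.read_csv(path, header=0 if has_header else None)
    frame.columns = COLUMNS
    feats = frame[FEATURE_COLUMNS]
    try:
        feats = feats.astype(float)
    except (ValueError, TypeError) as exc:
        bad = feats.apply(pd.to_numeric, errors="coerce").isna().any(axis=1)
        row = int(np.flatnonzero(bad.to_numpy())[0]) + 1
        raise FormatError(f"{path}: non-numeric feature value in data row {row}") from exc
    if not np.all(np.isfinite(feats.to_numpy())):
        raise FormatError(f"{path}: non-finite feature value")
    frame[FEATURE_COLUMNS] = feats
    frame["user"] = frame["user"].astype(int)
    return RawDataset(frame.reset_index(drop=True))


def write_dataset(dataset: RawDataset, path, header: bool = False) -> None:
    """Write the dataset back as CSV; lossless round-trip with read_dataset."""
    dataset.frame.to_csv(path, index=False, header=header)


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

@dataclass
class MinMaxStats:
    """Per-feature minima and maxima fitted on a training split."""

    mins: np.ndarray
    maxs: np.ndarray

    def to_dict(self) -> dict:
        return {"mins": self.mins.tolist(), "maxs": self.maxs.tolist()}

    @classmethod
    def from_dict(cls, data: dict) -> "MinMaxStats":
        return cls(np.asarray(data["mins"], float), np.asarray(data["maxs"], float))


def _minmax_transform(X: np.ndarray, stats: MinMaxStats) -> np.ndarray:
    span = stats.maxs - stats.mins
    constant = span == 0
    if np.any(constant):
        warnings.warn(
            "constant feature(s) during normalization; mapped to 0.5", stacklevel=3
        )
    safe = np.where(constant, 1.0, span)
    scaled = (X - stats.mins) / safe
    scaled = np.where(constant, 0.5, scaled)
    return np.clip(scaled, 0.0, 1.0)


def normalize(
    dataset: RawDataset, stats: MinMaxStats | None = None
) -> tuple[list[InputPattern], MinMaxStats]:
    """Min–max scale features to [0, 1] and wrap rows as input patterns.

    When ``stats`` is None they are fitted on this dataset; otherwise the
    given (training-split) statistics are applied and out-of-range values
    are clipped into [0, 1].  A constant feature maps to 0.5 with a warning.
    """
    X = dataset.features()
    if stats is None:
        stats = MinMaxStats(mins=X.min(axis=0), maxs=X.max(axis=0))
    scaled = _minmax_transform(X, stats)
    patterns = [
        InputPattern(
            features=scaled[k],
            label=dataset.frame["label"].iloc[k],
            user_id=int(dataset.frame["user"].iloc[k]),
            sample_index=k,
        )
        for k in range(len(scaled))
    ]
    return patterns, stats


# ---------------------------------------------------------------------------
# PCA variants
# ---------------------------------------------------------------------------

@dataclass
class PcaBasis:
    """Fitted PCA projection plus per-component [0, 1] rescaling."""

    mean: np.ndarray
    components: np.ndarray  # (n_components, F)
    explained_variance: np.ndarray
    score_stats: MinMaxStats

    @property
    def n_components(self) -> int:
        return self.components.shape[0]

    def transform(self, X: np.ndarray) -> np.ndarray:
        scores = (X - self.mean) @ self.components.T
        return _minmax_transform(scores, self.score_stats)


def pca_reduce(
    patterns: Sequence[InputPattern],
    n_components: int,
    basis: PcaBasis | None = None,
) -> tuple[list[InputPattern], PcaBasis]:
    """Project patterns onto the top principal axes, rescaled to [0, 1].

    The basis (mean, axes and per-component score range) is fitted on the
    given patterns when ``basis`` is None, otherwise the supplied
    (training-split) basis is applied — scores outside the training range
    are clipped, as the classifier's membership geometry needs a bounded
    domain.  ``n_components = F`` keeps an invertible orthogonal transform
    (up to the rescaling).
    """
    X = np.vstack([p.features for p in patterns])
    F = X.shape[1]
    if not 1 <= n_components <= F:
        raise ValueError(f"n_components must be in [1, {F}], got {n_components}")
    if basis is None:
        pca = PCA(n_components=n_components)
        scores = pca.fit_transform(X)
        stats = MinMaxStats(mins=scores.min(axis=0), maxs=scores.max(axis=0))
        basis = PcaBasis(
            mean=pca.mean_,
            components=pca.components_,
            explained_variance=pca.explained_variance_,
            score_stats=stats,
        )
    elif basis.n_components != n_components:
        raise ValueError("supplied basis has a different number of components")
    scaled = basis.transform(X)
    reduced = [
        InputPattern(scaled[k], p.label, p.user_id, p.sample_index)
        for k, p in enumerate(patterns)
    ]
    return reduced, basis


# ---------------------------------------------------------------------------
# synthetic generator
# ---------------------------------------------------------------------------

def _default_centers(n_classes: int, n_features: int) -> np.ndarray:
    """Class centres along the physiological stress axis.

    For the reference 3-class / 5-feature case: pulse, SCL, SCR and
    respiration increase from relax to stress while skin temperature
    decreases.  Other shapes are spread evenly along the same kind of axis
    (last feature reversed) so pairwise separation stays comparable.
    """
    if n_classes == 3 and n_features == 5:
        return np.array(
            [
                [0.30, 0.25, 0.20, 0.30, 0.70],  # relax
                [0.50, 0.50, 0.45, 0.50, 0.50],  # medium
                [0.75, 0.75, 0.70, 0.70, 0.30],  # stress
            ]
        )
    levels = np.linspace(0.2, 0.8, n_classes)
    centers = np.tile(levels[:, None], (1, n_features))
    centers[:, -1] = levels[::-1]
    return centers


_LABELS_3 = ["relax", "medium", "stress"]


@dataclass
class SyntheticSpec:
    """Conditions for the synthetic physiological-pattern generator.

    Defaults mirror the reference study shape: 7 users x 3 classes x 5
    samples per class (K = 105, 15 per user), 5 features in [0, 1].
    ``spread`` is the per-feature sample standard deviation within a class;
    ``user_spread`` the standard deviation of a per-user baseline offset
    shared by all of that user's samples; ``label_noise`` the probability a
    sample's supervision label is replaced by a different class.
    """

    n_users: int = 7
    samples_per_user_per_class: int = 5
    n_features: int = 5
    n_classes: int = 3
    class_centers: np.ndarray | None = None
    spread: float = 0.1
    user_spread: float = 0.05
    label_noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 1 or self.n_features < 1:
            raise ValueError("n_classes and n_features must be >= 1")
        if self.n_users < 1 or self.samples_per_user_per_class < 1:
            raise ValueError("n_users and samples_per_user_per_class must be >= 1")
        if not 0.0 <= self.label_noise <= 1.0:
            raise ValueError("label_noise must lie in [0, 1]")
        if self.spread < 0 or self.user_spread < 0:
            raise ValueError("spreads must be non-negative")
        if self.class_centers is None:
            self.class_centers = _default_centers(self.n_classes, self.n_features)
        else:
            self.class_centers = np.asarray(self.class_centers, dtype=float)
            if self.class_centers.shape != (self.n_classes, self.n_features):
                raise ValueError("class_centers must have shape (n_classes, n_features)")

    @property
    def class_names(self) -> list[str]:
        if self.n_classes == 3:
            return list(_LABELS_3)
        return [f"class{k}" for k in range(self.n_classes)]

    def min_center_gap(self) -> float:
        """Smallest pairwise Euclidean distance between class centres."""
        c = self.class_centers
        gaps = [
            float(np.linalg.norm(c[i] - c[j]))
            for i in range(len(c))
            for j in range(i + 1, len(c))
        ]
        return min(gaps) if gaps else np.inf


def generate_synthetic(spec: SyntheticSpec) -> RawDataset:
    """Draw an S1-shaped synthetic dataset; fully reproducible from the seed.

    Rows are ordered user by user and, within a user, class block by class
    block (the protocol's activity order), matching how such recordings
    arrive in time.
    """
    rng = np.random.default_rng(spec.seed)
    names = spec.class_names
    rows = []
    true_classes = []
    for user in range(1, spec.n_users + 1):
        offset = rng.normal(0.0, spec.user_spread, size=spec.n_features)
        for k in range(spec.n_classes):
            for _ in range(spec.samples_per_user_per_class):
                x = spec.class_centers[k] + offset + rng.normal(
                    0.0, spec.spread, size=spec.n_features
                )
                rows.append([user, *np.clip(x, 0.0, 1.0)])
                true_classes.append(k)
    n = len(rows)
    # nested label noise: fixed draws, flip set grows with the noise level
    u = rng.uniform(size=n)
    alt_shift = rng.integers(1, max(spec.n_classes, 2), size=n)
    labels = []
    for i, k in enumerate(true_classes):
        if spec.n_classes > 1 and u[i] < spec.label_noise:
            k = (k + int(alt_shift[i])) % spec.n_classes
        labels.append(names[k])
    frame = pd.DataFrame(rows, columns=["user"] + FEATURE_COLUMNS)
    frame["user"] = frame["user"].astype(int)
    frame["label"] = labels
    frame["difficulty"] = [names[k] for k in true_classes]
    return RawDataset(frame)
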