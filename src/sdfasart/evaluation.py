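"""Evaluation protocol: leave-one-out cross-validation, the A_R–sigma grid
sweep and the category-proliferation study.

LOOCV builds K models, each trained on K−1 samples in their original
presentation order with the held-out sample removed, and scores the held-out
prediction; the success percentage is the arithmetic mean over folds.  When
the input is a raw dataset, per-feature min–max normalization (and the
optional PCA basis) is re-fitted inside every fold on the K−1 training
samples only, so no test information leaks into the preprocessing.

The sweep repeats LOOCV over a grid of (A_R, sigma) pairs with every other
parameter held at its default; the default reconstructed grid pairs 106 A_R
values (0.05 to 2.15 in steps of 0.02) with 105 log-spaced sigma values on
[1e-4, 1], i.e. 11130 configurations.  The proliferation study fits one
model per A_R on the full sample set and records how many categories it
commits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Sequence

import numpy as np
import pandas as pd

from .core import InputPattern
from .data_io import RawDataset, normalize, pca_reduce
from .params import NetworkParams
from .training import fit_new, predict

__all__ = [
    "FoldRecord",
    "LoocvResult",
    "SweepResult",
    "SweepReport",
    "ProliferationResult",
    "InsufficientDataError",
    "loocv",
    "sweep",
    "proliferation_study",
    "confusion_and_accuracy",
    "default_grids",
    "sweep_to_csv",
]


class InsufficientDataError(ValueError):
    """Fewer samples than the protocol requires."""


@dataclass
class FoldRecord:
    """Outcome of one LOOCV fold."""

    held_out_index: int
    true_label: Hashable
    predicted_label: Hashable
    n_categories: int
    correct: bool


@dataclass
class LoocvResult:
    success_pct: float
    folds: list[FoldRecord]

    @property
    def category_count_min(self) -> int:
        return min(f.n_categories for f in self.folds)

    @property
    def category_count_max(self) -> int:
        return max(f.n_categories for f in self.folds)


@dataclass
class SweepResult:
    """One grid point: configuration, success and per-fold category range."""

    a_r: float
    sigma: float
    success_pct: float
    category_count_min: int
    category_count_max: int


@dataclass
class SweepReport:
    results: list[SweepResult]
    best: SweepResult

    def above(self, threshold_pct: float) -> list[SweepResult]:
        """Grid points whose success exceeds the threshold (surface plot set)."""
        return [r for r in self.results if r.success_pct > threshold_pct]


@dataclass
class ProliferationResult:
    counts: list[tuple[float, int]]  # (a_r, n_categories)

    def band_interval(self, lo: int, hi: int) -> tuple[float, float] | None:
        """Range of A_R values whose category counts fall inside [lo, hi]."""
        inside = [a for a, n in self.counts if lo <= n <= hi]
        if not inside:
            return None
        return (min(inside), max(inside))


def _fold_patterns(
    dataset: Sequence[InputPattern] | RawDataset,
    held_out: int,
    n_components: int | None,
) -> tuple[list[InputPattern], InputPattern]:
    """Training patterns (order preserved, one removed) and the test pattern,
    with all preprocessing fitted on the training part only."""
    if isinstance(dataset, RawDataset):
        train_raw = RawDataset(
            dataset.frame.drop(index=dataset.frame.index[held_out]).reset_index(
                drop=True
            )
        )
        test_raw = RawDataset(
            dataset.frame.iloc[[held_out]].reset_index(drop=True)
        )
        train, stats = normalize(train_raw)
        test, _ = normalize(test_raw, stats)
    else:
        patterns = list(dataset)
        train = patterns[:held_out] + patterns[held_out + 1 :]
        test = [patterns[held_out]]
    if n_components is not None:
        train, basis = pca_reduce(train, n_components)
        test, _ = pca_reduce(test, n_components, basis)
    return train, test[0]


def _dataset_length(dataset: Sequence[InputPattern] | RawDataset) -> int:
    return dataset.n_samples if isinstance(dataset, RawDataset) else len(dataset)


def _labels_present(dataset: Sequence[InputPattern] | RawDataset) -> bool:
    if isinstance(dataset, RawDataset):
        return not dataset.frame["label"].isna().any()
    return all(p.label is not None for p in dataset)


def loocv(
    dataset: Sequence[InputPattern] | RawDataset,
    params: NetworkParams | None = None,
    n_components: int | None = None,
) -> LoocvResult:
    """Leave-one-out cross-validation of the classifier on a labeled dataset.

    Accepts either ready patterns (already in [0, 1]) or a raw dataset, in
    which case min–max normalization — and PCA when ``n_components`` is set —
    is refitted per fold on the training samples.
    """
    K = _dataset_length(dataset)
    if K < 2:
        raise InsufficientDataError(f"LOOCV needs at least 2 samples, got {K}")
    if not _labels_present(dataset):
        raise ValueError("all samples must carry a supervision label")
    params = params if params is not None else NetworkParams()
    folds: list[FoldRecord] = []
    for k in range(K):
        train, test = _fold_patterns(dataset, k, n_components)
        model = fit_new(train, params)
        pred = predict(model, InputPattern(test.features))
        folds.append(
            FoldRecord(
                held_out_index=k,
                true_label=test.label,
                predicted_label=pred,
                n_categories=model.n_categories,
                correct=pred == test.label,
            )
        )
    success = 100.0 * sum(f.correct for f in folds) / K
    return LoocvResult(success_pct=success, folds=folds)


def sweep(
    dataset: Sequence[InputPattern] | RawDataset,
    a_r_grid: Sequence[float],
    sigma_grid: Sequence[float],
    params: NetworkParams | None = None,
    n_components: int | None = None,
) -> SweepReport:
    """LOOCV at every (A_R, sigma) grid point, other parameters fixed.

    The best configuration is the argmax of the success percentage; exact
    ties resolve to the lowest A_R, then the lowest sigma.
    """
    if len(a_r_grid) == 0 or len(sigma_grid) == 0:
        raise ValueError("grids must be non-empty")
    if any(v <= 0 for v in a_r_grid) or any(v <= 0 for v in sigma_grid):
        raise ValueError("grid values must be positive")
    params = params if params is not None else NetworkParams()
    results: list[SweepResult] = []
    best: SweepResult | None = None
    for a_r in sorted(a_r_grid):
        for sig in sorted(sigma_grid):
            res = loocv(dataset, params.replace(a_r=a_r, sigma=sig), n_components)
            row = SweepResult(
                a_r=float(a_r),
                sigma=float(sig),
                success_pct=res.success_pct,
                category_count_min=res.category_count_min,
                category_count_max=res.category_count_max,
            )
            results.append(row)
            if best is None or row.success_pct > best.success_pct:
                best = row
    return SweepReport(results=results, best=best)


def proliferation_study(
    dataset: Sequence[InputPattern] | RawDataset,
    a_r_grid: Sequence[float],
    params: NetworkParams | None = None,
) -> ProliferationResult:
    """Category counts of one full fit per A_R value (defaults elsewhere).

    Used to pick an A_R range that keeps the category count reasonable for
    the sample size before running the sweep.
    """
    if len(a_r_grid) == 0:
        raise ValueError("a_r_grid must be non-empty")
    if any(not 0 < a <= 20 for a in a_r_grid):
        raise ValueError("a_r_grid values must lie in (0, 20]")
    params = params if params is not None else NetworkParams()
    if isinstance(dataset, RawDataset):
        patterns, _ = normalize(dataset)
    else:
        patterns = list(dataset)
    counts = []
    for a_r in a_r_grid:
        model = fit_new(patterns, params.replace(a_r=a_r))
        counts.append((float(a_r), model.n_categories))
    return ProliferationResult(counts=counts)


def confusion_and_accuracy(
    y_true: Sequence[Hashable], y_pred: Sequence[Hashable]
) -> tuple[pd.DataFrame, float]:
    """Confusion table (rows = true, cols = predicted) and accuracy in %."""
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred must have equal length")
    labels = sorted(set(y_true) | set(y_pred), key=str)
    table = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
    for t, p in zip(y_true, y_pred):
        table.loc[t, p] += 1
    accuracy = 100.0 * np.trace(table.to_numpy()) / max(len(y_true), 1)
    return table, accuracy


def default_grids() -> tuple[np.ndarray, np.ndarray]:
    """The default reconstructed sweep grid: 106 A_R x 105 sigma values.

    A_R runs from 0.05 to 2.15 in steps of 0.02; sigma is log-spaced over
    [1e-4, 1] (the reported best sigmas cluster near the low end, so a log
    grid covers that region densely).
    """
    a_r = np.round(np.arange(0.05, 2.15 + 1e-12, 0.02), 10)
    sigma = np.logspace(-4.0, 0.0, 105)
    return a_r, sigma


def sweep_to_csv(report: SweepReport | Sequence[SweepResult], path) -> None:
    results = report.results if isinstance(report, SweepReport) else list(report)
    frame = pd.DataFrame(
        [
            {
                "a_r": r.a_r,
                "sigma": r.sigma,
                "success_pct": r.success_pct,
                "cat_min": r.category_count_min,
                "cat_max": r.category_count_max,
            }
            for r in results
        ]
    )
    frame.to_csv(path, index=False)
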