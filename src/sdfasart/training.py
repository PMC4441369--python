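"""Supervised one-pass learning loop and prediction.

Training presents each labeled sample exactly once, in order.  For a sample,
every category's equilibrium activation and reset level are computed; the
search loop then repeatedly takes the most active non-disabled category and

* resets it (temporary disable) if its reset level reaches the vigilance
  threshold,
* match-tracks if its label disagrees with the supervision label — vigilance
  is set to the offender's reset level, the offender is disabled and the
  search continues among strictly more similar categories,
* otherwise resonates: the winner learns the sample by slow recode.

If no category exists, none is eligible, or the maximum activation is null,
a new point category is fast-committed.  Vigilance returns to baseline and
disables are cleared before the next sample, so match tracking is strictly
per-sample.

Prediction recomputes activations only (no vigilance, no learning) and
returns the winner's label; a rejection-free fallback handles probes outside
every category's support.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Iterable, Sequence

import numpy as np

from .core import (
    InputPattern,
    NotFittedError,
    SdFasArtModel,
    ShapeError,
    SupervisionRequiredError,
    _category_size_arrays,
    _eta_product,
    fallback_membership,
    fast_commit,
    reset_level,
)
from .params import NetworkParams

__all__ = ["TrainEvent", "train_step", "fit", "fit_new", "predict", "predict_batch"]


@dataclass
class TrainEvent:
    """Audit record of one branch taken while processing one sample."""

    sample_index: int
    event: str  # commit | recode | reset | match_track
    category_index: int
    vigilance_at_event: float


def train_step(model: SdFasArtModel, pattern: InputPattern) -> list[TrainEvent]:
    """Present one labeled pattern; mutate the model; return the event trail.

    Exactly one terminal event (commit or recode) is produced per sample,
    possibly preceded by reset and match-track events.
    """
    if pattern.label is None:
        raise SupervisionRequiredError("training requires labeled patterns")
    if model.n_features is not None and pattern.n_features != model.n_features:
        raise ShapeError(
            f"pattern has {pattern.n_features} features, model expects {model.n_features}"
        )
    idx = pattern.sample_index if pattern.sample_index is not None else -1
    events: list[TrainEvent] = []
    params = model.params
    vigilance = params.vigilance

    if model.n_categories == 0:
        fast_commit(pattern, model)
        events.append(TrainEvent(idx, "commit", model.n_categories - 1, vigilance))
        return events

    W, C, V = model.weight_arrays()
    cat_labels = model.category_labels()
    p = _eta_product(pattern.features, W, C, V, params.sigma)
    T = params.b_t / params.a_t * p
    d = _category_size_arrays(pattern.features, W, C, V, params.epsilon)
    R = np.asarray(reset_level(d, params))

    enabled = np.ones(model.n_categories, dtype=bool)
    while True:
        T_masked = np.where(enabled, T, 0.0)
        J = int(np.argmax(T_masked))
        if not enabled.any() or T_masked[J] <= params.alpha:
            fast_commit(pattern, model)
            events.append(TrainEvent(idx, "commit", model.n_categories - 1, vigilance))
            return events
        if R[J] >= vigilance:
            events.append(TrainEvent(idx, "reset", J, vigilance))
            enabled[J] = False
            continue
        if cat_labels[J] != pattern.label:
            vigilance = float(R[J])
            events.append(TrainEvent(idx, "match_track", J, vigilance))
            enabled[J] = False
            continue
        model._recode_in_place(J, pattern.features)
        events.append(TrainEvent(idx, "recode", J, vigilance))
        return events


def fit(
    model: SdFasArtModel,
    dataset: Sequence[InputPattern],
    record_events: bool = False,
) -> SdFasArtModel | tuple[SdFasArtModel, list[TrainEvent]]:
    """Single supervised pass over the dataset in the given order.

    Deterministic: the same ordered dataset always yields the same model.
    Category structure is order-sensitive, as in all ART-family learners.
    """
    events: list[TrainEvent] = []
    for k, pattern in enumerate(dataset):
        if pattern.sample_index is None:
            pattern = InputPattern(
                pattern.features, pattern.label, pattern.user_id, k
            )
        ev = train_step(model, pattern)
        if record_events:
            events.extend(ev)
    if record_events:
        return model, events
    return model


def fit_new(
    dataset: Sequence[InputPattern], params: NetworkParams | None = None
) -> SdFasArtModel:
    """Convenience: build a fresh model and fit it on the dataset."""
    model = SdFasArtModel(params=params)
    fit(model, dataset)
    return model


def predict(
    model: SdFasArtModel, pattern: InputPattern, strict: bool = False
) -> Hashable | None:
    """Classify a pattern: label of the maximally activated category.

    No vigilance testing and no learning happen at test time.  When every
    activation is null (the probe lies outside all sigma-supports), the
    default rejection-free fallback scores each category by the product of
    memberships with flanks extended to the domain boundary, breaking exact
    score ties by proximity to the category centre and then by age.  With
    ``strict=True`` such probes return None instead.
    """
    if model.n_categories == 0:
        raise NotFittedError("model has no categories; fit it first")
    if pattern.n_features != model.n_features:
        raise ShapeError("pattern dimensionality differs from the model's")
    params = model.params
    W, C, V = model.weight_arrays()
    p = _eta_product(pattern.features, W, C, V, params.sigma)
    T = params.b_t / params.a_t * p
    J = int(np.argmax(T))
    if T[J] > params.alpha:
        return model.category_labels()[J]
    if strict:
        return None
    scores = np.prod(
        np.atleast_2d(fallback_membership(pattern.features, W, V)), axis=1
    )
    best = scores.max()
    candidates = np.flatnonzero(scores == best)
    if candidates.size > 1:
        dist = np.linalg.norm(C[candidates] - pattern.features, axis=1)
        candidates = candidates[np.argsort(dist, kind="stable")]
    return model.category_labels()[int(candidates[0])]


def predict_batch(
    model: SdFasArtModel, patterns: Iterable[InputPattern], strict: bool = False
) -> list[Hashable | None]:
    return [predict(model, pat, strict=strict) for pat in patterns]
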