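"""Core S-dFasArt types and dynamic equations.

The classifier maintains an ordered set of fuzzy categories.  Each category
*j* stores three weight vectors per input feature *i*: a minimum ``W_ji``, a
centre ``C_ji`` and a maximum ``V_ji``.  The interval ``[W, V]`` is the
category's plateau of full membership; linear flanks of width ``sigma``
extend it on each side, so the membership in feature *i* is a trapezoid that
degenerates to a triangle for a freshly committed point category
(``W = C = V``).

Three dynamic laws drive recognition and learning:

* activation ``dT/dt = -A_T*T + B_T * prod_i eta_i`` — the AND (product) of
  the per-feature memberships, low-pass filtered; classification uses its
  equilibrium ``T* = (B_T/A_T) * prod_i eta_i``;
* reset ``R`` grown from the category size
  ``d = sum_i [max(V_i, I_i) - min(W_i, I_i)] / (|2 C_i| + eps)`` — a
  dissimilarity that is 0 exactly when the input sits on a point category;
* learning (slow recode) which moves ``W`` down towards ``min(I, W)``, ``C``
  towards ``I`` and ``V`` up towards ``max(I, V)``.

Scalar operations here accept either a single category (1-D weight vectors)
or a stacked batch (2-D arrays, one row per category); the training loop uses
the batched forms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Sequence

import numpy as np

from .params import NetworkParams

__all__ = [
    "InputPattern",
    "FuzzyCategory",
    "SdFasArtModel",
    "membership",
    "fallback_membership",
    "activation",
    "category_size",
    "reset_level",
    "select_winner",
    "fast_commit",
    "slow_recode",
    "InvalidCategoryError",
    "ShapeError",
    "SupervisionRequiredError",
    "NotFittedError",
]


class InvalidCategoryError(ValueError):
    """Weight ordering W <= C <= V is violated."""


class ShapeError(ValueError):
    """Pattern and category dimensions do not match."""


class SupervisionRequiredError(ValueError):
    """A supervision label is required but absent."""


class NotFittedError(RuntimeError):
    """The model holds no categories yet."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class InputPattern:
    """One sample: a feature vector in [0, 1]^F plus an optional class label.

    ``user_id`` and ``sample_index`` are bookkeeping metadata (subject of
    origin and presentation order); they do not influence the dynamics.
    """

    features: np.ndarray
    label: Hashable | None = None
    user_id: int | None = None
    sample_index: int | None = None

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 1:
            raise ShapeError(f"features must be 1-D, got shape {self.features.shape}")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("features must be finite")
        if np.any(self.features < 0.0) or np.any(self.features > 1.0):
            raise ValueError("features must lie in [0, 1]; normalize first")

    @property
    def n_features(self) -> int:
        return self.features.shape[0]


@dataclass
class FuzzyCategory:
    """One committed category node: weight triple (W, C, V), label, state.

    ``T`` is the current activation, ``R`` the current reset level and
    ``disabled`` marks a temporary disable by the orientation subsystem
    during within-sample search.
    """

    W: np.ndarray
    C: np.ndarray
    V: np.ndarray
    label: Hashable
    T: float = 0.0
    R: float = 0.0
    disabled: bool = False

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.C = np.asarray(self.C, dtype=float)
        self.V = np.asarray(self.V, dtype=float)
        if not (self.W.shape == self.C.shape == self.V.shape) or self.W.ndim != 1:
            raise ShapeError("W, C, V must be 1-D arrays of identical length")
        _check_ordering(self.W, self.C, self.V)

    @property
    def n_features(self) -> int:
        return self.W.shape[0]


def _check_ordering(W: np.ndarray, C: np.ndarray, V: np.ndarray) -> None:
    if np.any(W > C) or np.any(C > V):
        raise InvalidCategoryError("weight ordering W <= C <= V violated")


# ---------------------------------------------------------------------------
# membership
# ---------------------------------------------------------------------------

def membership(x, w, c, v, sigma: float):
    """Trapezoidal fuzzy membership eta(x) of input x in a category interval.

    Equals 1 on the plateau ``[w, v]``, falls linearly to 0 over a flank of
    width ``sigma`` on each side; the support is exactly
    ``[w - sigma, v + sigma]``.  Accepts scalars or broadcastable arrays.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    x = np.asarray(x, dtype=float)
    w = np.asarray(w, dtype=float)
    c = np.asarray(c, dtype=float)
    v = np.asarray(v, dtype=float)
    if np.any(w > c) or np.any(c > v):
        raise InvalidCategoryError("weight ordering w <= c <= v violated")
    left = (x - (w - sigma)) / sigma
    right = ((v + sigma) - x) / sigma
    eta = np.clip(np.minimum(left, right), 0.0, 1.0)
    # the plateau is exact, immune to flank-formula roundoff
    eta = np.where((x >= w) & (x <= v), 1.0, eta)
    if eta.ndim == 0:
        return float(eta)
    return eta


def fallback_membership(x, w, v):
    """Membership with flanks extended to the domain boundaries [0, 1].

    Used only by the rejection-free prediction fallback when a probe lies
    outside every category's sigma-support: the plateau is kept, but the
    flanks reach 0 exactly at the domain edges instead of at ``sigma`` away,
    so every in-domain probe scores positively against any category whose
    plateau does not touch the opposite boundary.
    """
    x = np.asarray(x, dtype=float)
    w = np.asarray(w, dtype=float)
    v = np.asarray(v, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        left = np.where(w > 0, x / np.where(w > 0, w, 1.0), 1.0)
        right = np.where(v < 1, (1.0 - x) / np.where(v < 1, 1.0 - v, 1.0), 1.0)
    eta = np.minimum(np.minimum(left, right), 1.0)
    return np.clip(eta, 0.0, 1.0)


# ---------------------------------------------------------------------------
# activation
# ---------------------------------------------------------------------------

def _eta_product(features: np.ndarray, W, C, V, sigma: float) -> np.ndarray:
    """Product over features of the memberships (AND of fuzzy degrees)."""
    eta = membership(features, W, C, V, sigma)
    return np.prod(np.atleast_2d(eta), axis=1)


def activation(
    pattern: InputPattern,
    cat: FuzzyCategory,
    params: NetworkParams,
    method: str = "equilibrium",
    tol: float = 1e-9,
    max_steps: int = 10_000_000,
) -> float:
    """Activation level T of a category for a pattern.

    ``method="equilibrium"`` (default) returns the fixed point
    ``T* = (B_T / A_T) * prod_i eta_i`` of the activation dynamics.
    ``method="euler"`` integrates ``dT/dt = -A_T*T + B_T*prod_i eta_i`` from
    ``T(0) = 0`` with explicit Euler (step ``params.dt``) until the slope
    magnitude drops below ``tol``; it converges to the same value and serves
    as the streaming mode and as an independent oracle.
    """
    if pattern.n_features != cat.n_features:
        raise ShapeError(
            f"pattern has {pattern.n_features} features, category has {cat.n_features}"
        )
    p = float(_eta_product(pattern.features, cat.W, cat.C, cat.V, params.sigma)[0])
    if method == "equilibrium":
        return params.b_t / params.a_t * p
    if method == "euler":
        T = 0.0
        for _ in range(max_steps):
            slope = -params.a_t * T + params.b_t * p
            T += params.dt * slope
            if abs(slope) < tol:
                break
        return T
    raise ValueError(f"unknown activation method {method!r}")


# ---------------------------------------------------------------------------
# category size and reset
# ---------------------------------------------------------------------------

def category_size(pattern: InputPattern, cat: FuzzyCategory, params: NetworkParams) -> float:
    """Dissimilarity d_reset between a pattern and a category.

    Per feature, ``l_i = max(V_i, I_i) - min(W_i, I_i)`` is the extent the
    category would need to cover the input; the size is
    ``sum_i l_i / (|2 C_i| + eps)``.  Zero exactly when the input coincides
    with a point category.
    """
    if pattern.n_features != cat.n_features:
        raise ShapeError("pattern/category dimension mismatch")
    return float(
        _category_size_arrays(pattern.features, cat.W, cat.C, cat.V, params.epsilon)[0]
    )


def _category_size_arrays(features, W, C, V, epsilon: float) -> np.ndarray:
    W2 = np.atleast_2d(W)
    C2 = np.atleast_2d(C)
    V2 = np.atleast_2d(V)
    l = np.maximum(V2, features) - np.minimum(W2, features)
    return np.sum(l / (np.abs(2.0 * C2) + epsilon), axis=1)


def _integrate_reset_py(d, a_r, b_r, r_max, dt, steps, factored):
    R = np.zeros_like(d)
    for _ in range(steps):
        if factored:
            slope = a_r * (-R + b_r * d) * (r_max - R)
        else:
            slope = (-a_r * R + b_r * d) * (r_max - R)
        R += dt * slope
        np.clip(R, 0.0, r_max, out=R)
    return R


try:  # JIT the hot loop; the numpy path is the reference semantics
    from numba import njit

    @njit(cache=True, fastmath=False)
    def _integrate_reset_jit(d, a_r, b_r, r_max, dt, steps, factored):  # pragma: no cover
        n = d.shape[0]
        R = np.zeros(n)
        for i in range(n):
            r = 0.0
            for _ in range(steps):
                if factored:
                    slope = a_r * (-r + b_r * d[i]) * (r_max - r)
                else:
                    slope = (-a_r * r + b_r * d[i]) * (r_max - r)
                r += dt * slope
                if r < 0.0:
                    r = 0.0
                elif r > r_max:
                    r = r_max
            R[i] = r
        return R

    _integrate_reset = _integrate_reset_jit
except ImportError:  # pragma: no cover
    _integrate_reset = _integrate_reset_py


def reset_level(d_reset, params: NetworkParams):
    """Reset level R reached for a category of size ``d_reset``.

    Three selectable laws (``params.reset_law``), all starting from
    ``R(0) = 0``, all returning 0 for ``d_reset = 0`` and all capped at
    ``R_max``:

    * ``printed_steady_state`` — equilibrium of
      ``dR/dt = (-A_R*R + B_R*d)(R_max - R)``, i.e.
      ``min(B_R*d/A_R, R_max)``;
    * ``printed_finite_horizon`` — explicit Euler of the same equation for
      ``horizon_steps`` steps of ``dt``;
    * ``factored_rate`` (default) — explicit Euler, same horizon, of
      ``dR/dt = A_R * (-R + B_R*d) * (R_max - R)``: here A_R scales the whole
      drive, so a larger A_R yields a larger reset at the horizon and hence
      more category creation.

    Accepts a scalar or an array of sizes; returns the matching shape.
    """
    d = np.asarray(d_reset, dtype=float)
    if np.any(d < 0):
        raise ValueError("d_reset must be non-negative")
    law = params.reset_law
    if law == "printed_steady_state":
        R = np.minimum(params.b_r * d / params.a_r, params.r_max)
    else:
        R = _integrate_reset(
            np.atleast_1d(d).astype(float),
            params.a_r,
            params.b_r,
            params.r_max,
            params.dt,
            params.horizon_steps,
            law == "factored_rate",
        ).reshape(d.shape)
    if R.ndim == 0:
        return float(R)
    return R


# ---------------------------------------------------------------------------
# winner selection, commit, recode
# ---------------------------------------------------------------------------

def select_winner(model: "SdFasArtModel", activations: Sequence[float]) -> int | None:
    """Index of the maximally activated category, or None if all are null.

    Disabled categories must carry activation 0.  Ties break toward the
    lowest index (the oldest category).  Returns None when every activation
    is at or below ``alpha`` — the "maximum activation is null" branch that
    triggers creation of an uncommitted node.
    """
    T = np.asarray(activations, dtype=float)
    if T.size == 0:
        return None
    J = int(np.argmax(T))
    if T[J] <= model.params.alpha:
        return None
    return J


def fast_commit(pattern: InputPattern, model: "SdFasArtModel") -> FuzzyCategory:
    """Commit a new point category encoding the pattern.

    The new node copies the input exactly (``W = C = V = I``), takes the
    supervision label, and starts with ``T = 1``, ``R = 0``.
    """
    if pattern.label is None:
        raise SupervisionRequiredError("fast commit requires a labeled pattern")
    cat = FuzzyCategory(
        W=pattern.features.copy(),
        C=pattern.features.copy(),
        V=pattern.features.copy(),
        label=pattern.label,
        T=1.0,
        R=0.0,
    )
    model._append(cat)
    return cat


def _recode_arrays(features, W, C, V, params: NetworkParams):
    """One discrete slow-recode step; returns new (W, C, V).

    Moves W towards min(I, W), C towards I and V towards max(I, V) at rates
    A_W, A_C, A_V.  With unequal rates a transient can push C past V (or
    below W); ordering is restored by widening the plateau to contain C,
    which leaves the fixed points min(I, W0), I, max(I, V0) untouched.
    """
    I = features
    W2 = W + params.a_w * (np.minimum(I, W) - W)
    C2 = C + params.a_c * (I - C)
    V2 = V + params.a_v * (np.maximum(I, V) - V)
    W2 = np.minimum(W2, C2)
    V2 = np.maximum(V2, C2)
    return W2, C2, V2


def slow_recode(
    pattern: InputPattern, cat: FuzzyCategory, params: NetworkParams
) -> FuzzyCategory:
    """Return the category after one slow-recode learning step on a pattern."""
    if pattern.n_features != cat.n_features:
        raise ShapeError("pattern/category dimension mismatch")
    W, C, V = _recode_arrays(pattern.features, cat.W, cat.C, cat.V, params)
    return FuzzyCategory(W=W, C=C, V=V, label=cat.label, T=cat.T, R=cat.R)


# ---------------------------------------------------------------------------
# the model container
# ---------------------------------------------------------------------------

class SdFasArtModel:
    """Ordered collection of fuzzy categories plus parameters and labels.

    Weight triples are stored row-wise in growable arrays so that the
    training loop can evaluate all categories at once; :attr:`categories`
    materialises the per-node view.
    """

    def __init__(
        self,
        params: NetworkParams | None = None,
        n_features: int | None = None,
        labels: Iterable[Hashable] | None = None,
    ) -> None:
        self.params = params if params is not None else NetworkParams()
        self.n_features = n_features
        self.labels: list[Hashable] = list(labels) if labels is not None else []
        self._n = 0
        self._cap = 0
        self._W = self._C = self._V = None  # type: np.ndarray | None
        self._label_idx = np.empty(0, dtype=int)

    # -- storage ------------------------------------------------------------

    @property
    def n_categories(self) -> int:
        return self._n

    def _ensure_capacity(self, extra: int = 1) -> None:
        need = self._n + extra
        if need <= self._cap:
            return
        new_cap = max(16, 2 * self._cap, need)
        F = self.n_features
        for name in ("_W", "_C", "_V"):
            old = getattr(self, name)
            arr = np.empty((new_cap, F), dtype=float)
            if old is not None:
                arr[: self._n] = old[: self._n]
            setattr(self, name, arr)
        idx = np.empty(new_cap, dtype=int)
        idx[: self._n] = self._label_idx[: self._n]
        self._label_idx = idx
        self._cap = new_cap

    def _append(self, cat: FuzzyCategory) -> None:
        if self.n_features is None:
            self.n_features = cat.n_features
        elif cat.n_features != self.n_features:
            raise ShapeError("category dimensionality differs from the model's")
        if cat.label not in self.labels:
            self.labels.append(cat.label)
        self._ensure_capacity()
        self._W[self._n] = cat.W
        self._C[self._n] = cat.C
        self._V[self._n] = cat.V
        self._label_idx[self._n] = self.labels.index(cat.label)
        self._n += 1

    def weight_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Views of the stacked (W, C, V) arrays, one row per category."""
        if self._n == 0:
            F = self.n_features or 0
            z = np.empty((0, F))
            return z, z.copy(), z.copy()
        return self._W[: self._n], self._C[: self._n], self._V[: self._n]

    def category_labels(self) -> list[Hashable]:
        return [self.labels[i] for i in self._label_idx[: self._n]]

    def category(self, j: int) -> FuzzyCategory:
        if not 0 <= j < self._n:
            raise IndexError(f"category index {j} out of range (N={self._n})")
        return FuzzyCategory(
            W=self._W[j].copy(),
            C=self._C[j].copy(),
            V=self._V[j].copy(),
            label=self.labels[self._label_idx[j]],
        )

    @property
    def categories(self) -> list[FuzzyCategory]:
        return [self.category(j) for j in range(self._n)]

    def _recode_in_place(self, j: int, features: np.ndarray) -> None:
        W, C, V = _recode_arrays(
            features, self._W[j], self._C[j], self._V[j], self.params
        )
        self._W[j], self._C[j], self._V[j] = W, C, V

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "labels": list(self.labels),
            "n_features": self.n_features,
            "categories": [
                {
                    "W": self._W[j].tolist(),
                    "C": self._C[j].tolist(),
                    "V": self._V[j].tolist(),
                    "label": self.labels[self._label_idx[j]],
                }
                for j in range(self._n)
            ],
        }

    @classmethod
    def from_dict(cls, data: dict) -> "SdFasArtModel":
        model = cls(
            params=NetworkParams.from_dict(data["params"]),
            n_features=data["n_features"],
            labels=data["labels"],
        )
        for cat in data["categories"]:
            model._append(
                FuzzyCategory(W=cat["W"], C=cat["C"], V=cat["V"], label=cat["label"])
            )
        return model

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "SdFasArtModel":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))
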