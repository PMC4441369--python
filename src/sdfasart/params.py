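"""Network parameters of the S-dFasArt classifier.

All scalar knobs of the architecture live in :class:`NetworkParams`.  The
defaults are the published operating point of the classifier: slow category
activation (``a_t = 0.01``), fast commit with slow recode learning rates
(``a_w = a_c = 0.8``, ``a_v = 0.1``), a reset ceiling ``r_max = 0.2`` and a
baseline vigilance of 0.1.  The two parameters that actually get tuned per
problem are ``a_r`` (growth speed of the reset level, which governs category
proliferation) and ``sigma`` (width of the fuzzy membership flanks, which
governs how diffuse a category is).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Literal

ResetLaw = Literal["factored_rate", "printed_steady_state", "printed_finite_horizon"]

RESET_LAWS: tuple[str, ...] = (
    "factored_rate",
    "printed_steady_state",
    "printed_finite_horizon",
)


@dataclass
class NetworkParams:
    """All scalar parameters of the S-dFasArt network.

    Parameters
    ----------
    a_t, b_t
        Rate and gain of the category-activation dynamics
        ``dT/dt = -a_t*T + b_t * prod_i eta_i``.
    a_r, b_r
        Rate and gain of the reset-level dynamics; ``a_r`` is the main
        proliferation control.
    r_max
        Ceiling of the reset level; categories whose reset reaches the
        vigilance threshold are disabled during search.
    a_w, a_c, a_v
        Learning speeds of the minimum, central and maximum weights during
        slow recode.
    b_w, b_v
        Printed gains of the weight dynamics; retained for completeness.  The
        discrete learning step uses the normalised fixed points
        (``min(I, W)``, ``I``, ``max(I, V)``) so these gains do not enter it.
    sigma
        Width of the linear membership flanks on each side of the category
        plateau ``[W, V]`` (the "diffuse character" of a category).
    epsilon
        Guard added to ``|2C|`` in the category-size denominator.
    alpha
        Activation level at or below which the maximum activation counts as
        null, triggering creation of an uncommitted category.
    vigilance
        Baseline vigilance ``h(rho)``; must be below ``r_max``.
    reset_law
        Which reset dynamics to integrate: ``"factored_rate"`` (default;
        ``dR/dt = a_r * (-R + b_r*d) * (r_max - R)`` over a finite horizon, so
        larger ``a_r`` raises the reset level reached and hence category
        counts), ``"printed_steady_state"`` (closed-form equilibrium
        ``min(b_r*d/a_r, r_max)``) or ``"printed_finite_horizon"`` (finite
        horizon of ``dR/dt = (-a_r*R + b_r*d) * (r_max - R)``).
    horizon_steps, dt
        Explicit-Euler controls for the finite-horizon reset laws.
    """

    a_t: float = 0.01
    b_t: float = 1.0
    a_r: float = 1.0
    b_r: float = 1.0
    r_max: float = 0.2
    a_w: float = 0.8
    a_c: float = 0.8
    a_v: float = 0.1
    b_w: float = 1.0
    b_v: float = 1.0
    sigma: float = 0.1
    epsilon: float = 0.001
    alpha: float = 1e-30
    vigilance: float = 0.1
    reset_law: str = "factored_rate"
    horizon_steps: int = 100
    dt: float = 0.01

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        positive = {
            "a_t": self.a_t, "b_t": self.b_t, "a_r": self.a_r, "b_r": self.b_r,
            "r_max": self.r_max, "a_w": self.a_w, "a_c": self.a_c,
            "a_v": self.a_v, "b_w": self.b_w, "b_v": self.b_v,
            "sigma": self.sigma, "epsilon": self.epsilon, "dt": self.dt,
        }
        for name, value in positive.items():
            if not value > 0:
                raise ValueError(f"parameter {name!r} must be strictly positive, got {value}")
        if self.alpha < 0:
            raise ValueError(f"alpha must be non-negative, got {self.alpha}")
        if not 0.0 <= self.vigilance < self.r_max:
            raise ValueError(
                f"vigilance must lie in [0, r_max={self.r_max}), got {self.vigilance}"
            )
        if self.reset_law not in RESET_LAWS:
            raise ValueError(
                f"unknown reset_law {self.reset_law!r}; expected one of {RESET_LAWS}"
            )
        if self.horizon_steps < 1:
            raise ValueError("horizon_steps must be >= 1")

    def replace(self, **overrides: object) -> "NetworkParams":
        """Return a copy with the given fields replaced (validated)."""
        data = asdict(self)
        data.update(overrides)
        return NetworkParams(**data)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "NetworkParams":
        return cls(**data)
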