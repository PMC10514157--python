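"""Growth functions and dynamics of a two-patch system with symmetric dispersal.

Two subpopulations N_A and N_B live on separate habitat patches and are
coupled by symmetric dispersal.  Each patch is characterised by an
intrinsic growth rate r_i and a carrying capacity K_i.  Two time modes are
supported:

* **discrete** — Beverton-Holt recruitment ``f(N) = r N / (1 + xi N)`` with
  competition strength ``xi = (r - 1) / K``, followed by dispersal in which
  a fraction ``delta`` in [0, 1] of each patch's output moves to the other
  patch.  ``delta = 0.5`` is perfect mixing (the two patches are equal
  after one step); ``delta = 1`` swaps the patch outputs entirely.
* **continuous** — logistic growth ``f(N) = r N (1 - N / K)`` with
  competition strength ``xi = r / K``, plus a flux ``delta_c (N_j - N_i)``
  between the patches for any ``delta_c >= 0``.

Both patches are assumed to be *sources*: ``r > 1`` in discrete mode and
``r > 0`` in continuous mode, so each isolated patch settles at its
carrying capacity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from enum import Enum

__all__ = [
    "Mode",
    "PatchParams",
    "PatchState",
    "ParameterError",
    "beverton_holt",
    "logistic_rate",
    "step_discrete",
    "vector_field_continuous",
]


class ParameterError(ValueError):
    """Raised for parameters outside the model's validity domain."""


class Mode(str, Enum):
    """Time mode of the two-patch model."""

    DISCRETE = "discrete"
    CONTINUOUS = "continuous"


def _as_mode(mode: "Mode | str") -> Mode:
    return Mode(mode)


@dataclass(frozen=True)
class PatchParams:
    """Demographic parameters of a two-patch system.

    Parameters
    ----------
    r_A, r_B
        Intrinsic growth rates (per generation in discrete mode, per unit
        time in continuous mode).  Both patches must be sources:
        ``r > 1`` (discrete) or ``r > 0`` (continuous).
    K_A, K_B
        Carrying capacities (individuals), strictly positive.
    mode
        ``Mode.DISCRETE`` (Beverton-Holt) or ``Mode.CONTINUOUS`` (logistic).
    """

    r_A: float
    r_B: float
    K_A: float
    K_B: float
    mode: Mode = Mode.DISCRETE

    def __post_init__(self) -> None:
        object.__setattr__(self, "mode", _as_mode(self.mode))
        for name in ("r_A", "r_B", "K_A", "K_B"):
            value = float(getattr(self, name))
            object.__setattr__(self, name, value)
            if not math.isfinite(value):
                raise ParameterError(f"{name} must be finite, got {value!r}")
        if self.K_A <= 0 or self.K_B <= 0:
            raise ParameterError(
                f"carrying capacities must be positive, got K_A={self.K_A}, K_B={self.K_B}"
            )
        r_floor = 1.0 if self.mode is Mode.DISCRETE else 0.0
        if self.r_A <= r_floor or self.r_B <= r_floor:
            raise ParameterError(
                f"{self.mode.value} mode requires growth rates > {r_floor}, "
                f"got r_A={self.r_A}, r_B={self.r_B}"
            )

    # Competition strengths are derived accessors, never stored, so that
    # (r, K, xi) can never become mutually inconsistent.
    @property
    def xi_A(self) -> float:
        """Intraspecific competition strength of patch A."""
        if self.mode is Mode.DISCRETE:
            return (self.r_A - 1.0) / self.K_A
        return self.r_A / self.K_A

    @property
    def xi_B(self) -> float:
        """Intraspecific competition strength of patch B."""
        if self.mode is Mode.DISCRETE:
            return (self.r_B - 1.0) / self.K_B
        return self.r_B / self.K_B

    def swapped(self) -> "PatchParams":
        """Return the same system with the patch labels exchanged."""
        return replace(
            self, r_A=self.r_B, r_B=self.r_A, K_A=self.K_B, K_B=self.K_A
        )

    def growth(self, N: float, patch: str) -> float:
        """Evaluate the growth function of one patch (``patch`` in 'AB')."""
        r = self.r_A if patch == "A" else self.r_B
        K = self.K_A if patch == "A" else self.K_B
        if self.mode is Mode.DISCRETE:
            return beverton_holt(N, r, K)
        return logistic_rate(N, r, K)


@dataclass(frozen=True)
class PatchState:
    """A pair of non-negative, finite subpopulation sizes."""

    N_A: float
    N_B: float

    def __post_init__(self) -> None:
        for name in ("N_A", "N_B"):
            value = float(getattr(self, name))
            object.__setattr__(self, name, value)
            if not math.isfinite(value) or value < 0:
                raise ValueError(
                    f"{name} must be finite and non-negative, got {value!r}"
                )

    @property
    def total(self) -> float:
        return self.N_A + self.N_B

    def swapped(self) -> "PatchState":
        return PatchState(self.N_B, self.N_A)

    def as_tuple(self) -> tuple[float, float]:
        return (self.N_A, self.N_B)


def beverton_holt(N: float, r: float, K: float) -> float:
    """Beverton-Holt recruitment ``r N / (1 + xi N)`` with ``xi = (r-1)/K``.

    Strictly increasing in ``N``, bounded above by ``r/xi``, and with ``K``
    as its unique positive fixed point.
    """
    if r <= 1 or K <= 0:
        raise ParameterError(f"Beverton-Holt needs r > 1 and K > 0, got r={r}, K={K}")
    if N < 0:
        raise ValueError(f"population size must be non-negative, got {N}")
    xi = (r - 1.0) / K
    return r * N / (1.0 + xi * N)


def logistic_rate(N: float, r: float, K: float) -> float:
    """Logistic growth rate ``r N (1 - N/K)``; zero at ``N = 0`` and ``N = K``."""
    if r <= 0 or K <= 0:
        raise ParameterError(f"logistic growth needs r > 0 and K > 0, got r={r}, K={K}")
    if N < 0:
        raise ValueError(f"population size must be non-negative, got {N}")
    return r * N * (1.0 - N / K)


def step_discrete(state: PatchState, params: PatchParams, delta: float) -> PatchState:
    """One generation of the discrete two-patch map: growth, then dispersal.

    Returns ``((1-d) f_A + d f_B, (1-d) f_B + d f_A)``.  The post-step total
    equals ``f_A(N_A) + f_B(N_B)`` for every ``delta``: dispersal only
    redistributes the patch outputs.
    """
    if params.mode is not Mode.DISCRETE:
        raise ParameterError("step_discrete requires discrete-mode parameters")
    if not 0.0 <= delta <= 1.0:
        raise ValueError(f"discrete dispersal rate must lie in [0, 1], got {delta}")
    fA = beverton_holt(state.N_A, params.r_A, params.K_A)
    fB = beverton_holt(state.N_B, params.r_B, params.K_B)
    return PatchState(
        (1.0 - delta) * fA + delta * fB,
        (1.0 - delta) * fB + delta * fA,
    )


def vector_field_continuous(
    state: PatchState, params: PatchParams, delta_c: float
) -> tuple[float, float]:
    """Instantaneous rates of the coupled logistic system.

    Returns ``(f_A(N_A) - flux, f_B(N_B) + flux)`` with
    ``flux = delta_c (N_A - N_B)``; the two dispersal terms cancel exactly,
    so dispersal conserves individuals.
    """
    if params.mode is not Mode.CONTINUOUS:
        raise ParameterError("vector_field_continuous requires continuous-mode parameters")
    if delta_c < 0:
        raise ValueError(f"continuous dispersal rate must be non-negative, got {delta_c}")
    fA = logistic_rate(state.N_A, params.r_A, params.K_A)
    fB = logistic_rate(state.N_B, params.r_B, params.K_B)
    flux = delta_c * (state.N_A - state.N_B)
    return (fA - flux, fB + flux)
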