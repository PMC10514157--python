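"""Closed-form quantities of the two-patch dispersal response.

Everything here is evaluated from the four demographic parameters alone —
no simulation.  Discrete mode (Beverton-Holt map, canonical orientation
``1 < r_B <= r_A``):

* ``delta_tilde`` — the nontrivial zero of H, i.e. the dispersal rate at
  which a beneficial effect turns detrimental;
* ``quadratic_and_nbar`` — the quadratic whose largest root is the
  maximum asymptotic subpopulation size ``Nbar_B``, plus ``Nbar_A``;
* ``delta_max`` — the dispersal rate at which H attains its maximum,
  expressed through ``Nbar_A``/``Nbar_B``;
* ``h_prime_zero`` — the right derivative H'(0+), whose sign decides
  whether a little dispersal helps or harms;
* ``max_population_summary`` — the maximum asymptotic total population
  size, the dispersal rate achieving it, and the delta=1 equilibrium;
* ``kappa_discrete`` — the threshold constant separating monotone from
  unimodal beneficial responses on the isolation-to-perfect-mixing range.

Continuous mode (coupled logistic, canonical orientation ``K_A < K_B``):

* ``continuous_limits`` — the perfect-mixing limit ``H_c(inf)``, the
  derivative ``H_c'(0+)``, the large-dispersal slope criterion, and the
  threshold constant ``kappa_c``.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass

from .models import Mode, ParameterError, PatchParams, beverton_holt

__all__ = [
    "ClosedFormSummary",
    "ContinuousLimits",
    "delta_tilde",
    "quadratic_and_nbar",
    "delta_max",
    "h_prime_zero",
    "max_population_summary",
    "continuous_limits",
    "kappa_discrete",
    "kappa_continuous",
    "summarize",
]

_DISC_TOL = 1e-9


def _require(params: PatchParams, mode: Mode, op: str) -> None:
    if params.mode is not mode:
        raise ParameterError(f"{op} requires {mode.value}-mode parameters")


def _canonical_discrete(params: PatchParams) -> PatchParams:
    """Reorder so that patch A has the faster growth (r_B <= r_A)."""
    return params.swapped() if params.r_B > params.r_A else params


def delta_tilde(params: PatchParams) -> float | None:
    """Nontrivial zero of H for the discrete model, or ``None``.

    Returns ``None`` when the growth rates are equal, when the rational
    expression degenerates (vanishing denominator factor), or when the
    value falls outside ``(0, 1]`` — in each of those cases delta=0 is the
    unique zero of H.
    """
    _require(params, Mode.DISCRETE, "delta_tilde")
    if params.K_A == params.K_B:
        raise ParameterError("delta_tilde is undefined for equal carrying capacities")
    p = _canonical_discrete(params)
    rA, rB, KA, KB = p.r_A, p.r_B, p.K_A, p.K_B
    if rA == rB:
        return None
    factor = KA * rA * (rB - 1.0) - KB * rB * (rA - 1.0)
    if abs(factor) < _DISC_TOL * max(1.0, KA * rA, KB * rB):
        return None
    num = KA * KB * (rA - 1.0) * (rB - 1.0) * (rA - rB)
    den = (KA * (rB - 1.0) + KB * (rA - 1.0)) * factor
    value = num / den
    if not 0.0 < value <= 1.0:
        return None
    return value


def quadratic_and_nbar(params: PatchParams) -> tuple[float, float, float, float, float]:
    """Coefficients ``(a, b, c)`` of the quadratic for ``Nbar_B`` plus
    ``(Nbar_B, Nbar_A)``, the maximum asymptotic subpopulation sizes.

    ``Nbar_B`` is the largest root of ``a y^2 + b y + c = 0``; the
    discriminant is non-negative throughout the source-source regime.
    """
    _require(params, Mode.DISCRETE, "quadratic_and_nbar")
    p = _canonical_discrete(params)
    rA, rB, KA, KB = p.r_A, p.r_B, p.K_A, p.K_B
    sA, sB = math.sqrt(rA), math.sqrt(rB)
    a = (rB - 1.0) * (KA * sA * (rB - 1.0) + KB * sB * (rA - 1.0))
    b = KB * (rB - 1.0) * (2.0 * KA * sA - (KA - KB + (KA + KB) * rA) * sB)
    c = -KA * KB**2 * (sA - sB) * (sA * sB - 1.0)
    disc = b * b - 4.0 * a * c
    if disc < -_DISC_TOL:
        raise ParameterError(
            f"negative discriminant ({disc:.3e}) — parameters outside the "
            "source-source regime"
        )
    nbar_B = (-b + math.sqrt(max(disc, 0.0))) / (2.0 * a)
    nbar_A = (
        KA * (KB * (sA - sB) + sA * (rB - 1.0) * nbar_B)
        / (KB * sB * (rA - 1.0))
    )
    return (a, b, c, nbar_B, nbar_A)


def delta_max(params: PatchParams) -> float:
    """Stationary point of H: ``(Nbar_B - f_B(Nbar_B)) / (f_A(Nbar_A) - f_B(Nbar_B))``.

    H has an interior maximum exactly when the value lies in (0, 1);
    otherwise H is strictly monotone on [0, 1].  Equal growth rates give
    ``Nbar_B = K_B`` and hence ``delta_max = 0`` (H strictly decreasing).
    """
    _require(params, Mode.DISCRETE, "delta_max")
    if params.K_A == params.K_B:
        raise ParameterError("delta_max is undefined for equal carrying capacities")
    p = _canonical_discrete(params)
    _, _, _, nbar_B, nbar_A = quadratic_and_nbar(p)
    fA = beverton_holt(nbar_A, p.r_A, p.K_A)
    fB = beverton_holt(nbar_B, p.r_B, p.K_B)
    den = fA - fB
    if abs(den) < 1e-14 * max(1.0, abs(fA), abs(fB)):
        raise ParameterError(
            "f_A(Nbar_A) == f_B(Nbar_B): outside the regime where delta_max is defined"
        )
    return (nbar_B - fB) / den


def h_prime_zero(params: PatchParams) -> float:
    """Right derivative of H at delta = 0:
    ``(r_A - r_B)(K_A - K_B) / ((r_A - 1)(r_B - 1))``.

    Positive iff the patch with the faster growth also has the larger
    carrying capacity, i.e. iff a little dispersal is beneficial.
    """
    _require(params, Mode.DISCRETE, "h_prime_zero")
    return (
        (params.r_A - params.r_B)
        * (params.K_A - params.K_B)
        / ((params.r_A - 1.0) * (params.r_B - 1.0))
    )


def equilibrium_full_exchange(params: PatchParams) -> tuple[float, float]:
    """Closed-form delta = 1 equilibrium of the discrete map.

    At full exchange the fixed point satisfies ``N_A = f_B(N_B)`` and
    ``N_B = f_A(N_A)``, which solves to the pair returned here.
    """
    _require(params, Mode.DISCRETE, "equilibrium_full_exchange")
    rA, rB, KA, KB = params.r_A, params.r_B, params.K_A, params.K_B
    num = KA * KB * (rA * rB - 1.0)
    N_A1 = num / (KA * rA * (rB - 1.0) + KB * (rA - 1.0))
    N_B1 = num / (KA * (rB - 1.0) + KB * rB * (rA - 1.0))
    return (N_A1, N_B1)


def max_population_summary(
    params: PatchParams,
) -> tuple[float, float, float, float]:
    """Maximum asymptotic total population size and where it is attained.

    Returns ``(max_total, argmax_delta, N_A(1), N_B(1))``.  Three regimes:

    * interior ``delta_max`` in (0, 1): the maximum is ``Nbar_A + Nbar_B``;
    * equal growth rates or ``K_A < K_B`` (canonical order): dispersal never
      helps, the maximum ``K_A + K_B`` is attained at delta = 0;
    * ``r_A > r_B`` and ``K_A > K_B`` with H monotone increasing: the
      maximum sits at full exchange, delta = 1.
    """
    _require(params, Mode.DISCRETE, "max_population_summary")
    if params.K_A == params.K_B:
        raise ParameterError("max_population_summary requires K_A != K_B")
    p = _canonical_discrete(params)
    N_A1, N_B1 = equilibrium_full_exchange(p)
    if p.r_A == p.r_B:
        return (p.K_A + p.K_B, 0.0, N_A1, N_B1)
    dm = delta_max(p)
    if 0.0 < dm < 1.0:
        _, _, _, nbar_B, nbar_A = quadratic_and_nbar(p)
        return (nbar_A + nbar_B, dm, N_A1, N_B1)
    if p.K_A < p.K_B:
        return (p.K_A + p.K_B, 0.0, N_A1, N_B1)
    return (N_A1 + N_B1, 1.0, N_A1, N_B1)


def kappa_discrete(params: PatchParams) -> float:
    """Discrete threshold constant separating monotone from unimodal
    beneficial responses on the [0, 0.5] dispersal range.

    Oriented so that it exceeds 1:
    ``(r_fast + sqrt(r_A r_B) - 2) / (r_slow + sqrt(r_A r_B) - 2)``.
    """
    _require(params, Mode.DISCRETE, "kappa_discrete")
    if params.r_A == params.r_B:
        raise ParameterError("kappa_discrete requires unequal growth rates")
    r_hi = max(params.r_A, params.r_B)
    r_lo = min(params.r_A, params.r_B)
    s = math.sqrt(params.r_A * params.r_B)
    value = (r_hi + s - 2.0) / (r_lo + s - 2.0)
    assert value > 1.0
    return value


def kappa_continuous(r_A: float, r_B: float) -> float:
    """Continuous threshold constant ``(r_slow + 3 r_fast) / (r_fast + 3 r_slow)``.

    Oriented with the faster-growing rate in the numerator's triple weight
    so that the constant always exceeds 1 for unequal rates (it equals the
    printed form ``(r_A + 3 r_B)/(r_B + 3 r_A)`` in the canonical
    orientation ``r_A < r_B``).
    """
    if r_A <= 0 or r_B <= 0:
        raise ParameterError("growth rates must be positive")
    r_hi, r_lo = max(r_A, r_B), min(r_A, r_B)
    return (r_lo + 3.0 * r_hi) / (r_hi + 3.0 * r_lo)


@dataclass(frozen=True)
class ContinuousLimits:
    """Limit quantities of the continuous response (canonical K_A < K_B)."""

    H_inf: float
    H_prime_zero: float
    Hprime_inf_criterion: float
    kappa_c: float


def continuous_limits(params: PatchParams) -> ContinuousLimits:
    """Evaluate the continuous-time limit expressions.

    ``H_inf`` is the response at perfect mixing (infinite dispersal),
    ``H_prime_zero`` the right derivative at zero dispersal,
    ``Hprime_inf_criterion`` the sign criterion for H' at very large
    dispersal, and ``kappa_c`` the threshold constant.  Requires the
    canonical orientation ``K_A < K_B`` (canonicalize first).
    """
    _require(params, Mode.CONTINUOUS, "continuous_limits")
    if params.K_A >= params.K_B:
        raise ParameterError(
            "continuous_limits requires the canonical orientation K_A < K_B"
        )
    rA, rB, KA, KB = params.r_A, params.r_B, params.K_A, params.K_B
    dK = KB - KA
    H_inf = dK * (rB * KA - rA * KB) / (rB * KA + rA * KB)
    H_prime_0 = dK * (rB - rA) / (rA * rB)
    Hp_inf = 0.5 * dK * (rB - rA) - 2.0 * rA * rB * dK**2 / (rB * KA + rA * KB)
    return ContinuousLimits(H_inf, H_prime_0, Hp_inf, kappa_continuous(rA, rB))


@dataclass(frozen=True)
class ClosedFormSummary:
    """All analytic quantities for one parameter set.

    Fields that do not apply to the mode (or are undefined for the
    parameter combination, e.g. thresholds at equal growth rates) are
    ``None``.
    """

    mode: str
    delta_tilde: float | None = None
    delta_max: float | None = None
    Nbar_A: float | None = None
    Nbar_B: float | None = None
    H_prime_zero: float | None = None
    max_total: float | None = None
    argmax_delta: float | None = None
    N_A_full_exchange: float | None = None
    N_B_full_exchange: float | None = None
    kappa: float | None = None
    kappa_c: float | None = None
    H_inf: float | None = None
    Hprime_inf_criterion: float | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def summarize(params: PatchParams) -> ClosedFormSummary:
    """Evaluate every closed form that applies to ``params``."""
    if params.mode is Mode.DISCRETE:
        equal_K = params.K_A == params.K_B
        equal_r = params.r_A == params.r_B
        dt = None if equal_K else delta_tilde(params)
        nbar_A = nbar_B = dm = None
        if not equal_K:
            _, _, _, nbar_B, nbar_A = quadratic_and_nbar(params)
            dm = 0.0 if equal_r else delta_max(params)
        mx = amx = NA1 = NB1 = None
        if not equal_K:
            mx, amx, NA1, NB1 = max_population_summary(params)
        return ClosedFormSummary(
            mode=params.mode.value,
            delta_tilde=dt,
            delta_max=dm,
            Nbar_A=nbar_A,
            Nbar_B=nbar_B,
            H_prime_zero=h_prime_zero(params),
            max_total=mx,
            argmax_delta=amx,
            N_A_full_exchange=NA1,
            N_B_full_exchange=NB1,
            kappa=None if equal_r else kappa_discrete(params),
        )
    # continuous
    equal_K = params.K_A == params.K_B
    if equal_K:
        return ClosedFormSummary(
            mode=params.mode.value,
            H_prime_zero=0.0,
            H_inf=0.0,
            Hprime_inf_criterion=0.0,
            kappa_c=None if params.r_A == params.r_B else kappa_continuous(params.r_A, params.r_B),
        )
    canon = params.swapped() if params.K_A > params.K_B else params
    lim = continuous_limits(canon)
    return ClosedFormSummary(
        mode=params.mode.value,
        H_prime_zero=lim.H_prime_zero,
        H_inf=lim.H_inf,
        Hprime_inf_criterion=lim.Hprime_inf_criterion,
        kappa_c=lim.kappa_c,
    )
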