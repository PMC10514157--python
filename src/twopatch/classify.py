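"""Exact parameter-condition classification of the dispersal response.

Increasing dispersal between two heterogeneous source patches changes the
asymptotic total population size in one of four qualitatively different
ways — monotonically beneficial, unimodally beneficial, beneficial
turning detrimental, or monotonically detrimental — plus the degenerate
neutral case of equal carrying capacities, where dispersal has no effect
at all.  The classifiers here decide the scenario from the parameters
alone, by closed-form inequalities; :func:`classify_empirical` labels a
numeric response curve instead and serves as an independent oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .closed_forms import (
    delta_max,
    delta_tilde,
    kappa_continuous,
    kappa_discrete,
)
from .equilibrium import ResponseCurve
from .models import Mode, ParameterError, PatchParams

__all__ = [
    "Scenario",
    "Classification",
    "canonicalize",
    "classify",
    "classify_discrete_full",
    "classify_discrete_restricted",
    "classify_continuous",
    "classify_empirical",
]

#: relative tolerance within which a defining inequality counts as "at the
#: boundary"; boundary cases resolve toward the branch stated with "<=".
BOUNDARY_RTOL = 1e-9


class Scenario(str, Enum):
    """Qualitative shape of the dispersal response H."""

    MONOTONICALLY_BENEFICIAL = "monotonically_beneficial"
    UNIMODALLY_BENEFICIAL = "unimodally_beneficial"
    BENEFICIAL_TURNING_DETRIMENTAL = "beneficial_turning_detrimental"
    MONOTONICALLY_DETRIMENTAL = "monotonically_detrimental"
    NEUTRAL_EQUAL_K = "neutral_equal_K"


@dataclass(frozen=True)
class Classification:
    """A scenario label plus bookkeeping flags.

    ``swapped`` records whether the patches were relabeled into the
    canonical theorem orientation; ``boundary`` flags parameter sets
    within tolerance of a defining equality, where the label is fragile.
    """

    label: Scenario
    swapped: bool = False
    boundary: bool = False

    def to_dict(self) -> dict:
        return {
            "label": self.label.value,
            "swapped": self.swapped,
            "boundary": self.boundary,
        }


def _near(x: float, y: float, rtol: float) -> bool:
    return abs(x - y) <= rtol * max(1.0, abs(x), abs(y))


def canonicalize(params: PatchParams) -> tuple[PatchParams, bool]:
    """Relabel the patches into the orientation the theory assumes.

    Discrete mode orders by growth rate (``r_B <= r_A``); continuous mode
    orders by carrying capacity (``K_A <= K_B``).  Patch-swap symmetry of
    the dynamics makes the relabeling lossless.
    """
    if params.mode is Mode.DISCRETE:
        if params.r_B > params.r_A:
            return params.swapped(), True
        return params, False
    if params.K_A > params.K_B:
        return params.swapped(), True
    return params, False


def classify_discrete_full(
    params: PatchParams, boundary_rtol: float = BOUNDARY_RTOL
) -> Classification:
    """Scenario of the discrete response on the full range delta in [0, 1].

    Case analysis (canonical ``1 < r_B < r_A``, ratio = K_B/K_A):

    * equal carrying capacities — neutral (dispersal has no effect);
    * equal growth rates — monotonically detrimental;
    * ratio > 1 — monotonically detrimental;
    * ratio < sqrt(r_A)(r_B-1)/(sqrt(r_B)(r_A-1)) — beneficial turning
      detrimental (the nontrivial zero of H lies inside (0, 1));
    * otherwise beneficial, split by whether ``delta_max`` is interior
      into unimodally vs monotonically beneficial.
    """
    if params.mode is not Mode.DISCRETE:
        raise ParameterError("classify_discrete_full requires discrete-mode parameters")
    p, swapped = canonicalize(params)
    boundary = _near(p.K_A, p.K_B, boundary_rtol) or _near(p.r_A, p.r_B, boundary_rtol)
    if p.K_A == p.K_B:
        return Classification(Scenario.NEUTRAL_EQUAL_K, swapped, boundary)
    if p.r_A == p.r_B:
        return Classification(Scenario.MONOTONICALLY_DETRIMENTAL, swapped, boundary)
    ratio = p.K_B / p.K_A
    boundary = boundary or _near(ratio, 1.0, boundary_rtol)
    if ratio > 1.0:
        return Classification(Scenario.MONOTONICALLY_DETRIMENTAL, swapped, boundary)
    sqrt_bound = (
        np.sqrt(p.r_A) * (p.r_B - 1.0) / (np.sqrt(p.r_B) * (p.r_A - 1.0))
    )
    boundary = boundary or _near(ratio, sqrt_bound, boundary_rtol)
    # equality at the threshold belongs to the beneficial branch ("<=")
    if ratio < sqrt_bound and not _near(ratio, sqrt_bound, boundary_rtol):
        return Classification(
            Scenario.BENEFICIAL_TURNING_DETRIMENTAL, swapped, boundary
        )
    dm = delta_max(p)
    boundary = boundary or _near(dm, 0.0, boundary_rtol) or _near(dm, 1.0, boundary_rtol)
    if 0.0 < dm < 1.0:
        return Classification(Scenario.UNIMODALLY_BENEFICIAL, swapped, boundary)
    return Classification(Scenario.MONOTONICALLY_BENEFICIAL, swapped, boundary)


def classify_discrete_restricted(
    params: PatchParams, boundary_rtol: float = BOUNDARY_RTOL
) -> Classification:
    """Scenario of the discrete response restricted to delta in [0, 0.5].

    This is the range comparable to the continuous model (isolation to
    perfect mixing).  The authoritative route compares the closed forms
    ``delta_tilde`` and ``delta_max`` against 0.5; it coincides with the
    inequality route through ``rho = (r_B-1)/(r_A-1)`` and the threshold
    constant kappa (see :func:`_classify_discrete_restricted_inequalities`).
    """
    if params.mode is not Mode.DISCRETE:
        raise ParameterError(
            "classify_discrete_restricted requires discrete-mode parameters"
        )
    p, swapped = canonicalize(params)
    boundary = _near(p.K_A, p.K_B, boundary_rtol) or _near(p.r_A, p.r_B, boundary_rtol)
    if p.K_A == p.K_B:
        return Classification(Scenario.NEUTRAL_EQUAL_K, swapped, boundary)
    if p.r_A == p.r_B:
        return Classification(Scenario.MONOTONICALLY_DETRIMENTAL, swapped, boundary)
    ratio = p.K_B / p.K_A
    boundary = boundary or _near(ratio, 1.0, boundary_rtol)
    if ratio > 1.0:
        return Classification(Scenario.MONOTONICALLY_DETRIMENTAL, swapped, boundary)
    dt = delta_tilde(p)
    if dt is not None:
        boundary = boundary or _near(dt, 0.5, boundary_rtol)
        if dt < 0.5:
            return Classification(
                Scenario.BENEFICIAL_TURNING_DETRIMENTAL, swapped, boundary
            )
    dm = delta_max(p)
    boundary = boundary or _near(dm, 0.5, boundary_rtol) or _near(dm, 0.0, boundary_rtol)
    if 0.0 < dm < 0.5:
        return Classification(Scenario.UNIMODALLY_BENEFICIAL, swapped, boundary)
    return Classification(Scenario.MONOTONICALLY_BENEFICIAL, swapped, boundary)


def _classify_discrete_restricted_inequalities(
    params: PatchParams, boundary_rtol: float = BOUNDARY_RTOL
) -> Classification:
    """Inequality route for the restricted range, kept as a cross-check.

    With canonical ``r_B < r_A``, ``rho = (r_B-1)/(r_A-1)`` and kappa > 1:
    ratio >= kappa*rho — monotonically beneficial; rho <= ratio <
    kappa*rho — unimodally beneficial; ratio < rho — beneficial turning
    detrimental; ratio > 1 — monotonically detrimental.
    """
    p, swapped = canonicalize(params)
    boundary = _near(p.K_A, p.K_B, boundary_rtol) or _near(p.r_A, p.r_B, boundary_rtol)
    if p.K_A == p.K_B:
        return Classification(Scenario.NEUTRAL_EQUAL_K, swapped, boundary)
    if p.r_A == p.r_B:
        return Classification(Scenario.MONOTONICALLY_DETRIMENTAL, swapped, boundary)
    ratio = p.K_B / p.K_A
    if ratio > 1.0:
        return Classification(
            Scenario.MONOTONICALLY_DETRIMENTAL, swapped, _near(ratio, 1.0, boundary_rtol)
        )
    rho = (p.r_B - 1.0) / (p.r_A - 1.0)
    kappa_rho = kappa_discrete(p) * rho
    boundary = (
        boundary
        or _near(ratio, rho, boundary_rtol)
        or _near(ratio, kappa_rho, boundary_rtol)
        or _near(ratio, 1.0, boundary_rtol)
    )
    if ratio >= kappa_rho or _near(ratio, kappa_rho, boundary_rtol):
        return Classification(Scenario.MONOTONICALLY_BENEFICIAL, swapped, boundary)
    if ratio >= rho or _near(ratio, rho, boundary_rtol):
        return Classification(Scenario.UNIMODALLY_BENEFICIAL, swapped, boundary)
    return Classification(Scenario.BENEFICIAL_TURNING_DETRIMENTAL, swapped, boundary)


def classify_continuous(
    params: PatchParams, boundary_rtol: float = BOUNDARY_RTOL
) -> Classification:
    """Scenario of the continuous response for delta_c in [0, inf).

    Case analysis (canonical ``K_A < K_B``, competition strengths
    ``xi_i = r_i / K_i``):

    * equal carrying capacities — neutral;
    * r_A >= r_B — monotonically detrimental (the large patch grows
      slower, so it loses more than the small patch can absorb);
    * xi_B >= kappa_c * xi_A — monotonically beneficial;
    * xi_A <= xi_B < kappa_c * xi_A — unimodally beneficial;
    * xi_B < xi_A — beneficial turning detrimental.
    """
    if params.mode is not Mode.CONTINUOUS:
        raise ParameterError("classify_continuous requires continuous-mode parameters")
    p, swapped = canonicalize(params)
    boundary = _near(p.K_A, p.K_B, boundary_rtol) or _near(p.r_A, p.r_B, boundary_rtol)
    if p.K_A == p.K_B:
        return Classification(Scenario.NEUTRAL_EQUAL_K, swapped, boundary)
    if p.r_A >= p.r_B:
        return Classification(Scenario.MONOTONICALLY_DETRIMENTAL, swapped, boundary)
    xi_A, xi_B = p.xi_A, p.xi_B
    kappa_c = kappa_continuous(p.r_A, p.r_B)
    boundary = (
        boundary
        or _near(xi_B, xi_A, boundary_rtol)
        or _near(xi_B, kappa_c * xi_A, boundary_rtol)
    )
    if xi_B >= kappa_c * xi_A or _near(xi_B, kappa_c * xi_A, boundary_rtol):
        return Classification(Scenario.MONOTONICALLY_BENEFICIAL, swapped, boundary)
    if xi_B >= xi_A or _near(xi_B, xi_A, boundary_rtol):
        return Classification(Scenario.UNIMODALLY_BENEFICIAL, swapped, boundary)
    return Classification(Scenario.BENEFICIAL_TURNING_DETRIMENTAL, swapped, boundary)


def classify(
    params: PatchParams,
    dispersal_range: str = "full",
    boundary_rtol: float = BOUNDARY_RTOL,
) -> Classification:
    """Mode- and range-dispatching front end for the analytic classifiers.

    ``dispersal_range`` is ``"full"`` ([0, 1] discrete / [0, inf)
    continuous) or ``"half"`` ([0, 0.5], discrete only).
    """
    if params.mode is Mode.CONTINUOUS:
        return classify_continuous(params, boundary_rtol)
    if dispersal_range == "half":
        return classify_discrete_restricted(params, boundary_rtol)
    if dispersal_range != "full":
        raise ValueError(f"dispersal_range must be 'full' or 'half', got {dispersal_range!r}")
    return classify_discrete_full(params, boundary_rtol)


def classify_empirical(curve: ResponseCurve, atol: float = 1e-8) -> Classification:
    """Label a numeric response curve from its H values alone.

    Used as the independent oracle for the analytic classifiers: the sign
    pattern and (tolerance-based) monotonicity of H determine the label.
    Requires a reasonably fine curve (at least 21 points).
    """
    if len(curve) < 21:
        raise ValueError(
            f"curve too coarse for empirical classification ({len(curve)} points)"
        )
    H = curve.H
    if np.max(np.abs(H)) < atol:
        return Classification(Scenario.NEUTRAL_EQUAL_K)
    H_max = float(np.max(H))
    if H_max <= atol:
        # never meaningfully positive: detrimental throughout
        return Classification(Scenario.MONOTONICALLY_DETRIMENTAL)
    if H[-1] < -atol:
        return Classification(Scenario.BENEFICIAL_TURNING_DETRIMENTAL)
    if np.all(np.diff(H) >= -atol):
        return Classification(Scenario.MONOTONICALLY_BENEFICIAL)
    return Classification(Scenario.UNIMODALLY_BENEFICIAL)
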