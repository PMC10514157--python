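"""Graphical-construction utilities for the discrete two-patch equilibrium.

At equilibrium the two points ``(N_A*, f_A*)`` and ``(N_B*, f_B*)`` on the
patch growth curves satisfy two conditions: the growth surplus of one
patch compensates the deficit of the other (``f_B* - N_B* = -(f_A* -
N_A*)``), and the chord connecting the two points has slope
``1/(1 - 2 delta)``.  At ``delta = 0`` the chord is the identity line
through the carrying capacities; at ``delta = 0.5`` (perfect mixing) it is
vertical.  The chord's intersection with the identity line equals half the
asymptotic total population size, and the response decomposes exactly into
overcrowding of the small patch minus undercrowding of the large patch:
``H = (N_small* - K_small) - (K_large - N_large*)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .equilibrium import equilibrium_discrete
from .models import Mode, ParameterError, PatchParams, beverton_holt

__all__ = ["ChordConstruction", "graphical_construction", "n_diamond"]


@dataclass(frozen=True)
class ChordConstruction:
    """Chord geometry of the discrete equilibrium at one dispersal rate.

    ``slope`` is ``1/(1-2 delta)`` or ``None`` when the chord is vertical
    (``vertical`` is then True).  ``chord`` holds the two equilibrium
    points ``((N_A*, f_A*), (N_B*, f_B*))`` in the canonical orientation
    ``K_B > K_A``.  ``half_total_intersection`` is the coordinate at which
    the chord crosses the identity line — half the asymptotic total.
    ``overcrowding`` is ``N_A* - K_A`` (small patch above capacity) and
    ``undercrowding`` is ``K_B - N_B*`` (large patch below capacity);
    their difference equals H(delta).
    """

    delta: float
    slope: float | None
    vertical: bool
    chord: tuple[tuple[float, float], tuple[float, float]]
    half_total_intersection: float
    overcrowding: float
    undercrowding: float
    residual: float

    @property
    def H(self) -> float:
        return self.overcrowding - self.undercrowding


def graphical_construction(params: PatchParams, delta: float) -> ChordConstruction:
    """Compute the chord construction at the discrete equilibrium.

    The patches are relabeled so that B is the larger patch (K_B > K_A).
    The returned ``residual`` is the compensation-condition defect
    ``(f_B* - N_B*) + (f_A* - N_A*)``, which is zero at the equilibrium.
    """
    if params.mode is not Mode.DISCRETE:
        raise ParameterError("graphical_construction requires discrete-mode parameters")
    if not 0.0 <= delta <= 1.0:
        raise ValueError(f"discrete dispersal rate must lie in [0, 1], got {delta}")
    if params.K_B < params.K_A:
        params = params.swapped()
    eq = equilibrium_discrete(params, delta)
    fA = beverton_holt(eq.N_A, params.r_A, params.K_A)
    fB = beverton_holt(eq.N_B, params.r_B, params.K_B)
    residual = (fB - eq.N_B) + (fA - eq.N_A)
    vertical = math.isclose(delta, 0.5, rel_tol=0.0, abs_tol=1e-15)
    if vertical:
        slope = None
        intersection = 0.5 * (eq.N_A + eq.N_B)  # chord degenerates onto N_A*=N_B*
    else:
        slope = 1.0 / (1.0 - 2.0 * delta)
        if delta == 0.0:
            intersection = 0.5 * (eq.N_A + eq.N_B)  # chord is the identity line
        else:
            # identity crossing of the line through (N_A*, f_A*) with this slope
            intersection = (fA - slope * eq.N_A) / (1.0 - slope)
    return ChordConstruction(
        delta=delta,
        slope=slope,
        vertical=vertical,
        chord=((eq.N_A, fA), (eq.N_B, fB)),
        half_total_intersection=intersection,
        overcrowding=eq.N_A - params.K_A,
        undercrowding=params.K_B - eq.N_B,
        residual=residual,
    )


def n_diamond(r: float, K: float) -> float:
    """Population size maximizing the per-step growth ``f(N) - N`` of the
    Beverton-Holt map: ``(sqrt(r) - 1)/xi = K/(sqrt(r) + 1)``.

    Marks the strength of intraspecific competition on the reproduction
    curve; always smaller than K, and tends to K/2 as r tends to 1.
    """
    if r <= 1 or K <= 0:
        raise ParameterError(f"n_diamond needs r > 1 and K > 0, got r={r}, K={K}")
    return K / (math.sqrt(r) + 1.0)
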