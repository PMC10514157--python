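"""Numerical equilibria and the dispersal-response function H.

For every admissible dispersal rate the coupled two-patch system has a
unique positive attracting equilibrium ``(N_A(delta), N_B(delta))``.  The
dispersal-response function

    H(delta) = N_A(delta) + N_B(delta) - (K_A + K_B)

measures the effect of connecting the patches: positive H means dispersal
is beneficial for the asymptotic total population size, negative H
detrimental.  ``H(0) = 0`` by definition.

The discrete equilibrium is found by iterating the map (globally
convergent from any positive state) and polishing with a 2-D root solve;
the continuous steady state by integrating the ODE towards the attractor
and polishing with a Newton-type root solve on the vector field.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.integrate import solve_ivp

from .models import Mode, ParameterError, PatchParams, PatchState, step_discrete

__all__ = [
    "ConvergenceError",
    "ResponseCurve",
    "default_grid",
    "equilibrium_discrete",
    "equilibrium_continuous",
    "H_discrete",
    "H_continuous",
    "response_curve",
    "numeric_argmax_H",
    "numeric_zero_H",
]

#: sup-norm tolerance for the discrete fixed-point iteration
ITERATION_TOL = 1e-12
#: iteration budget for the discrete map (generously above what is ever needed)
MAX_ITERATIONS = 1_000_000
#: vector-field norm below which the ODE is considered converged
FIELD_TOL = 1e-9


class ConvergenceError(RuntimeError):
    """Raised when an equilibrium solver exhausts its budget."""


# ---------------------------------------------------------------------------
# discrete mode
# ---------------------------------------------------------------------------

def _iterate_discrete(
    params: PatchParams,
    delta: float,
    x0: tuple[float, float],
    tol: float,
    max_iter: int,
) -> tuple[float, float]:
    rA, rB = params.r_A, params.r_B
    xiA, xiB = params.xi_A, params.xi_B
    NA, NB = x0
    omd = 1.0 - delta
    for _ in range(max_iter):
        fA = rA * NA / (1.0 + xiA * NA)
        fB = rB * NB / (1.0 + xiB * NB)
        nA = omd * fA + delta * fB
        nB = omd * fB + delta * fA
        if abs(nA - NA) < tol and abs(nB - NB) < tol:
            return (nA, nB)
        NA, NB = nA, nB
    raise ConvergenceError(
        f"discrete map did not converge within {max_iter} iterations "
        f"(delta={delta}, params={params})"
    )


def equilibrium_discrete(
    params: PatchParams,
    delta: float,
    x0: PatchState | tuple[float, float] | None = None,
    tol: float = ITERATION_TOL,
    max_iter: int = MAX_ITERATIONS,
    polish: bool = True,
) -> PatchState:
    """Unique positive fixed point of the discrete two-patch map.

    Iterates the map from ``x0`` (default ``(K_A, K_B)``) until the
    sup-norm change drops below ``tol``, then refines with a 2-D root
    solve on ``x - step(x)``.  Global convergence of the iteration makes
    the result independent of the initial state.
    """
    if params.mode is not Mode.DISCRETE:
        raise ParameterError("equilibrium_discrete requires discrete-mode parameters")
    if not 0.0 <= delta <= 1.0:
        raise ValueError(f"discrete dispersal rate must lie in [0, 1], got {delta}")
    if delta == 0.0 and x0 is None:
        return PatchState(params.K_A, params.K_B)
    if x0 is None:
        start = (params.K_A, params.K_B)
    elif isinstance(x0, PatchState):
        start = x0.as_tuple()
    else:
        start = (float(x0[0]), float(x0[1]))
    approx = _iterate_discrete(params, delta, start, tol, max_iter)
    if not polish:
        return PatchState(*approx)

    def residual(x: np.ndarray) -> np.ndarray:
        nxt = step_discrete(PatchState(max(x[0], 0.0), max(x[1], 0.0)), params, delta)
        return np.array([x[0] - nxt.N_A, x[1] - nxt.N_B])

    sol = optimize.root(residual, np.array(approx), method="hybr", tol=1e-14)
    if sol.success and sol.x.min() > 0 and np.abs(sol.fun).max() <= 1e-10:
        return PatchState(*sol.x)
    return PatchState(*approx)


def H_discrete(params: PatchParams, delta: float, **kwargs) -> float:
    """Dispersal response of the asymptotic total population size.

    ``H(0)`` is returned as exactly 0 by definition, avoiding cancellation
    noise at the anchor point.
    """
    if params.mode is not Mode.DISCRETE:
        raise ParameterError("H_discrete requires discrete-mode parameters")
    if delta == 0.0:
        return 0.0
    eq = equilibrium_discrete(params, delta, **kwargs)
    return eq.total - (params.K_A + params.K_B)


# ---------------------------------------------------------------------------
# continuous mode
# ---------------------------------------------------------------------------

def _field_and_jac(params: PatchParams, delta_c: float):
    rA, rB = params.r_A, params.r_B
    KA, KB = params.K_A, params.K_B

    def fun(x: np.ndarray) -> np.ndarray:
        NA, NB = x
        flux = delta_c * (NA - NB)
        return np.array(
            [rA * NA * (1.0 - NA / KA) - flux, rB * NB * (1.0 - NB / KB) + flux]
        )

    def jac(x: np.ndarray) -> np.ndarray:
        NA, NB = x
        return np.array(
            [
                [rA * (1.0 - 2.0 * NA / KA) - delta_c, delta_c],
                [delta_c, rB * (1.0 - 2.0 * NB / KB) - delta_c],
            ]
        )

    return fun, jac


def equilibrium_continuous(
    params: PatchParams,
    delta_c: float,
    x0: PatchState | tuple[float, float] | None = None,
    tol: float = FIELD_TOL,
) -> PatchState:
    """Positive steady state of the coupled logistic system.

    Without an initial guess, the ODE is integrated from ``(K_A, K_B)``
    (a stiff-capable method, since large ``delta_c`` makes the exchange
    fast) until the vector-field norm falls below ``tol``; the endpoint is
    then polished with a Newton-type root solve on the vector field.  When
    ``K_A < K_B`` the steady state satisfies the strict ordering
    ``K_A < N_A < N_B < K_B`` for any ``delta_c > 0``.
    """
    if params.mode is not Mode.CONTINUOUS:
        raise ParameterError("equilibrium_continuous requires continuous-mode parameters")
    if delta_c < 0:
        raise ValueError(f"continuous dispersal rate must be non-negative, got {delta_c}")
    if delta_c == 0.0 and x0 is None:
        return PatchState(params.K_A, params.K_B)
    if params.K_A == params.K_B:
        # (K, K) kills both the logistic terms and the flux exactly.
        return PatchState(params.K_A, params.K_B)

    fun, jac = _field_and_jac(params, delta_c)

    if x0 is not None:
        start = np.asarray(
            x0.as_tuple() if isinstance(x0, PatchState) else x0, dtype=float
        )
    else:
        start = np.array([params.K_A, params.K_B])
        t_chunk = 50.0
        for _ in range(40):
            if np.linalg.norm(fun(start)) < tol:
                break
            ivp = solve_ivp(
                lambda t, y: fun(y),
                (0.0, t_chunk),
                start,
                method="LSODA",
                jac=lambda t, y: jac(y),
                rtol=1e-10,
                atol=1e-12,
            )
            if not ivp.success:
                raise ConvergenceError(
                    f"ODE integration failed at delta_c={delta_c}: {ivp.message}"
                )
            start = ivp.y[:, -1]

    sol = optimize.root(fun, start, jac=jac, method="hybr", tol=1e-13)
    # judge by the residual, not the solver flag: with very fast exchange the
    # step-size heuristics can report stagnation at a fully converged point
    if sol.x.min() <= 0 or np.abs(sol.fun).max() > 1e-8:
        raise ConvergenceError(
            f"steady-state root solve failed at delta_c={delta_c} "
            f"(residual {np.abs(sol.fun).max():.2e})"
        )
    return PatchState(*sol.x)


def H_continuous(params: PatchParams, delta_c: float, **kwargs) -> float:
    """Continuous-time dispersal response; ``H_c(0)`` is exactly 0."""
    if params.mode is not Mode.CONTINUOUS:
        raise ParameterError("H_continuous requires continuous-mode parameters")
    if delta_c == 0.0:
        return 0.0
    eq = equilibrium_continuous(params, delta_c, **kwargs)
    return eq.total - (params.K_A + params.K_B)


# ---------------------------------------------------------------------------
# mode dispatch helpers
# ---------------------------------------------------------------------------

def _equilibrium(params: PatchParams, delta: float, x0=None) -> PatchState:
    if params.mode is Mode.DISCRETE:
        return equilibrium_discrete(params, delta, x0=x0)
    return equilibrium_continuous(params, delta, x0=x0)


def _H(params: PatchParams, delta: float, x0=None) -> float:
    if delta == 0.0:
        return 0.0
    eq = _equilibrium(params, delta, x0=x0)
    return eq.total - (params.K_A + params.K_B)


def default_grid(mode: Mode | str, n: int = 201) -> np.ndarray:
    """Default dispersal grid: ``[0, 1]`` discrete; ``[0, 10]`` plus a
    log-spaced tail out to 1e4 in continuous mode (the tail resolves the
    approach to the perfect-mixing limit)."""
    mode = Mode(mode)
    if mode is Mode.DISCRETE:
        return np.linspace(0.0, 1.0, n)
    n_tail = max(n // 10, 2)
    head = np.linspace(0.0, 10.0, n - n_tail)
    tail = np.geomspace(10.0, 1e4, n_tail + 1)[1:]
    return np.concatenate([head, tail])


@dataclass
class ResponseCurve:
    """Equilibria and H values along a grid of dispersal rates.

    The grid is strictly increasing and starts at 0, where H is exactly 0.
    """

    mode: Mode
    grid: np.ndarray
    N_A: np.ndarray
    N_B: np.ndarray
    H: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mode = Mode(self.mode)
        self.grid = np.asarray(self.grid, dtype=float)
        self.N_A = np.asarray(self.N_A, dtype=float)
        self.N_B = np.asarray(self.N_B, dtype=float)
        self.H = np.asarray(self.H, dtype=float)
        if self.grid.size == 0 or self.grid[0] != 0.0:
            raise ValueError("dispersal grid must start at 0")
        if self.grid.size > 1 and not np.all(np.diff(self.grid) > 0):
            raise ValueError("dispersal grid must be strictly increasing")
        if self.mode is Mode.DISCRETE and self.grid[-1] > 1.0:
            raise ValueError("discrete dispersal grid must stay within [0, 1]")

    def __len__(self) -> int:
        return self.grid.size

    def state(self, i: int) -> PatchState:
        return PatchState(self.N_A[i], self.N_B[i])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"delta": self.grid, "N_A": self.N_A, "N_B": self.N_B, "H": self.H}
        )

    def summary(self) -> dict:
        """JSON-ready digest of the curve."""
        imax = int(np.argmax(self.H))
        return {
            "mode": self.mode.value,
            "n_points": int(self.grid.size),
            "H_max": float(self.H[imax]),
            "delta_at_H_max": float(self.grid[imax]),
            "H_final": float(self.H[-1]),
            "n_positive": int(np.sum(self.H > 0)),
            "n_negative": int(np.sum(self.H < 0)),
            **{k: v for k, v in self.metadata.items()},
        }

    def to_csv(self, path) -> None:
        """Write the curve as CSV with ``# key: value`` provenance headers."""
        buf = io.StringIO()
        meta = {"mode": self.mode.value, **self.metadata}
        for key, value in meta.items():
            buf.write(f"# {key}: {value}\n")
        self.to_frame().to_csv(buf, index=False)
        with open(path, "w") as fh:
            fh.write(buf.getvalue())

    @classmethod
    def from_csv(cls, path) -> "ResponseCurve":
        meta: dict = {}
        with open(path) as fh:
            text = fh.read()
        for line in text.splitlines():
            if line.startswith("# "):
                key, _, value = line[2:].partition(": ")
                meta[key] = value
        frame = pd.read_csv(io.StringIO(text), comment="#", float_precision="round_trip")
        mode = Mode(meta.pop("mode", "discrete"))
        return cls(
            mode=mode,
            grid=frame["delta"].to_numpy(),
            N_A=frame["N_A"].to_numpy(),
            N_B=frame["N_B"].to_numpy(),
            H=frame["H"].to_numpy(),
            metadata=meta,
        )


def response_curve(params: PatchParams, grid=None) -> ResponseCurve:
    """Evaluate the equilibrium and H at every point of a dispersal grid.

    Successive grid points reuse the previous equilibrium as the initial
    guess (continuation), which keeps the curve cheap even on fine grids.
    """
    if grid is None:
        grid = default_grid(params.mode)
    grid = np.asarray(grid, dtype=float)
    NA = np.empty_like(grid)
    NB = np.empty_like(grid)
    H = np.empty_like(grid)
    prev: PatchState | None = None
    for i, d in enumerate(grid):
        try:
            eq = _equilibrium(params, float(d), x0=prev)
        except ConvergenceError as exc:
            raise ConvergenceError(
                f"equilibrium failed at grid point delta={d} (index {i}): {exc}"
            ) from exc
        NA[i], NB[i] = eq.N_A, eq.N_B
        H[i] = 0.0 if d == 0.0 else eq.total - (params.K_A + params.K_B)
        prev = eq
    meta = {
        "r_A": params.r_A,
        "r_B": params.r_B,
        "K_A": params.K_A,
        "K_B": params.K_B,
        "iteration_tol": ITERATION_TOL,
        "field_tol": FIELD_TOL,
    }
    return ResponseCurve(params.mode, grid, NA, NB, H, metadata=meta)


def numeric_argmax_H(
    params: PatchParams,
    interval: tuple[float, float] | None = None,
    coarse: int = 101,
    xatol: float = 1e-10,
) -> tuple[float, float]:
    """Locate the maximizer of H on an interval.

    A coarse grid scan brackets the maximum, then a bounded scalar
    minimization of ``-H`` refines it.  Valid because H is either
    monotone or unimodal on the admissible range; if the coarse maximum
    sits at an interval endpoint, that endpoint is returned.
    """
    if interval is None:
        interval = (0.0, 1.0) if params.mode is Mode.DISCRETE else (0.0, 100.0)
    lo, hi = float(interval[0]), float(interval[1])
    if params.mode is Mode.DISCRETE and not (0.0 <= lo < hi <= 1.0):
        raise ValueError(f"invalid discrete interval {interval}")
    grid = np.linspace(lo, hi, coarse)
    values = np.array([_H(params, float(d)) for d in grid])
    i = int(np.argmax(values))  # argmax takes the first hit: ties toward smaller delta
    if i == 0 or i == coarse - 1:
        return (float(grid[i]), float(values[i]))
    bracket = (float(grid[i - 1]), float(grid[i + 1]))
    res = optimize.minimize_scalar(
        lambda d: -_H(params, float(d)),
        bounds=bracket,
        method="bounded",
        options={"xatol": xatol},
    )
    d_star = float(res.x)
    return (d_star, _H(params, d_star))


def numeric_zero_H(
    params: PatchParams,
    interval: tuple[float, float] | None = None,
    coarse: int = 201,
    xtol: float = 1e-12,
) -> float | None:
    """Nontrivial zero of H on an interval excluding the trivial zero at 0.

    Scans a coarse grid for the (unique, if any) sign change and refines
    with bisection; returns ``None`` when H keeps a constant sign.
    """
    if interval is None:
        interval = (1e-3, 1.0) if params.mode is Mode.DISCRETE else (1e-3, 1e4)
    lo, hi = float(interval[0]), float(interval[1])
    if lo <= 0:
        raise ValueError("interval must exclude the trivial zero at delta=0")
    if params.mode is Mode.CONTINUOUS and hi > 10.0:
        # log spacing resolves both the small-dispersal rise and the tail
        grid = np.geomspace(lo, hi, coarse)
    else:
        grid = np.linspace(lo, hi, coarse)
    values = np.array([_H(params, float(d)) for d in grid])
    sign_change = np.flatnonzero(values[:-1] * values[1:] < 0)
    if sign_change.size == 0:
        return None
    i = int(sign_change[0])  # ties toward smaller delta
    root = optimize.brentq(
        lambda d: _H(params, float(d)), grid[i], grid[i + 1], xtol=xtol
    )
    return float(root)
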