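"""Parameter sweeps of equilibrium structure, fold detection and hysteresis.

Because equilibria are found by an exhaustive scalar scan (see
:mod:`cytotriad.equilibria`), a fold (saddle-node) shows up as a change in the
equilibrium *count* between adjacent sweep values; each such interval is
refined by bisection on the parameter.  Hysteresis is probed dynamically: the
attained steady state is tracked by long-time integration with state
inheritance along ascending and descending parameter sweeps.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .model import CytokineState, DEFAULT_INITIAL_STATE, ParameterSet, rhs, validate_parameters
from .equilibria import EquilibriumPoint, enumerate_equilibria
from .simulate import rk4_integrate

__all__ = [
    "BifurcationDiagram",
    "HysteresisResult",
    "BranchRegression",
    "DEFAULT_SWEEP_GRID",
    "detect_folds",
    "sweep_equilibria",
    "hysteresis_sweep",
    "branch_regression",
]

#: Default sweep range for the IL-10 -> TNF-alpha suppression strength
#: (physiologically plausible range, 27 points).
DEFAULT_SWEEP_GRID = np.linspace(0.02, 0.15, 27)

_FOLD_REFINE_TOL = 1e-4


@dataclass(frozen=True)
class BifurcationDiagram:
    """Equilibria per value of a swept parameter, plus fold intervals.

    ``fold_locations`` holds (lo, hi) parameter intervals, refined to width
    <= 1e-4, across which the equilibrium count changes.
    """

    parameter_name: str
    grid: np.ndarray
    points: list[list[EquilibriumPoint]]
    fold_locations: list[tuple[float, float]]

    def counts(self) -> np.ndarray:
        return np.array([len(pts) for pts in self.points])


def detect_folds(
    grid: Sequence[float],
    counts: Sequence[int],
    count_fn: Callable[[float], int],
    refine_tol: float = _FOLD_REFINE_TOL,
) -> list[tuple[float, float]]:
    """Bisection-refined parameter intervals where a root count changes.

    ``counts`` are the root counts on ``grid``; ``count_fn`` recounts at
    arbitrary parameter values during refinement.  Shared by the model sweep
    and the analytic fold fixtures.
    """
    folds: list[tuple[float, float]] = []
    for a, b, ca, cb in zip(grid[:-1], grid[1:], counts[:-1], counts[1:]):
        if ca == cb:
            continue
        lo, hi, clo = float(a), float(b), ca
        while hi - lo > refine_tol:
            mid = 0.5 * (lo + hi)
            if count_fn(mid) == clo:
                lo = mid
            else:
                hi = mid
        folds.append((lo, hi))
    return folds


def sweep_equilibria(
    p: ParameterSet,
    parameter_name: str = "gamma_T10",
    grid: Sequence[float] | None = None,
    regime: str = "post_delay",
    scan_points: int = 10001,
) -> BifurcationDiagram:
    """Enumerate equilibria across a parameter grid and locate folds."""
    grid = DEFAULT_SWEEP_GRID if grid is None else np.asarray(grid, dtype=float)
    if not np.all(np.diff(grid) > 0):
        raise ValueError("grid must be strictly increasing")

    def at(value: float) -> list[EquilibriumPoint]:
        try:
            q = validate_parameters(p.replace(**{parameter_name: float(value)}))
        except ValueError as exc:
            raise ValueError(f"invalid {parameter_name} = {value!r}: {exc}") from exc
        return enumerate_equilibria(q, regime=regime, scan_points=scan_points)

    points = [at(v) for v in grid]
    counts = [len(pts) for pts in points]
    folds = detect_folds(grid, counts, lambda v: len(at(v)))
    return BifurcationDiagram(parameter_name=parameter_name, grid=np.asarray(grid),
                              points=points, fold_locations=folds)


@dataclass(frozen=True)
class HysteresisResult:
    """Attained steady states from ascending/descending parameter sweeps.

    ``max_gap`` is the largest |up - down| TNF-alpha difference over the
    grid; a nonzero gap signals direction-dependent attractor selection,
    i.e. hysteresis.  ``unsettled`` lists (direction, parameter value) pairs
    that failed the settling criterion even after one 4x time extension.
    """

    parameter_name: str
    grid: np.ndarray
    up_states: np.ndarray    # (n, 3)
    down_states: np.ndarray  # (n, 3)
    max_gap: float
    unsettled: tuple[tuple[str, float], ...] = ()


def _settle(p: ParameterSet, y0: np.ndarray, t_settle: float, dt: float,
            tol: float = 1e-9) -> tuple[np.ndarray, bool]:
    """Integrate to t_settle (extend once by 4x if needed); check ||rhs||_inf."""
    y = y0
    for horizon in (t_settle, 3.0 * t_settle):
        s0 = CytokineState(0.0, *map(float, y))
        tr = rk4_integrate(p, s0, horizon, dt)
        y = tr.states[-1]
        deriv = rhs(CytokineState(0.0, *map(float, y)), p, gate=True)
        if float(np.max(np.abs(deriv.as_array()))) <= tol:
            return y, True
    return y, False


def hysteresis_sweep(
    p: ParameterSet,
    parameter_name: str = "gamma_T10",
    grid: Sequence[float] | None = None,
    t_settle: float = 500.0,
    dt: float = 0.05,
) -> HysteresisResult:
    """Forward/backward sweep with state inheritance.

    The ascending pass starts from the reference initial concentrations at
    the first grid value and inherits the attained state at each subsequent
    value; the descending pass mirrors this from the last grid value.
    """
    grid = DEFAULT_SWEEP_GRID if grid is None else np.asarray(grid, dtype=float)
    if not np.all(np.diff(grid) > 0):
        raise ValueError("grid must be strictly increasing")
    n = len(grid)
    up = np.empty((n, 3))
    down = np.empty((n, 3))
    unsettled: list[tuple[str, float]] = []

    y = np.array(DEFAULT_INITIAL_STATE, dtype=float)
    for i, v in enumerate(grid):
        q = validate_parameters(p.replace(**{parameter_name: float(v)}))
        y, ok = _settle(q, y, t_settle, dt)
        if not ok:
            unsettled.append(("up", float(v)))
        up[i] = y

    y = np.array(DEFAULT_INITIAL_STATE, dtype=float)
    for i in range(n - 1, -1, -1):
        v = grid[i]
        q = validate_parameters(p.replace(**{parameter_name: float(v)}))
        y, ok = _settle(q, y, t_settle, dt)
        if not ok:
            unsettled.append(("down", float(v)))
        down[i] = y

    max_gap = float(np.max(np.abs(up[:, 0] - down[:, 0])))
    return HysteresisResult(parameter_name=parameter_name, grid=np.asarray(grid),
                            up_states=up, down_states=down, max_gap=max_gap,
                            unsettled=tuple(unsettled))


@dataclass(frozen=True)
class BranchRegression:
    """OLS fit of steady-state TNF-alpha against the swept parameter."""

    branch_selector: str
    slope: float
    intercept: float
    r_squared: float
    n_points: int


def branch_regression(
    diagram: BifurcationDiagram,
    branch_selector: str = "stable",
    regime: str | None = None,
) -> BranchRegression:
    """Regress steady-state C_T on the swept parameter along one branch.

    ``branch_selector`` picks points by stability class; ``regime``
    optionally restricts further.  Requires >= 3 selected points.
    """
    xs: list[float] = []
    ys: list[float] = []
    for v, pts in zip(diagram.grid, diagram.points):
        for pt in pts:
            if pt.stability != branch_selector:
                continue
            if regime is not None and pt.regime != regime:
                continue
            xs.append(float(v))
            ys.append(pt.state.C_T)
    if len(xs) < 3:
        raise ValueError(f"need >= 3 points on branch {branch_selector!r}, got {len(xs)}")
    x = np.asarray(xs)
    y = np.asarray(ys)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_res = float(np.sum(resid ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot < 1e-30:
        if ss_res < 1e-30:
            r2 = 1.0
        else:
            raise ValueError("zero variance in steady-state C_T with nonzero residuals")
    else:
        r2 = 1.0 - ss_res / ss_tot
    return BranchRegression(branch_selector=branch_selector, slope=float(slope),
                            intercept=float(intercept), r_squared=float(r2),
                            n_points=len(xs))
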