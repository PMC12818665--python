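"""Steady states, Jacobian assembly, stability, and the pre-delay linear solution.

For a fixed IL-10 level the TNF-alpha/IL-6 balance equations are linear, so
every equilibrium of the full system is a root of a single scalar residual in
C_10.  Enumeration therefore reduces to a sign-change scan plus bisection,
which is exhaustive on the scanned interval — no Newton multistart needed.

Two Jacobian conventions are provided for the IL-10 row.  The ``exact`` mode
differentiates the induction term by the product rule.  The ``paper`` mode
keeps only the Hill-derivative contribution with a combined prefactor
(k_10T + k_106) and antisymmetric C_T/C_6 entries — the form used in the
published stability arithmetic; it requires a strictly positive
pro-inflammatory excess C_T > C_6.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy.linalg import expm
from scipy.optimize import bisect

from .model import (
    CytokineState,
    ParameterSet,
    hill_activation,
    rhs,
    validate_parameters,
)

__all__ = [
    "SubsystemSolution",
    "EquilibriumPoint",
    "JacobianResult",
    "LinearSubsystem",
    "solve_pro_subsystem_at_C10",
    "enumerate_equilibria",
    "assemble_jacobian",
    "classify_stability",
    "closed_form_linear_solution",
]

_SINGULAR_TOL = 1e-12
_STABILITY_TOL = 1e-9


class SubsystemSolution(NamedTuple):
    C_T: float
    C_6: float
    #: True when a component is negative (possible when the determinant D < 0).
    nonphysical: bool


def _subsystem_determinant(p: ParameterSet, C_10):
    return ((p.beta_T + p.gamma_T10 * C_10) * (p.beta_6 + p.gamma_610 * C_10)
            - p.k_T6 * p.k_6T)


def _subsystem_arrays(p: ParameterSet, C_10):
    """Vectorized (C_T, C_6, D) of the pro-inflammatory balance at fixed C_10."""
    C_10 = np.asarray(C_10, dtype=float)  # numpy semantics: x/0 -> inf, not raise
    bT = p.beta_T + p.gamma_T10 * C_10
    b6 = p.beta_6 + p.gamma_610 * C_10
    D = bT * b6 - p.k_T6 * p.k_6T
    with np.errstate(divide="ignore", invalid="ignore"):
        C_T = (p.alpha_T * b6 + p.k_T6 * p.alpha_6) / D
        C_6 = (p.alpha_6 * bT + p.k_6T * p.alpha_T) / D
    return C_T, C_6, D


def solve_pro_subsystem_at_C10(p: ParameterSet, C_10: float) -> SubsystemSolution:
    """Solve the TNF-alpha/IL-6 balance equations for a fixed IL-10 level.

    The two balance equations are linear in (C_T, C_6) once C_10 is fixed;
    the unique solution is returned together with a ``nonphysical`` flag if a
    component is negative.

    Raises
    ------
    ValueError
        If the 2x2 system is singular (|D| < 1e-12).
    """
    C_T, C_6, D = _subsystem_arrays(p, float(C_10))
    if abs(D) < _SINGULAR_TOL:
        raise ValueError(
            f"singular pro-inflammatory subsystem at C_10 = {C_10!r} (D = {D!r})")
    return SubsystemSolution(float(C_T), float(C_6), bool(C_T < 0 or C_6 < 0))


@dataclass(frozen=True)
class JacobianResult:
    """Jacobian of the network at a state, with sorted eigenvalues."""

    matrix: np.ndarray
    mode: str
    evaluation_state: CytokineState
    eigenvalues: tuple[complex, complex, complex]


def _sorted_eigenvalues(matrix: np.ndarray) -> tuple[complex, complex, complex]:
    eigs = np.linalg.eigvals(matrix)
    return tuple(sorted((complex(e) for e in eigs), key=lambda z: (z.real, z.imag)))


def assemble_jacobian(
    p: ParameterSet,
    s: CytokineState,
    mode: str = "exact",
    *,
    gate: bool = True,
) -> JacobianResult:
    """Assemble the 3x3 Jacobian at state ``s``.

    Parameters
    ----------
    mode : {"exact", "paper"}
        IL-10-row convention (see module docstring).  ``paper`` requires
        C_T > C_6.
    gate : bool
        Whether the delayed IL-10 induction is active (post-delay regime).
        With the gate off the IL-10 row is simply (0, 0, -beta_10).
    """
    if mode not in ("exact", "paper"):
        raise ValueError(f"mode must be 'exact' or 'paper', got {mode!r}")
    K, n = p.hill_K, p.hill_n
    d = s.C_T - s.C_6
    J = np.array([
        [-p.beta_T - p.gamma_T10 * s.C_10, p.k_T6, -p.gamma_T10 * s.C_T],
        [p.k_6T, -p.beta_6 - p.gamma_610 * s.C_10, -p.gamma_610 * s.C_6],
        [0.0, 0.0, -p.beta_10],
    ])
    if gate:
        if mode == "paper":
            if d <= 0:
                raise ValueError(
                    "mode='paper' requires C_T > C_6 (pro-inflammatory dominance)")
            dHill = n * K ** n * d ** (n - 1) / (K ** n + d ** n) ** 2
            J31 = (p.k_10T + p.k_106) * dHill
            J[2, 0] = J31
            J[2, 1] = -J31
        else:
            if d > 0:
                hill = hill_activation(s.C_T, s.C_6, K, n)
                dHill = n * K ** n * d ** (n - 1) / (K ** n + d ** n) ** 2
            else:
                hill = 0.0
                dHill = 0.0  # gate is flat (clamped) for C_T <= C_6
            drive = p.k_10T * s.C_T + p.k_106 * s.C_6
            J[2, 0] = p.k_10T * hill + drive * dHill
            J[2, 1] = p.k_106 * hill - drive * dHill
    return JacobianResult(matrix=J, mode=mode, evaluation_state=s,
                          eigenvalues=_sorted_eigenvalues(J))


def classify_stability(result) -> str:
    """Classify stability from eigenvalue real parts.

    Accepts a :class:`JacobianResult` or a sequence of eigenvalues.  All real
    parts < -1e-9 gives ``stable``; any real part > 1e-9 gives ``unstable``;
    anything else is ``marginal``.
    """
    eigs = result.eigenvalues if isinstance(result, JacobianResult) else result
    re = [complex(e).real for e in eigs]
    if all(r < -_STABILITY_TOL for r in re):
        return "stable"
    if any(r > _STABILITY_TOL for r in re):
        return "unstable"
    return "marginal"


@dataclass(frozen=True)
class EquilibriumPoint:
    """A steady state with residual, eigenvalues and stability class."""

    state: CytokineState
    regime: str  # "pre_delay" | "post_delay"
    residual_norm: float
    eigenvalues: tuple[complex, complex, complex]
    stability: str


def _scalar_residual(p: ParameterSet, C_10, gate: int):
    """f(C_10): IL-10 balance with (C_T, C_6) eliminated via the 2x2 solve."""
    C_T, C_6, D = _subsystem_arrays(p, C_10)
    hill = hill_activation(C_T, C_6, p.hill_K, p.hill_n)
    f = p.alpha_10 + (p.k_10T * C_T + p.k_106 * C_6) * hill * gate - p.beta_10 * C_10
    return f, D


def _default_C10_max(p: ParameterSet, cap: float) -> float:
    if _subsystem_determinant(p, 0.0) <= _SINGULAR_TOL:
        return cap
    sol = solve_pro_subsystem_at_C10(p, 0.0)
    if sol.nonphysical:
        return cap
    c10_max = 2.0 * (p.alpha_10 + p.k_10T * sol.C_T + p.k_106 * sol.C_6) / p.beta_10
    return max(c10_max, 1e-3)


def enumerate_equilibria(
    p: ParameterSet,
    regime: str = "post_delay",
    C10_max: float | None = None,
    scan_points: int = 10001,
    *,
    fallback_cap: float = 10.0,
) -> list[EquilibriumPoint]:
    """Enumerate all steady states with C_10 in [0, C10_max].

    The scalar residual f(C_10) is scanned on a uniform grid; each bracketed
    sign change is refined by bisection to |dC_10| <= 1e-12 and expanded to a
    full state.  Roots with a negative concentration are discarded.
    Subintervals where the 2x2 pro-inflammatory subsystem is (near-)singular
    are excluded from the scan and reported via a warning.

    In the ``pre_delay`` regime the induction gate is off and the only root
    is alpha_10/beta_10 exactly.
    """
    validate_parameters(p)
    if regime not in ("pre_delay", "post_delay"):
        raise ValueError(f"regime must be 'pre_delay' or 'post_delay', got {regime!r}")
    if scan_points < 100:
        raise ValueError("scan_points must be >= 100")
    gate = 1 if regime == "post_delay" else 0
    if C10_max is None:
        C10_max = _default_C10_max(p, fallback_cap)

    grid = np.linspace(0.0, C10_max, scan_points)
    f, D = _scalar_residual(p, grid, gate)
    valid = np.abs(D) >= _SINGULAR_TOL

    roots: list[float] = []
    excluded: list[tuple[float, float]] = []
    for j in range(scan_points - 1):
        a, b = grid[j], grid[j + 1]
        if not (valid[j] and valid[j + 1]) or D[j] * D[j + 1] < 0:
            excluded.append((float(a), float(b)))
            continue
        fa, fb = f[j], f[j + 1]
        if fa == 0.0:
            roots.append(float(a))
        if fa * fb < 0:
            root = bisect(lambda x: _scalar_residual(p, x, gate)[0], a, b,
                          xtol=1e-13)
            roots.append(float(root))
    if valid[-1] and f[-1] == 0.0:
        roots.append(float(grid[-1]))
    if excluded:
        warnings.warn(
            f"excluded {len(excluded)} scan subinterval(s) with singular "
            f"pro-inflammatory subsystem: {excluded[:3]}...", stacklevel=2)

    deduped: list[float] = []
    for r in sorted(roots):
        if not deduped or r - deduped[-1] > 1e-9:
            deduped.append(r)

    points: list[EquilibriumPoint] = []
    for c10 in deduped:
        sol = solve_pro_subsystem_at_C10(p, c10)
        ct, c6 = max(sol.C_T, 0.0), max(sol.C_6, 0.0)
        if sol.C_T < -1e-9 or sol.C_6 < -1e-9:
            continue  # nonphysical branch
        state = CytokineState(0.0, ct, c6, max(c10, 0.0))
        deriv = rhs(state, p, gate=bool(gate))
        residual = float(np.max(np.abs(deriv.as_array())))
        jac = assemble_jacobian(p, state, mode="exact", gate=bool(gate))
        points.append(EquilibriumPoint(
            state=state, regime=regime, residual_norm=residual,
            eigenvalues=jac.eigenvalues,
            stability=classify_stability(jac)))
    return points


@dataclass(frozen=True)
class LinearSubsystem:
    """The pre-delay TNF-alpha/IL-6 linear system dC/dt = A C + alpha.

    Before the IL-10 gate opens (and absent IL-10 suppression) the
    pro-inflammatory pair evolves autonomously with
    A = [[-beta_T, k_T6], [k_6T, -beta_6]].
    """

    A: np.ndarray
    alpha_vec: np.ndarray
    C0: np.ndarray

    @classmethod
    def from_parameters(cls, p: ParameterSet, C0: Sequence[float]) -> "LinearSubsystem":
        A = np.array([[-p.beta_T, p.k_T6], [p.k_6T, -p.beta_6]], dtype=float)
        return cls(A=A, alpha_vec=np.array([p.alpha_T, p.alpha_6], dtype=float),
                   C0=np.asarray(C0, dtype=float))


def closed_form_linear_solution(sub: LinearSubsystem, t) -> np.ndarray:
    """Matrix-exponential solution C(t) = e^{At} C0 + A^{-1}(e^{At} - I) alpha.

    ``t`` may be a scalar (returns shape (2,)) or a 1-D array (returns shape
    (len(t), 2)).

    Raises
    ------
    ValueError
        If A is singular (|det A| < 1e-12).
    """
    A = np.asarray(sub.A, dtype=float)
    if abs(np.linalg.det(A)) < _SINGULAR_TOL:
        raise ValueError("singular coefficient matrix A")
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t_arr < 0):
        raise ValueError("t must be >= 0")
    out = np.empty((len(t_arr), 2))
    Ainv_alpha = np.linalg.solve(A, sub.alpha_vec)
    for i, ti in enumerate(t_arr):
        eAt = expm(A * ti)
        out[i] = eAt @ sub.C0 + (eAt - np.eye(2)) @ Ainv_alpha
    return out[0] if np.ndim(t) == 0 else out
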