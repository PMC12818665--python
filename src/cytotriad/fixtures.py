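"""Fixture generators with analytically known answers.

These back the property-test suite: each fixture pairs inputs with a
closed-form solution so the numerical machinery can be checked against an
independent oracle.

* ``pure_decay`` — the network with all couplings zeroed; every species
  decays exponentially toward alpha/beta.
* ``linear_2d`` — a randomized stable 2x2 linear system with its
  matrix-exponential solution.
* ``cubic_fold`` — root counting of the saddle-node normal-form family
  q + x - x^3, whose folds sit exactly at q = +/- 2/(3*sqrt(3)).
* ``ishigami`` — the three-input Ishigami function with its analytic Sobol
  variance decomposition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.linalg import expm

from .model import ParameterSet
from .bifurcation import detect_folds
from .equilibria import LinearSubsystem

__all__ = [
    "FixtureSpec",
    "PureDecayFixture",
    "Linear2DFixture",
    "CubicFoldFixture",
    "IshigamiFixture",
    "FreeRange",
    "generate_fixture",
]

FIXTURE_KINDS = ("pure_decay", "linear_2d", "cubic_fold", "ishigami")

#: Analytic fold location of the cubic normal form q + x - x^3.
CUBIC_FOLD_Q = 2.0 / (3.0 * math.sqrt(3.0))


@dataclass(frozen=True)
class FixtureSpec:
    kind: str
    parameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in FIXTURE_KINDS:
            raise ValueError(f"unknown fixture kind {self.kind!r}; "
                             f"expected one of {FIXTURE_KINDS}")


@dataclass(frozen=True)
class FreeRange:
    """Unconstrained sampling range for non-model inputs (e.g. Ishigami)."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError("require low < high")


@dataclass(frozen=True)
class PureDecayFixture:
    """Uncoupled network: C_i(t) = alpha_i/beta_i + (C_i(0) - alpha_i/beta_i) e^{-beta_i t}."""

    parameters: ParameterSet
    solution: Callable[[tuple[float, float, float], float], np.ndarray]


@dataclass(frozen=True)
class Linear2DFixture:
    subsystem: LinearSubsystem
    solution: Callable[[float], np.ndarray]


@dataclass(frozen=True)
class CubicFoldFixture:
    grid: np.ndarray
    counts: np.ndarray
    fold_locations: list[tuple[float, float]]
    analytic_folds: tuple[float, float] = (-CUBIC_FOLD_Q, CUBIC_FOLD_Q)


@dataclass(frozen=True)
class IshigamiFixture:
    func: Callable[[np.ndarray], np.ndarray]
    ranges: tuple[FreeRange, FreeRange, FreeRange]
    first_order: tuple[float, float, float]
    total_order: tuple[float, float, float]


def _cubic_root_count(q: float) -> int:
    """Real-root count of q + x - x^3 (sign changes of the cubic)."""
    roots = np.roots([-1.0, 0.0, 1.0, q])
    return int(np.sum(np.abs(roots.imag) < 1e-9))


def generate_fixture(spec: FixtureSpec):
    """Build the fixture named by ``spec.kind`` (see module docstring)."""
    if spec.kind == "pure_decay":
        base = ParameterSet(**spec.parameters) if spec.parameters else ParameterSet()
        p = base.replace(k_T6=0.0, k_6T=0.0, k_10T=0.0, k_106=0.0,
                         gamma_T10=0.0, gamma_610=0.0,
                         alpha_T=0.0, alpha_6=0.0, alpha_10=0.0)

        def solution(c0: tuple[float, float, float], t: float) -> np.ndarray:
            betas = np.array([p.beta_T, p.beta_6, p.beta_10])
            return np.asarray(c0, dtype=float) * np.exp(-betas * t)

        return PureDecayFixture(parameters=p, solution=solution)

    if spec.kind == "linear_2d":
        rng = np.random.default_rng(spec.seed)
        while True:
            # stable: negative diagonal dominating random off-diagonal coupling
            diag = -rng.uniform(0.5, 3.0, 2)
            off = rng.uniform(0.0, 1.0, 2)
            A = np.array([[diag[0], off[0]], [off[1], diag[1]]])
            if np.all(np.linalg.eigvals(A).real < -1e-6) and abs(np.linalg.det(A)) > 1e-6:
                break
        alpha = rng.uniform(0.0, 0.1, 2)
        C0 = rng.uniform(0.0, 1.0, 2)
        sub = LinearSubsystem(A=A, alpha_vec=alpha, C0=C0)
        Ainv_alpha = np.linalg.solve(A, alpha)

        def solution(t: float) -> np.ndarray:
            eAt = expm(A * t)
            return eAt @ C0 + (eAt - np.eye(2)) @ Ainv_alpha

        return Linear2DFixture(subsystem=sub, solution=solution)

    if spec.kind == "cubic_fold":
        n_points = int(spec.parameters.get("n_points", 81))
        grid = np.linspace(-1.0, 1.0, n_points)
        counts = np.array([_cubic_root_count(q) for q in grid])
        folds = detect_folds(grid, counts, _cubic_root_count)
        return CubicFoldFixture(grid=grid, counts=counts, fold_locations=folds)

    if spec.kind == "ishigami":
        a = float(spec.parameters.get("a", 7.0))
        b = float(spec.parameters.get("b", 0.1))

        def ishigami(X: np.ndarray) -> np.ndarray:
            X = np.atleast_2d(X)
            return (np.sin(X[:, 0]) + a * np.sin(X[:, 1]) ** 2
                    + b * X[:, 2] ** 4 * np.sin(X[:, 0]))

        pi = math.pi
        V1 = 0.5 * (1.0 + b * pi ** 4 / 5.0) ** 2
        V2 = a ** 2 / 8.0
        V13 = b ** 2 * pi ** 8 * 8.0 / 225.0
        V = V1 + V2 + V13
        ranges = tuple(FreeRange(f"x{i+1}", -pi, pi) for i in range(3))
        return IshigamiFixture(
            func=ishigami,
            ranges=ranges,
            first_order=(V1 / V, V2 / V, 0.0),
            total_order=((V1 + V13) / V, V2 / V, V13 / V),
        )

    raise ValueError(f"unknown fixture kind {spec.kind!r}")
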