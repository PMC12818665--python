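"""Core three-cytokine network model.

State variables are the concentrations (nM) of TNF-alpha (``C_T``), IL-6
(``C_6``) and IL-10 (``C_10``).  TNF-alpha and IL-6 form a mutually
amplifying pro-inflammatory loop (cross-activation rates ``k_T6``, ``k_6T``,
an abstraction of NF-kB-mediated co-expression); IL-10 multiplicatively
suppresses both (``gamma_T10``, ``gamma_610``) and is itself induced,
cooperatively and after a transcriptional delay, by the pro-inflammatory
excess ``C_T - C_6`` through a Hill gate.

The governing equations are

    dC_T/dt  = alpha_T + k_T6*C_6 - beta_T*C_T - gamma_T10*C_10*C_T
    dC_6/dt  = alpha_6 + k_6T*C_T - beta_6*C_6 - gamma_610*C_10*C_6
    dC_10/dt = alpha_10
               + (k_10T*C_T + k_106*C_6) * Hill(C_T - C_6) * H(t - t_delay)
               - beta_10*C_10

with Hill(d) = d^n / (K^n + d^n) evaluated on the clamped excess
d = max(C_T - C_6, 0), and H the right-continuous Heaviside step.

Units are nM and hours throughout.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Mapping

import numpy as np

__all__ = [
    "ParameterSet",
    "CytokineState",
    "DerivativeVector",
    "DimensionlessForm",
    "DEFAULT_INITIAL_STATE",
    "validate_parameters",
    "heaviside",
    "hill_activation",
    "rhs",
    "nondimensionalize",
]

#: Default initial concentrations (C_T, C_6, C_10) in nM.
DEFAULT_INITIAL_STATE = (0.1, 0.05, 0.01)


@dataclass(frozen=True)
class ParameterSet:
    """Rate constants and gate parameters of the cytokine network.

    Defaults are the literature-calibrated reference values for acute
    post-stroke inflammation.

    Attributes
    ----------
    alpha_T, alpha_6, alpha_10 : float
        Basal production rates (nM/hr).
    k_T6 : float
        IL-6 -> TNF-alpha cross-activation rate (1/(nM hr)).
    k_6T : float
        TNF-alpha -> IL-6 cross-activation rate (1/(nM hr)).
    k_10T, k_106 : float
        TNF-alpha- and IL-6-driven IL-10 induction rates (1/(nM hr)).
    gamma_T10, gamma_610 : float
        IL-10 suppression strengths on TNF-alpha and IL-6 (1/(nM hr)).
    beta_T, beta_6, beta_10 : float
        First-order decay rates (1/hr).
    hill_n : float
        Hill cooperativity of IL-10 induction (dimensionless, >= 1).
    hill_K : float
        Half-max pro-inflammatory excess for IL-10 induction (nM).
    t_delay : float
        Transcriptional delay before IL-10 induction switches on (hr).
    """

    alpha_T: float = 0.02
    alpha_6: float = 0.01
    alpha_10: float = 0.005
    k_T6: float = 0.45
    k_6T: float = 0.40
    k_10T: float = 0.15
    k_106: float = 0.12
    gamma_T10: float = 0.10
    gamma_610: float = 0.06
    beta_T: float = 1.8
    beta_6: float = 1.2
    beta_10: float = 0.35
    hill_n: float = 5.0
    hill_K: float = 0.3
    t_delay: float = 18.0

    def replace(self, **changes: float) -> "ParameterSet":
        """Return a copy with the given fields replaced (no re-validation)."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, mapping: Mapping[str, float]) -> "ParameterSet":
        """Build from a flat mapping; unknown keys are an error.

        Guards against silent typos such as ``gamma_t10``.
        """
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(mapping) - known)
        if unknown:
            raise ValueError(f"unknown parameter name(s): {', '.join(unknown)}")
        return validate_parameters(cls(**dict(mapping)))


_NONNEGATIVE_FIELDS = (
    "alpha_T", "alpha_6", "alpha_10",
    "k_T6", "k_6T", "k_10T", "k_106",
    "gamma_T10", "gamma_610",
    "t_delay",
)
_POSITIVE_FIELDS = ("beta_T", "beta_6", "beta_10", "hill_K")


def validate_parameters(p: ParameterSet) -> ParameterSet:
    """Check all :class:`ParameterSet` invariants; return ``p`` unchanged.

    Raises
    ------
    ValueError
        Naming the first violated field.
    """
    for f in dataclasses.fields(p):
        v = getattr(p, f.name)
        if not np.isfinite(v):
            raise ValueError(f"{f.name} must be finite, got {v!r}")
    for name in _NONNEGATIVE_FIELDS:
        if getattr(p, name) < 0:
            raise ValueError(f"{name} must be >= 0, got {getattr(p, name)!r}")
    for name in _POSITIVE_FIELDS:
        if getattr(p, name) <= 0:
            raise ValueError(f"{name} must be > 0, got {getattr(p, name)!r}")
    if p.hill_n < 1:
        raise ValueError(f"hill_n must be >= 1, got {p.hill_n!r}")
    return p


@dataclass(frozen=True)
class CytokineState:
    """Cytokine concentrations (nM) at time ``t`` (hr)."""

    t: float
    C_T: float
    C_6: float
    C_10: float

    def __post_init__(self) -> None:
        for name in ("t", "C_T", "C_6", "C_10"):
            v = getattr(self, name)
            if not np.all(np.isfinite(v)):
                raise ValueError(f"{name} must be finite")
        if np.any(np.asarray(self.t) < 0):
            raise ValueError("t must be >= 0")
        for name in ("C_T", "C_6", "C_10"):
            if np.any(np.asarray(getattr(self, name)) < 0):
                raise ValueError(f"{name} must be >= 0")

    def as_array(self) -> np.ndarray:
        return np.array([self.C_T, self.C_6, self.C_10], dtype=float)


@dataclass(frozen=True)
class DerivativeVector:
    """Time derivatives of the three concentrations (nM/hr)."""

    dC_T: float
    dC_6: float
    dC_10: float

    def as_array(self) -> np.ndarray:
        return np.array([self.dC_T, self.dC_6, self.dC_10], dtype=float)


def heaviside(x: float) -> int:
    """Right-continuous unit step: 1 for x >= 0, 0 for x < 0.

    The convention H(0) = 1 makes IL-10 induction switch on exactly at
    t = t_delay.
    """
    if np.ndim(x) == 0:
        return 1 if x >= 0 else 0
    return (np.asarray(x) >= 0).astype(int)


def hill_activation(C_T, C_6, K: float, n: float):
    """Cooperative IL-10 induction gate on the pro-inflammatory excess.

    Returns d^n / (K^n + d^n) with d = max(C_T - C_6, 0).  The clamp keeps
    the gate well defined (zero) whenever IL-6 meets or exceeds TNF-alpha,
    for every cooperativity n >= 1.  Value lies in [0, 1); equals 0.5 at
    d = K; strictly increasing in d.

    Accepts scalars or broadcastable arrays.
    """
    d = np.maximum(np.asarray(C_T, dtype=float) - np.asarray(C_6, dtype=float), 0.0)
    dn = d ** n
    return (dn / (K ** n + dn))[()] if np.ndim(dn) == 0 else dn / (K ** n + dn)


def rhs(s: CytokineState, p: ParameterSet, *, gate: bool | None = None) -> DerivativeVector:
    """Right-hand side of the cytokine network ODEs.

    Parameters
    ----------
    s : CytokineState
        Current state; time enters only through the delay gate.
    p : ParameterSet
    gate : bool, optional
        Override the Heaviside delay gate (used by the integrator to keep
        all stages of a step on one side of the discontinuity).  By default
        the gate is H(s.t - p.t_delay).

    Returns
    -------
    DerivativeVector
    """
    g = heaviside(s.t - p.t_delay) if gate is None else (1 if gate else 0)
    hill = hill_activation(s.C_T, s.C_6, p.hill_K, p.hill_n)
    dC_T = p.alpha_T + p.k_T6 * s.C_6 - p.beta_T * s.C_T - p.gamma_T10 * s.C_10 * s.C_T
    dC_6 = p.alpha_6 + p.k_6T * s.C_T - p.beta_6 * s.C_6 - p.gamma_610 * s.C_10 * s.C_6
    dC_10 = p.alpha_10 + (p.k_10T * s.C_T + p.k_106 * s.C_6) * hill * g - p.beta_10 * s.C_10
    return DerivativeVector(dC_T, dC_6, dC_10)


@dataclass(frozen=True)
class DimensionlessForm:
    """Dimensionless state and the control ratios of the rescaled system.

    Concentrations are scaled by the Hill threshold K (IL-10 additionally by
    the suppression strength gamma_T10) and time by the TNF-alpha decay rate.
    """

    C_tilde_T: float
    C_tilde_6: float
    C_tilde_10: float
    tau: float
    ratio_activation_T: float   # k_T6 / beta_T
    ratio_activation_6: float   # k_6T / beta_6
    ratio_suppression: float    # gamma_610 / gamma_T10
    ratio_delay: float          # beta_10 / beta_T


def nondimensionalize(p: ParameterSet, s: CytokineState) -> DimensionlessForm:
    """Rescale a state to dimensionless variables and report control ratios.

    C~_T = C_T/K, C~_6 = C_6/K, C~_10 = gamma_T10*C_10/K, tau = beta_T*t.

    Raises
    ------
    ValueError
        If gamma_T10 = 0, since both the IL-10 scaling and the suppression
        ratio are then undefined.
    """
    validate_parameters(p)
    if p.gamma_T10 <= 0:
        raise ValueError("gamma_T10 must be > 0 for the dimensionless form "
                         "(IL-10 scaling and suppression ratio undefined)")
    K = p.hill_K
    return DimensionlessForm(
        C_tilde_T=s.C_T / K,
        C_tilde_6=s.C_6 / K,
        C_tilde_10=p.gamma_T10 * s.C_10 / K,
        tau=p.beta_T * s.t,
        ratio_activation_T=p.k_T6 / p.beta_T,
        ratio_activation_6=p.k_6T / p.beta_6,
        ratio_suppression=p.gamma_610 / p.gamma_T10,
        ratio_delay=p.beta_10 / p.beta_T,
    )
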