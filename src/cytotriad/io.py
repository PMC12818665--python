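"""CSV/JSON writers and readers for simulation and analysis results.

All outputs are plain text: RFC-4180 CSV with '.' decimal separator, plus a
JSON run-manifest (parameters, seed, version) written alongside each result
so any run can be reproduced from its outputs alone.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import pandas as pd

from . import __version__
from .model import ParameterSet
from .bifurcation import BifurcationDiagram, HysteresisResult
from .equilibria import EquilibriumPoint
from .sensitivity import SensitivityResult
from .simulate import Trajectory

__all__ = [
    "write_trajectory_csv",
    "read_trajectory_csv",
    "write_equilibria_csv",
    "write_diagram_csv",
    "write_hysteresis_csv",
    "write_sensitivity_csv",
    "write_manifest",
]

_FLOAT_FMT = "%.17g"


def write_manifest(path: str | Path, parameters: ParameterSet,
                   seed: int | None = None, **extra) -> Path:
    """Write the JSON run-manifest next to ``path`` (same stem, .manifest.json)."""
    path = Path(path)
    manifest_path = path.with_suffix(path.suffix + ".manifest.json")
    payload = {
        "version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "parameters": parameters.to_dict(),
        "seed": seed,
        **extra,
    }
    manifest_path.write_text(json.dumps(payload, indent=2) + "\n")
    return manifest_path


def write_trajectory_csv(tr: Trajectory, path: str | Path,
                         seed: int | None = None) -> Path:
    """Trajectory CSV: header ``time_hr,TNF_nM,IL6_nM,IL10_nM``."""
    path = Path(path)
    tr.to_dataframe().to_csv(path, index=False, float_format=_FLOAT_FMT)
    write_manifest(path, tr.parameters, seed=seed,
                   schedule={"boluses": [vars(b) for b in tr.schedule.boluses],
                             "modulations": [vars(m) for m in tr.schedule.modulations]})
    return path


def read_trajectory_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    expected = ["time_hr", "TNF_nM", "IL6_nM", "IL10_nM"]
    if list(df.columns) != expected:
        raise ValueError(f"unexpected columns {list(df.columns)}; expected {expected}")
    return df


def write_equilibria_csv(points: list[EquilibriumPoint], path: str | Path,
                         parameters: ParameterSet | None = None) -> Path:
    """Equilibria report CSV (one row per steady state)."""
    rows = []
    for pt in points:
        eigs = pt.eigenvalues
        rows.append({
            "regime": pt.regime,
            "C10_root_nM": pt.state.C_10,
            "CT_nM": pt.state.C_T,
            "C6_nM": pt.state.C_6,
            "residual": pt.residual_norm,
            "stability": pt.stability,
            "lambda1_re": eigs[0].real, "lambda2_re": eigs[1].real,
            "lambda3_re": eigs[2].real,
            "lambda1_im": eigs[0].imag, "lambda2_im": eigs[1].imag,
            "lambda3_im": eigs[2].imag,
        })
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False, float_format=_FLOAT_FMT)
    if parameters is not None:
        write_manifest(path, parameters)
    return path


def write_diagram_csv(diagram: BifurcationDiagram, path: str | Path,
                      parameters: ParameterSet | None = None) -> Path:
    """Bifurcation diagram CSV: one row per (parameter value, branch)."""
    rows = []
    for v, pts in zip(diagram.grid, diagram.points):
        for j, pt in enumerate(pts):
            rows.append({
                diagram.parameter_name: float(v),
                "branch_index": j,
                "CT_nM": pt.state.C_T,
                "C6_nM": pt.state.C_6,
                "C10_nM": pt.state.C_10,
                "stability": pt.stability,
            })
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False, float_format=_FLOAT_FMT)
    if parameters is not None:
        write_manifest(path, parameters,
                       fold_locations=[list(f) for f in diagram.fold_locations])
    return path


def write_hysteresis_csv(result: HysteresisResult, path: str | Path,
                         parameters: ParameterSet | None = None) -> Path:
    """Hysteresis CSV: attained states for both sweep directions."""
    rows = []
    for direction, states in (("up", result.up_states), ("down", result.down_states)):
        for v, y in zip(result.grid, states):
            rows.append({
                result.parameter_name: float(v),
                "direction": direction,
                "CT_nM": float(y[0]), "C6_nM": float(y[1]), "C10_nM": float(y[2]),
            })
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False, float_format=_FLOAT_FMT)
    if parameters is not None:
        write_manifest(path, parameters, max_gap=result.max_gap)
    return path


def write_sensitivity_csv(result: SensitivityResult, path: str | Path) -> Path:
    """Sensitivity CSV (parameter, S1, ST, CIs) plus a JSON sidecar."""
    path = Path(path)
    rows = [{
        "parameter": name,
        "S1": result.first_order[name],
        "ST": result.total_order[name],
        "S1_ci": result.first_order_ci[name],
        "ST_ci": result.total_order_ci[name],
    } for name in result.parameters]
    pd.DataFrame(rows).to_csv(path, index=False, float_format=_FLOAT_FMT)
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    sidecar.write_text(json.dumps({
        "qoi_name": result.qoi_name,
        "n_base": result.n_base,
        "seed": result.seed,
        "ranges": [{"name": r.name, "low": r.low, "high": r.high}
                   for r in result.ranges],
        "version": __version__,
    }, indent=2) + "\n")
    return path
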