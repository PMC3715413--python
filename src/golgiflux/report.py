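"""Result serialization: tidy profile tables and per-species run reports."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import SpeciesSpec, SteadyStateResult

__all__ = ["RunReport", "SpeciesSummary", "summarize", "write_profiles", "write_report"]

#: significant digits used for CSV output; chosen so a round trip through
#: text reproduces the matrix to the printed precision
CSV_DIGITS = 12


@dataclass(frozen=True)
class SpeciesSummary:
    name: str
    argmax_cisterna: int          # 1-based position of the profile maximum
    peak_value: float
    total: float                  # summed stack content, pre-shift
    er_fraction: float
    monotonicity: str             # increasing | decreasing | unimodal | constant | other
    fitted_exponent: Optional[float] = None
    fit_r_squared: Optional[float] = None


@dataclass
class RunReport:
    """Summary of one converged (or capped) scenario run.

    All summaries are recomputable from the profile table alone (plus the
    ER fractions, which the profile CSV also determines together with the
    scenario configuration).
    """

    scenario: Optional[str]
    parameters: dict
    species: list[dict]
    converged: bool
    n_periods_used: int
    residual: float
    mass_balance_defect: float
    summaries: list[SpeciesSummary] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "scenario": self.scenario,
            "parameters": self.parameters,
            "species": self.species,
            "converged": self.converged,
            "n_periods_used": self.n_periods_used,
            "residual": self.residual,
            "mass_balance_defect": self.mass_balance_defect,
            "summaries": [vars(s).copy() for s in self.summaries],
        }

    def to_text(self) -> str:
        lines = [
            f"scenario: {self.scenario or '<custom>'}   converged: {self.converged} "
            f"({self.n_periods_used} periods, residual {self.residual:.2e})",
            f"{'species':<10} {'argmax':>6} {'peak':>10} {'total':>10} "
            f"{'er_frac':>8}  monotonicity",
        ]
        for s in self.summaries:
            lines.append(
                f"{s.name:<10} {s.argmax_cisterna:>6d} {s.peak_value:>10.4f} "
                f"{s.total:>10.4f} {s.er_fraction:>8.4f}  {s.monotonicity}"
            )
        return "\n".join(lines)


def _monotonicity(profile: np.ndarray, rtol: float = 1e-9) -> str:
    """Classify a profile as increasing/decreasing/unimodal/constant/other."""
    d = np.diff(profile)
    scale = max(float(np.max(np.abs(profile))), 1e-300)
    d = np.where(np.abs(d) <= rtol * scale, 0.0, d)
    if np.all(d == 0):
        return "constant"
    if np.all(d >= 0):
        return "increasing"
    if np.all(d <= 0):
        return "decreasing"
    signs = np.sign(d[d != 0])
    if np.sum(np.diff(signs) != 0) == 1 and signs[0] > 0:
        return "unimodal"
    return "other"


def summarize(result: SteadyStateResult, scenario: Optional[str] = None) -> RunReport:
    """Per-species argmax, peak, totals, ER fractions and shape flags.

    Works on non-converged results too (the report carries the converged
    flag); summaries always reflect the last pre-shift snapshot.
    """
    if scenario is None:
        scenario = result.scenario
    p = result.params
    summaries = []
    for i, spec in enumerate(result.species):
        prof = result.profiles[i]
        fit = (result.fitted_exponent or {}).get(spec.name)
        summaries.append(
            SpeciesSummary(
                name=spec.name,
                argmax_cisterna=int(np.argmax(prof)) + 1,
                peak_value=float(prof.max()),
                total=float(prof.sum()),
                er_fraction=float(result.er_fraction[i]),
                monotonicity=_monotonicity(prof),
                fitted_exponent=None if fit is None else fit["a"],
                fit_r_squared=None if fit is None else fit["r_squared"],
            )
        )
    defect = float(np.max(np.abs(result.mass_balance.defect)))
    return RunReport(
        scenario=scenario,
        parameters={
            "n_cisternae": p.n_cisternae,
            "period": p.period,
            "omega": p.omega,
            "n_sites": p.n_sites,
            "T_ER": p.T_ER,
            "topology": p.topology.value,
            "boundary": p.boundary.value,
            "er_access": p.er_access.value,
            "linear_loading": p.linear_loading,
            "dt": p.dt,
            "tol": p.tol,
            "max_periods": p.max_periods,
        },
        species=[
            {
                "name": s.name,
                "role": s.role.value,
                "K": s.K,
                "kappa": s.kappa,
                "C_init": s.C_init,
                "site_group": s.site_group,
            }
            for s in result.species
        ],
        converged=result.converged,
        n_periods_used=result.n_periods_used,
        residual=float(result.residual),
        mass_balance_defect=defect,
        summaries=summaries,
    )


def write_profiles(
    result: SteadyStateResult,
    species: Sequence[SpeciesSpec],
    path,
    scenario: Optional[str] = None,
) -> Path:
    """Write the tidy profile CSV (deterministic row order).

    Columns: scenario, species, cisterna, concentration and the per-species
    max-normalized concentration (the plotting convention for enzyme
    profiles); rows ordered by species then ascending cisterna.
    """
    path = Path(path)
    frame = result.to_frame()
    frame.insert(0, "scenario", scenario or "custom")
    # species order must follow the configuration, not alphabetical
    order = {s.name: i for i, s in enumerate(species)}
    frame = frame.sort_values(
        ["species", "cisterna"], key=lambda col: col.map(order) if col.name == "species" else col
    ).reset_index(drop=True)
    frame.to_csv(path, index=False, float_format=f"%.{CSV_DIGITS}g")
    return path


def write_report(report: RunReport, path) -> Path:
    """Serialize a RunReport to JSON (schema: golgiflux/schema/report.schema.json)."""
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(report.to_dict(), fh, indent=2)
        fh.write("\n")
    return path
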