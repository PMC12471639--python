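"""Deterministic fixture generation: velocity fields, flow sweeps, curves.

Everything needed to exercise the package is generated from constants; no
external data.  The flow sweep mirrors the five reference operating
conditions, 100-500 mL/min, whose superficial velocities are
0.34-1.70 cm/s.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import physiology as phys
from .channel import build_grid, plug_profile, poiseuille_profile, velocity_to_csv
from .config import RunConfig, save_config
from .parameters import BloodParameters, GasTransportConstants

__all__ = ["FLOW_SWEEP_ML_MIN", "SUPERFICIAL_CM_S", "generate_fixtures",
           "curve_table"]

#: Reference blood flow rates (mL/min) and their superficial velocities (cm/s).
FLOW_SWEEP_ML_MIN = (100.0, 200.0, 300.0, 400.0, 500.0)
SUPERFICIAL_CM_S = (0.34, 0.68, 1.02, 1.36, 1.70)


def curve_table(pressure_grid, species: str = "O2",
                params: BloodParameters | None = None,
                constants: GasTransportConstants | None = None,
                other_pressure: float | None = None) -> pd.DataFrame:
    """Physiology curves over a pressure grid.

    For O2: columns PO2, pH, SO2, content, Deff at fixed PCO2
    (``other_pressure``, default 44 mmHg).  For CO2: columns PCO2, pH,
    SCO2, content, Deff at fixed PO2 (default 35.9 mmHg).
    """
    params = params or BloodParameters()
    constants = constants or GasTransportConstants()
    p = np.asarray(pressure_grid, dtype=float)
    if species.upper() == "O2":
        pco2 = 44.0 if other_pressure is None else float(other_pressure)
        ph = np.full_like(p, phys.solve_acid_base(pco2, params).pH)
        return pd.DataFrame({
            "po2_mmhg": p,
            "ph": ph,
            "so2": np.asarray(phys.so2(p, np.full_like(p, pco2), params, constants)),
            "c_o2_ml_ml": np.asarray(phys.o2_content(p, np.full_like(p, pco2),
                                                     params, constants)),
            "deff_o2_m2_s": np.asarray(phys.deff_o2(p, np.full_like(p, pco2),
                                                    params, constants)),
        })
    if species.upper() == "CO2":
        po2 = 35.9 if other_pressure is None else float(other_pressure)
        ab = phys.solve_acid_base(p, params)
        return pd.DataFrame({
            "pco2_mmhg": p,
            "ph": np.asarray(ab.pH),
            "sco2": np.asarray(phys.sco2(p, np.full_like(p, po2), ab.pH,
                                         params.T, constants, params)),
            "c_co2_ml_ml": np.asarray(phys.co2_content(p, np.full_like(p, po2),
                                                       params, constants)),
            "deff_co2_m2_s": np.asarray(phys.deff_co2(p, np.full_like(p, po2),
                                                      params, constants)),
        })
    raise ValueError(f"unknown species {species!r}")


def generate_fixtures(kind: str, out_dir: str | Path, *,
                      Nx: int = 120, Ny: int = 40, grading: float = 1.06,
                      profile: str = "poiseuille",
                      pressure_range: tuple[float, float] = (1.0, 150.0),
                      n_points: int = 76) -> list[Path]:
    """Write deterministic fixture files and return their paths.

    kind='velocity'
        One velocity CSV per flow condition, discretized on the named grid.
    kind='sweep'
        Five run configs (YAML), one per reference flow rate.
    kind='curves'
        O2 and CO2 physiology curve tables over an inclusive pressure grid.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = RunConfig()
    geometry = cfg.geometry.build()
    grid = build_grid(geometry, Nx, Ny, grading)
    written: list[Path] = []

    if kind == "velocity":
        for q, v_cm in zip(FLOW_SWEEP_ML_MIN, SUPERFICIAL_CM_S):
            mean = v_cm * 1e-2
            field = (plug_profile(grid, mean) if profile == "plug"
                     else poiseuille_profile(grid, mean))
            path = out / f"velocity_{int(q)}ml_min_{profile}.csv"
            velocity_to_csv(field, path)
            written.append(path)
    elif kind == "sweep":
        for q, v_cm in zip(FLOW_SWEEP_ML_MIN, SUPERFICIAL_CM_S):
            c = RunConfig()
            c.velocity.mean_velocity = v_cm * 1e-2
            c.velocity.profile = profile
            c.grid.Nx, c.grid.Ny, c.grid.grading = Nx, Ny, grading
            path = out / f"run_{int(q)}ml_min.yaml"
            save_config(c, path)
            written.append(path)
    elif kind == "curves":
        lo, hi = pressure_range
        pgrid = np.linspace(lo, hi, n_points)
        for species in ("O2", "CO2"):
            path = out / f"curves_{species.lower()}.csv"
            curve_table(pgrid, species).to_csv(path, index=False)
            written.append(path)
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    return written
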