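"""End-to-end run driver: build -> minimize -> sweep -> state map -> tension.

A single JSON-able configuration documents every knob; each run writes CSV
curves, the state-map grid, mesh files, a JSON report and a checksum
manifest, and is bit-reproducible given the seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .energy import MaterialParams
from .flower import BuildSpec
from .inflation import InflationCurve, state_map, sweep_inflation, \
    tension, zero_tension_volume
from .io import write_manifest, write_mesh, write_vtk
from .thermal import TemperatureSchedule, ThermalParams, steady_state_tension, \
    transient_tension


@dataclass
class RunConfig:
    """One document for a full pipeline run (demo-sized defaults)."""

    seed: int = 0
    out_dir: str = "vescomp_run"
    phi: float = 0.14
    alphas: tuple = (1.0, 2.0, 3.0)
    subdivisions: int = 3
    vbar_grid: tuple = tuple(np.round(np.linspace(0.9, 1.0, 6), 6))
    t_over_R: float = 8.3e-5
    nu: float = 0.4
    r_sigma_over_b: tuple = (40.0, 200.0, 1000.0)
    thermal_radius_um: tuple = (5.0, 15.0, 30.0)
    cooling_C_per_min: float = 0.3
    export_vtk: bool = True

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full chain and write all artifacts; returns the report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = MaterialParams(t_over_R=config.t_over_R, nu=config.nu)
    grid = np.asarray(config.vbar_grid, float)

    curves: dict[float, InflationCurve] = {}
    frames = []
    report: dict = {"seed": config.seed, "alphas": {}}
    for alpha in config.alphas:
        spec = BuildSpec(alpha=float(alpha), phi=config.phi,
                         subdivisions=config.subdivisions, seed=config.seed)
        curve = sweep_inflation(spec, grid, params, keep_meshes=True)
        curves[float(alpha)] = curve
        df = curve.to_frame()
        df["tau"] = tension(curve)
        frames.append(df)
        entry = {"truncated": curve.truncated}
        try:
            entry["vbar0"] = zero_tension_volume(curve)
        except ValueError:
            entry["vbar0"] = None
        report["alphas"][str(alpha)] = entry
        final = curve.meshes[-1]
        write_mesh(final, out / f"vesicle_alpha{alpha:g}.ply")
        if config.export_vtk:
            write_vtk(final, out / f"vesicle_alpha{alpha:g}.vtk")
    pd.concat(frames, ignore_index=True).to_csv(out / "inflation_curves.csv",
                                                index=False)

    smap = state_map(curves, grid, np.asarray(config.r_sigma_over_b, float))
    smap.to_csv(out / "state_map.csv", index=False)

    tension_rows = []
    for r_um in config.thermal_radius_um:
        tp = ThermalParams(radius_um=float(r_um),
                           cooling_C_per_min=config.cooling_C_per_min)
        tension_rows.append({"radius_um": r_um,
                             "tau_ss_mN_per_m": steady_state_tension(tp)})
    pd.DataFrame(tension_rows).to_csv(out / "steady_tension.csv", index=False)
    report["steady_tension"] = tension_rows

    (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True,
                                                default=str))
    write_manifest(out, asdict(config), config.seed)
    return report
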