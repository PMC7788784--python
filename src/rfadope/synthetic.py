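"""Synthetic inputs: phantom measurement emulation, sweep grids,
manufactured verification cases, and the bench-experiment reference table.

Every input the pipeline needs is generated here with no external data.
The phantom impedance groups are emulated as Gaussian samples around the
study's reported means and standard deviations; the sweep grid enumerates
the full dopant × zone-size × voltage study; the manufactured cases carry
closed-form answers computed by code paths independent of the solvers they
verify.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .inverse import ImpedanceMeasurement

__all__ = [
    "PHANTOM_GROUPS",
    "SweepGrid",
    "simulate_phantom_measurements",
    "make_sweep_configs",
    "manufactured_cases",
    "exvivo_reference_table",
    "REFERENCE_TISSUE_TABLES",
]

# Measured phantom impedance groups (mean Ω, SD Ω, n) and the conductivities
# the original characterization attributed to cylinder and sphere.
PHANTOM_GROUPS: dict[str, dict] = {
    "agar": {"mean": 322.4, "sd": 2.7, "sigma_cyl": 0.067, "sigma_sphere": 0.067},
    "nacl_1wt": {"mean": 213.6, "sd": 2.4, "sigma_cyl": 0.067, "sigma_sphere": 0.113},
    "nacl_1.5wt": {"mean": 177.5, "sd": 4.1, "sigma_cyl": 0.067, "sigma_sphere": 0.145},
    "aunp_1wt": {"mean": 185.9, "sd": 6.2, "sigma_cyl": 0.067, "sigma_sphere": 0.138},
}


def simulate_phantom_measurements(
    groups: dict[str, dict] | None = None,
    n: int = 10,
    seed: int = 0,
) -> tuple[list[ImpedanceMeasurement], pd.DataFrame]:
    """Draw per-sample phantom impedances for each measurement group.

    Gaussian noise with the group SD around the group mean, reproducible
    under a fixed seed.  Returns the per-group summaries (recomputed from
    the samples) and the tidy per-sample table.
    """
    if n < 2:
        raise ValueError("need at least two samples per group")
    if groups is None:
        groups = PHANTOM_GROUPS
    rng = np.random.default_rng(seed)
    rows = []
    summaries = []
    for name, g in groups.items():
        if g["sd"] < 0:
            raise ValueError("group SD must be non-negative")
        z = g["mean"] + g["sd"] * rng.standard_normal(n)
        for i, zi in enumerate(z):
            rows.append({"group": name, "sample": i, "z_ohm": zi})
        summaries.append(
            ImpedanceMeasurement(
                group=name, n=n, mean_z=float(z.mean()), sd=float(z.std(ddof=1))
            )
        )
    return summaries, pd.DataFrame(rows)


@dataclass(frozen=True)
class SweepGrid:
    """The full simulation study grid: 9 dopant settings × 3 zones × 3 voltages."""

    dopants: tuple = (
        ("none", 0),
        ("nacl", 1),
        ("nacl", 2),
        ("nacl", 5),
        ("nacl", 10),
        ("aunp", 1),
        ("aunp", 2),
        ("aunp", 5),
        ("aunp", 10),
    )
    zone_diameters_cm: tuple = (2.0, 3.0, 4.0)
    voltages: tuple = (50.0, 70.0, 90.0)
    seed: int = 0

    @property
    def size(self) -> int:
        return len(self.dopants) * len(self.zone_diameters_cm) * len(self.voltages)


def make_sweep_configs(grid: SweepGrid | None = None, *, deduplicate_nd: bool = False) -> list[dict]:
    """One run-config record per grid combination.

    Non-doped runs are physically independent of the zone label; with
    ``deduplicate_nd`` they are emitted once per voltage only.
    """
    if grid is None:
        grid = SweepGrid()
    configs = []
    seen_nd = set()
    for dopant, conc in grid.dopants:
        for zone in grid.zone_diameters_cm:
            for v in grid.voltages:
                if deduplicate_nd and dopant == "none":
                    if v in seen_nd:
                        continue
                    seen_nd.add(v)
                configs.append(
                    {
                        "kind": "tissue",
                        "dopant": dopant,
                        "concentration_pct": conc,
                        "doped_zone_cm": 0.0 if dopant == "none" else zone,
                        "v_applied": v,
                        "seed": grid.seed,
                    }
                )
    return configs


def manufactured_cases() -> dict[str, dict]:
    """Solver-verification fixtures with closed-form answers.

    (a) concentric spherical shell conduction: series resistance of nested
        spherical surfaces, Z = (1/4πσ)(1/r_in − 1/r_out);
    (b) insulated uniform-source heating: dT/dt = q/(ρc);
    (c) constant-temperature Arrhenius damage: Ω(t) = A·t·exp(−Ea/RT).

    Each answer is evaluated here from the closed form, independently of
    the FEM/ODE code paths it is used to verify.
    """
    sigma, r_in, r_out = 0.2, 0.005, 0.05
    z_exact = (1.0 / (4.0 * math.pi * sigma)) * (1.0 / r_in - 1.0 / r_out)

    rho_c = 1080.0 * 3455.0
    q = 3.7314e4
    slope = q / rho_c

    A, ea, r_gas = 7.39e39, 2.557e5, 8.314
    t_const, dur = 50.0, 134.0
    omega = A * dur * math.exp(-ea / (r_gas * (t_const + 273.15)))

    return {
        "concentric_shell": {
            "sigma": sigma,
            "r_inner": r_in,
            "r_outer": r_out,
            "impedance_ohm": z_exact,
        },
        "uniform_heating": {
            "q_w_m3": q,
            "rho_c": rho_c,
            "slope_c_per_s": slope,
        },
        "constant_t_damage": {
            "temperature_c": t_const,
            "duration_s": dur,
            "omega": omega,
        },
    }


# Bench (wet-lab) reference results: comparison fixture only, never a model
# input. Columns: transverse/axial coagulation diameters (cm), roll-off (s).
_EXVIVO_ROWS = [
    ("ND", 2.4, 0.2, 3.4, 0.5, 281.0, 31.0),
    ("NaCl", 3.0, 0.4, 3.7, 0.4, 379.0, 12.0),
    ("AuNPs", 3.7, 0.3, 4.1, 0.2, 432.0, 36.0),
]


def exvivo_reference_table() -> pd.DataFrame:
    """The bench-experiment summary (n = 4 per group, mean ± SD)."""
    return pd.DataFrame(
        _EXVIVO_ROWS,
        columns=[
            "group",
            "transverse_cm",
            "transverse_sd",
            "axial_cm",
            "axial_sd",
            "t_rolloff_s",
            "t_rolloff_sd",
        ],
    )


def _table(rows: list[tuple]) -> pd.DataFrame:
    return pd.DataFrame(
        rows,
        columns=[
            "dopant",
            "concentration_pct",
            "z_i_ohm",
            "t100_50v_s",
            "b_50v_cm",
            "a_50v_cm",
            "t100_70v_s",
            "b_70v_cm",
            "a_70v_cm",
            "t100_90v_s",
            "b_90v_cm",
            "a_90v_cm",
        ],
    )


#: Published simulation-sweep results, keyed by doped-zone diameter (cm).
#: Used only by the table-reproduction report to print relative deviations.
REFERENCE_TISSUE_TABLES: dict[float, pd.DataFrame] = {
    2.0: _table(
        [
            ("none", 0, 87.7, 457.0, 2.7, 4.4, 94.5, 1.6, 3.8, 31.5, 1.0, 3.7),
            ("nacl", 1, 84.6, 454.0, 2.8, 4.3, 95.0, 1.7, 4.0, 35.0, 1.2, 3.7),
            ("nacl", 2, 82.0, 452.0, 2.8, 4.3, 97.5, 1.7, 4.0, 35.5, 1.2, 3.7),
            ("nacl", 5, 75.5, 457.0, 3.1, 4.6, 103.0, 1.9, 4.0, 36.0, 1.3, 3.8),
            ("nacl", 10, 67.8, 450.0, 3.5, 5.0, 109.5, 2.2, 4.2, 37.5, 1.3, 3.9),
            ("aunp", 1, 78.0, 456.0, 3.0, 4.5, 101.0, 1.8, 4.0, 35.5, 1.2, 3.6),
            ("aunp", 2, 71.5, 451.0, 3.2, 4.7, 106.5, 2.0, 4.1, 36.5, 1.3, 3.8),
            ("aunp", 5, 60.0, 448.0, 3.7, 4.8, 120.5, 2.6, 4.2, 41.0, 1.5, 4.0),
            ("aunp", 10, 51.6, 479.0, 4.4, 5.0, 144.0, 3.2, 4.4, 49.5, 2.3, 4.0),
        ]
    ),
    3.0: _table(
        [
            ("none", 0, 87.7, 465.5, 2.7, 4.4, 94.5, 1.6, 3.8, 31.5, 1.0, 3.7),
            ("nacl", 1, 82.5, 438.0, 2.6, 4.4, 92.0, 1.8, 3.9, 32.0, 1.2, 3.8),
            ("nacl", 2, 78.0, 421.5, 2.7, 4.5, 90.0, 1.8, 4.0, 31.5, 1.2, 3.8),
            ("nacl", 5, 67.7, 392.0, 2.7, 4.6, 86.5, 1.8, 4.2, 30.0, 1.2, 3.8),
            ("nacl", 10, 57.0, 382.0, 3.1, 4.8, 87.0, 1.8, 4.2, 30.5, 1.3, 3.9),
            ("aunp", 1, 71.7, 402.0, 2.7, 4.5, 88.0, 1.8, 4.1, 30.5, 1.3, 3.7),
            ("aunp", 2, 62.0, 385.0, 3.0, 4.8, 86.5, 1.8, 4.2, 30.0, 1.3, 3.8),
            ("aunp", 5, 47.6, 399.5, 3.0, 4.8, 97.8, 1.9, 4.3, 34.0, 1.3, 4.0),
            ("aunp", 10, 38.0, 468.0, 4.5, 5.5, 126.5, 2.5, 4.8, 43.5, 1.7, 4.2),
        ]
    ),
    4.0: _table(
        [
            ("none", 0, 87.7, 440.0, 2.7, 4.4, 94.5, 1.6, 3.8, 31.5, 1.0, 3.7),
            ("nacl", 1, 81.4, 400.0, 2.7, 4.4, 87.0, 1.6, 3.9, 30.0, 1.2, 3.6),
            ("nacl", 2, 76.0, 367.0, 2.6, 4.4, 80.0, 1.7, 3.9, 29.0, 1.2, 3.6),
            ("nacl", 5, 64.0, 306.0, 2.5, 4.3, 66.0, 1.7, 3.9, 25.5, 1.2, 3.6),
            ("nacl", 10, 52.0, 269.0, 2.5, 4.4, 55.0, 1.7, 3.8, 22.5, 1.2, 3.4),
            ("aunp", 1, 69.0, 327.0, 2.5, 4.4, 71.0, 1.7, 3.9, 27.0, 1.2, 3.6),
            ("aunp", 2, 58.0, 287.0, 2.5, 4.4, 60.0, 1.7, 3.9, 23.5, 1.2, 3.6),
            ("aunp", 5, 42.0, 245.0, 2.5, 4.4, 50.5, 1.6, 3.8, 20.5, 1.2, 3.6),
            ("aunp", 10, 31.9, 265.0, 2.6, 4.9, 54.5, 1.7, 3.9, 21.5, 1.2, 3.6),
        ]
    ),
}


def write_fixtures(out_dir: str | Path, seed: int = 20210106, n: int = 10) -> None:
    """Write the fixture tree (CSV + config records) under ``out_dir``."""
    import yaml

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summaries, samples = simulate_phantom_measurements(n=n, seed=seed)
    samples.to_csv(out / "phantom_samples.csv", index=False)
    pd.DataFrame(
        [{"group": s.group, "n": s.n, "mean_z": s.mean_z, "sd": s.sd} for s in summaries]
    ).to_csv(out / "phantom_summary.csv", index=False)
    exvivo_reference_table().to_csv(out / "exvivo_reference.csv", index=False)
    with open(out / "sweep_configs.yaml", "w") as f:
        yaml.safe_dump(
            {"seed": seed, "configs": make_sweep_configs(SweepGrid(seed=seed))}, f
        )
    with open(out / "manufactured_cases.yaml", "w") as f:
        yaml.safe_dump(manufactured_cases(), f)
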