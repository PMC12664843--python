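"""Seeded synthetic fixtures emulating a two-field ubiquitin-like panel.

The default preset stands in for a perdeuterated-ubiquitin style dataset
recorded at 277 K on 600 and 800 MHz spectrometers: a majority of flat
residues, a cluster of sites exchanging on a ~55 microsecond timescale with
assorted chemical-shift variances, and one faster ~12.5 microsecond site.
All residue identities and parameter values are synthetic stand-ins chosen to
be representative, not measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .extraction import IntensityTable
from .io import write_intensity_table, write_panel, write_schedule
from .scheduler import CpmgSchedule, PulseCalibration, build_schedule
from .simulator import ExchangeParams, simulate_experiment

__all__ = ["FixtureSpec", "ubiquitin_like_panel", "default_spec", "generate_fixture"]

#: 90-degree pulse calibrations of the two emulated spectrometers (seconds)
TAU90_BY_FIELD = {600.0: 8.4e-6, 800.0: 7.6e-6}


def _distinct_n_grid(n_points: int, t_cpmg: float = 0.040) -> tuple[float, ...]:
    """Log-spaced CPMG frequencies realizing ``n_points`` distinct loop counters.

    Spans 200 Hz to 30 kHz (N = 8 to 1200 at a 40 ms constant time) on a
    roughly geometric grid of multiples of 4.
    """
    grid = 4 * np.unique(np.round(np.geomspace(8, 1200, 4 * n_points) / 4.0).astype(int))
    idx = np.unique(np.round(np.linspace(0, len(grid) - 1, n_points)).astype(int))
    return tuple(float(grid[i]) / t_cpmg for i in idx)


#: unique dispersion points per field: 35 at 600 MHz and 24 at 800 MHz,
#: the plane counts of the emulated two-field acquisition
_DEFAULT_TARGETS = {
    600.0: _distinct_n_grid(35),
    800.0: _distinct_n_grid(24),
}

#: repeat planes per field: four duplicated frequencies at 600 MHz, three at
#: 800 MHz, again mirroring the emulated acquisition
_DEFAULT_REPEATS = {
    600.0: (500.0, 2600.0, 7600.0, 22500.0),
    800.0: (500.0, 5300.0, 18700.0),
}

#: assorted chemical-shift variances (ppm^2) of the slow-cluster residues
_CLUSTER_PHI_PPM2 = (0.002, 0.003, 0.004, 0.006, 0.008, 0.010)
_CLUSTER_IDS = ("I23", "K33", "I36", "E51", "T55", "I61")
_FAST_ID = "T09"
_FAST_TAU_US = 12.5
_CLUSTER_TAU_US = 55.0
_FAST_PHI_PPM2 = 0.015


@dataclass
class FixtureSpec:
    """Everything needed to generate one reproducible synthetic dataset."""

    residues: list[tuple[str, ExchangeParams]]
    fields: tuple[float, ...] = (600.0, 800.0)
    tau90_by_field: dict[float, float] = dataclass_field(
        default_factory=lambda: dict(TAU90_BY_FIELD)
    )
    t_cpmg: float = 0.040
    divisor: int = 4
    targets_by_field: dict[float, tuple[float, ...]] = dataclass_field(
        default_factory=lambda: dict(_DEFAULT_TARGETS)
    )
    repeats_by_field: dict[float, tuple[float, ...]] = dataclass_field(
        default_factory=lambda: dict(_DEFAULT_REPEATS)
    )
    noise_sigma: float = 0.004
    seed: int = 1

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("residue panel must be non-empty")
        for f in self.fields:
            if f not in self.tau90_by_field:
                raise ValueError(f"no tau90 calibration for field {f} MHz")
            if f not in self.targets_by_field:
                raise ValueError(f"no frequency targets for field {f} MHz")


def ubiquitin_like_panel(seed: int = 1) -> list[tuple[str, ExchangeParams]]:
    """Synthetic residue panel: 20 flat sites, 6 slow-cluster sites, 1 fast site.

    Flat residues draw R2,0 uniformly from [8, 25] 1/s and R1 from
    [0.8, 1.5] 1/s (perdeuterated amide protons at low temperature).
    Exchanging sites share p_A = 0.95; their shift differences are derived
    from the preset phi_ex values via dw = sqrt(phi / (p_A p_B)).
    """
    rng = np.random.default_rng(seed)
    residues: list[tuple[str, ExchangeParams]] = []
    for i in range(20):
        r1 = float(rng.uniform(0.8, 1.5))
        r2 = float(rng.uniform(8.0, 25.0))
        residues.append(
            (
                f"F{i + 1:02d}",
                ExchangeParams(p_a=0.95, k_ex=0.0, delta_omega_ppm=0.0, r1=r1, r2=r2),
            )
        )
    p_a = 0.95
    for rid, phi in zip(_CLUSTER_IDS, _CLUSTER_PHI_PPM2):
        dw = float(np.sqrt(phi / (p_a * (1 - p_a))))
        residues.append(
            (
                rid,
                ExchangeParams(
                    p_a=p_a,
                    k_ex=1.0 / (_CLUSTER_TAU_US * 1e-6),
                    delta_omega_ppm=dw,
                    r1=float(rng.uniform(0.9, 1.4)),
                    r2=float(rng.uniform(8.0, 14.0)),
                ),
            )
        )
    dw_fast = float(np.sqrt(_FAST_PHI_PPM2 / (p_a * (1 - p_a))))
    residues.append(
        (
            _FAST_ID,
            ExchangeParams(
                p_a=p_a,
                k_ex=1.0 / (_FAST_TAU_US * 1e-6),
                delta_omega_ppm=dw_fast,
                r1=1.2,
                r2=10.0,
            ),
        )
    )
    return residues


def default_spec(seed: int = 1, noise_sigma: float = 0.004) -> FixtureSpec:
    """The ubiquitin-like two-field preset with its default noise level."""
    return FixtureSpec(
        residues=ubiquitin_like_panel(seed), seed=seed, noise_sigma=noise_sigma
    )


def ground_truth_frame(spec: FixtureSpec) -> pd.DataFrame:
    rows = []
    for rid, p in spec.residues:
        exchanging = p.has_exchange
        rows.append(
            {
                "residue": rid,
                "p_a": p.p_a,
                "k_ex_s": p.k_ex,
                "tau_ex_us": 1e6 / p.k_ex if p.k_ex > 0 else np.nan,
                "delta_omega_ppm": p.delta_omega_ppm,
                "phi_ex_ppm2": p.phi_ex_ppm2(),
                "r1_s": p.r1,
                "r2_s": p.r2,
                "exchanging": exchanging,
            }
        )
    return pd.DataFrame(rows)


def generate_fixture(
    spec: FixtureSpec, out_dir: Optional[str | Path] = None
) -> tuple[dict[float, IntensityTable], pd.DataFrame, dict[float, CpmgSchedule]]:
    """Simulate the panel at every field of the spec.

    Returns the per-field intensity tables, the ground-truth parameter table
    and the per-field schedules; writes them all as plain text when
    ``out_dir`` is given.  Identical specs produce byte-identical files.
    """
    tables: dict[float, IntensityTable] = {}
    schedules: dict[float, CpmgSchedule] = {}
    seed_seq = np.random.SeedSequence(spec.seed)
    field_seeds = seed_seq.generate_state(len(spec.fields)) % (2**31)
    for field_mhz, field_seed in zip(spec.fields, field_seeds):
        cal = PulseCalibration(
            tau90=spec.tau90_by_field[field_mhz], larmor_mhz=field_mhz
        )
        schedule = build_schedule(
            spec.targets_by_field[field_mhz],
            spec.t_cpmg,
            cal,
            divisor=spec.divisor,
            repeats=spec.repeats_by_field.get(field_mhz, ()),
        )
        schedules[field_mhz] = schedule
        tables[field_mhz] = simulate_experiment(
            schedule,
            spec.residues,
            larmor_mhz=field_mhz,
            noise_sigma=spec.noise_sigma,
            seed=int(field_seed),
        )
    truth = ground_truth_frame(spec)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for field_mhz in spec.fields:
            write_schedule(schedules[field_mhz], out / f"schedule_{field_mhz:g}.tsv")
            write_intensity_table(
                tables[field_mhz], out / f"intensities_{field_mhz:g}.tsv"
            )
        write_panel(spec.residues, out / "panel.tsv")
        truth.to_csv(out / "ground_truth.tsv", sep="\t", index=False)
    return tables, truth, schedules
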