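"""Effective transverse relaxation rates from pseudo-3D peak intensities.

In a constant-time CPMG experiment every plane shares the same relaxation
period ``T_CPMG``, so the effective rate follows directly from the intensity
ratio to the reference plane recorded without the CPMG period:

    R2,eff(nu_CPMG) = -ln[ I(nu_CPMG) / I(ref) ] / T_CPMG

Per-point uncertainties come from repeat planes: frequencies acquired more
than once give per-residue rate standard deviations which are pooled and
attached to every point of that residue's dispersion curve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

logger = logging.getLogger("ecpmg")

__all__ = [
    "IntensityTable",
    "DispersionCurve",
    "r2eff_from_intensity",
    "sigma_from_repeats",
    "extract_curves",
]

#: column order of the tabular payload of an IntensityTable
TABLE_COLUMNS = ["residue", "plane", "nu_cpmg_hz", "intensity", "is_repeat"]


@dataclass
class IntensityTable:
    """Peak intensities per residue per plane of one pseudo-3D experiment.

    ``data`` holds one row per (residue, plane) with columns ``residue``,
    ``plane``, ``nu_cpmg_hz`` (NaN for the reference plane), ``intensity`` and
    ``is_repeat``.  Metadata carries the constant CPMG time, the spectrometer
    frequency and an optional temperature label.
    """

    data: pd.DataFrame
    t_cpmg: float
    larmor_mhz: float
    temperature: Optional[str] = None

    def __post_init__(self) -> None:
        missing = [c for c in TABLE_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"intensity table is missing columns {missing}")
        if self.t_cpmg <= 0:
            raise ValueError(f"T_cpmg must be positive, got {self.t_cpmg}")

    @property
    def residues(self) -> list[str]:
        return list(dict.fromkeys(self.data["residue"]))


@dataclass
class DispersionCurve:
    """Per-residue, per-field series of (nu_CPMG, R2,eff, sigma)."""

    residue_id: str
    larmor_mhz: float
    nu_cpmg: np.ndarray
    r2eff: np.ndarray
    sigma: np.ndarray
    n_avg: np.ndarray = field(default=None)  # type: ignore[assignment]
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.nu_cpmg = np.asarray(self.nu_cpmg, dtype=float)
        self.r2eff = np.asarray(self.r2eff, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.n_avg is None:
            self.n_avg = np.ones_like(self.nu_cpmg, dtype=int)
        self.n_avg = np.asarray(self.n_avg, dtype=int)
        if self.nu_cpmg.size:
            if np.any(self.nu_cpmg <= 0):
                raise ValueError("nu_cpmg values must be strictly positive")
            if np.any(np.diff(self.nu_cpmg) <= 0):
                raise ValueError("nu_cpmg values must be strictly increasing")
            if np.any(self.sigma < 0):
                raise ValueError("sigma values must be non-negative")

    def __len__(self) -> int:
        return self.nu_cpmg.size


def r2eff_from_intensity(
    intensity: float | np.ndarray, i_ref: float, t_cpmg: float
) -> float | np.ndarray:
    """Constant-time rate from an intensity ratio to the reference plane.

    Negative results (intensity above the reference) are returned as-is, not
    clipped — downstream consumers decide how to treat them.
    """
    if t_cpmg <= 0:
        raise ValueError(f"T_cpmg must be positive, got {t_cpmg}")
    if i_ref <= 0:
        raise ValueError(f"reference intensity must be positive, got {i_ref}")
    arr = np.asarray(intensity, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("intensity must be positive (log of the ratio is undefined)")
    out = -np.log(arr / i_ref) / t_cpmg
    return float(out) if np.isscalar(intensity) else out


def _reference_intensity(group: pd.DataFrame, residue: str) -> float:
    refs = group[group["nu_cpmg_hz"].isna()]
    if len(refs) != 1:
        raise ValueError(
            f"residue {residue}: expected exactly one reference record, found {len(refs)}"
        )
    i_ref = float(refs["intensity"].iloc[0])
    if i_ref <= 0:
        raise ValueError(f"residue {residue}: reference intensity must be positive")
    return i_ref


def sigma_from_repeats(
    table: IntensityTable, default_sigma: float = 0.2
) -> dict[str, float]:
    """Per-residue R2,eff uncertainty pooled over repeated frequencies.

    For each frequency acquired more than once the intensities are converted
    to rates and the pooled sigma is the root mean square of the per-frequency
    sample variances (for a duplicate pair differing by ``d`` this is
    ``d / sqrt(2)``).  Residues without any repeated frequency fall back to
    ``default_sigma`` with a logged warning.
    """
    sigmas: dict[str, float] = {}
    for residue, group in table.data.groupby("residue", sort=False):
        try:
            i_ref = _reference_intensity(group, str(residue))
        except ValueError:
            continue
        cpmg = group[group["nu_cpmg_hz"].notna()]
        variances = []
        for _, sub in cpmg.groupby("nu_cpmg_hz"):
            if len(sub) >= 2:
                rates = r2eff_from_intensity(
                    sub["intensity"].to_numpy(), i_ref, table.t_cpmg
                )
                variances.append(float(np.var(rates, ddof=1)))
        if variances:
            sigmas[str(residue)] = float(np.sqrt(np.mean(variances)))
        else:
            logger.warning(
                "residue %s has no repeat planes; using default sigma %.3g 1/s",
                residue,
                default_sigma,
            )
            sigmas[str(residue)] = default_sigma
    return sigmas


def extract_curves(
    table: IntensityTable, default_sigma: float = 0.2
) -> list[DispersionCurve]:
    """Convert an intensity table into one dispersion curve per residue.

    Repeat measurements at the same frequency are averaged into a single
    point (the pre-averaging rates feed the repeat-based error estimate);
    residues lacking a valid reference record are skipped with a warning.
    """
    sigmas = sigma_from_repeats(table, default_sigma=default_sigma)
    curves: list[DispersionCurve] = []
    for residue, group in table.data.groupby("residue", sort=False):
        residue = str(residue)
        try:
            i_ref = _reference_intensity(group, residue)
        except ValueError as exc:
            logger.warning("skipping residue %s: %s", residue, exc)
            continue
        cpmg = group[group["nu_cpmg_hz"].notna()]
        flags: list[str] = []
        if cpmg.empty:
            logger.warning("residue %s has only a reference plane; empty curve", residue)
            curves.append(
                DispersionCurve(
                    residue_id=residue,
                    larmor_mhz=table.larmor_mhz,
                    nu_cpmg=np.array([]),
                    r2eff=np.array([]),
                    sigma=np.array([]),
                    n_avg=np.array([], dtype=int),
                    flags=["empty"],
                )
            )
            continue
        rates = r2eff_from_intensity(cpmg["intensity"].to_numpy(), i_ref, table.t_cpmg)
        frame = pd.DataFrame({"nu": cpmg["nu_cpmg_hz"].to_numpy(), "r2eff": rates})
        agg = (
            frame.groupby("nu", sort=True)["r2eff"]
            .agg(["mean", "count"])
            .reset_index()
        )
        if np.any(agg["mean"].to_numpy() < 0):
            flags.append("negative_r2eff")
        sigma = sigmas[residue]
        curves.append(
            DispersionCurve(
                residue_id=residue,
                larmor_mhz=table.larmor_mhz,
                nu_cpmg=agg["nu"].to_numpy(),
                r2eff=agg["mean"].to_numpy(),
                sigma=np.full(len(agg), sigma),
                n_avg=agg["count"].to_numpy(),
                flags=flags,
            )
        )
    return curves
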