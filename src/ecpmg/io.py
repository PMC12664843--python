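"""Plain-text readers and writers for schedules, tables, curves and reports.

All formats are tab- or comma-separated text with ``#key=value`` metadata
comment lines, matching the artifact's boundary: peak intensities and fit
parameters, never binary spectral data.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .extraction import TABLE_COLUMNS, DispersionCurve, IntensityTable
from .fitting import FitResult
from .scheduler import CpmgSchedule, PulseCalibration, compute_entry
from .simulator import ExchangeParams

__all__ = [
    "write_schedule",
    "read_schedule",
    "write_intensity_table",
    "read_intensity_table",
    "write_curves",
    "read_curves",
    "write_panel",
    "read_panel",
    "write_fit_report",
    "read_fit_report",
    "format_fit_table",
    "read_config",
]


def _us(seconds: float | None) -> str:
    """Seconds formatted in microseconds with 4 significant digits."""
    if seconds is None:
        return "NA"
    return f"{seconds * 1e6:.4g}"


def _read_metadata(path: Path) -> tuple[dict[str, str], list[str]]:
    meta: dict[str, str] = {}
    body: list[str] = []
    for line in path.read_text().splitlines():
        if line.startswith("#"):
            if "=" in line:
                key, _, value = line[1:].partition("=")
                meta[key.strip()] = value.strip()
        elif line.strip():
            body.append(line)
    return meta, body


# -- schedules ---------------------------------------------------------------


def write_schedule(schedule: CpmgSchedule, path: str | Path) -> None:
    """Write a schedule as TSV, one row per plane in acquisition order.

    The metadata block carries the exact timing inputs; delays are printed in
    microseconds for humans, but reading reconstructs them exactly from the
    loop counters, so the round trip is lossless.
    """
    path = Path(path)
    lines = [
        f"#T_cpmg_s={schedule.t_cpmg!r}",
        f"#tau90_s={schedule.calibration.tau90!r}",
        f"#larmor_mhz={schedule.calibration.larmor_mhz!r}",
        f"#divisor={schedule.divisor}",
        "N\tnu_cpmg_hz\ttau_cp_us\tdelta_us\tis_reference\tis_repeat",
    ]
    for e in schedule.entries:
        lines.append(
            "\t".join(
                [
                    str(e.N),
                    f"{e.nu_cpmg:.10g}",
                    _us(e.tau_cp),
                    _us(e.delta),
                    str(int(e.is_reference)),
                    str(int(e.is_repeat)),
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n")


def read_schedule(path: str | Path) -> CpmgSchedule:
    """Read a schedule TSV, reconstructing exact delays from the loop counters."""
    path = Path(path)
    meta, body = _read_metadata(path)
    t_cpmg = float(meta["T_cpmg_s"])
    cal = PulseCalibration(tau90=float(meta["tau90_s"]), larmor_mhz=float(meta["larmor_mhz"]))
    divisor = int(meta["divisor"])
    header, *rows = body
    cols = header.split("\t")
    idx = {c: i for i, c in enumerate(cols)}
    parsed = [r.split("\t") for r in rows]
    n_max = max((int(r[idx["N"]]) for r in parsed), default=0)
    entries = []
    for r in parsed:
        n = int(r[idx["N"]])
        entry = compute_entry(
            n, t_cpmg, cal, n_max, is_repeat=bool(int(r[idx["is_repeat"]]))
        )
        printed_nu = float(r[idx["nu_cpmg_hz"]])
        if not math.isclose(printed_nu, entry.nu_cpmg, rel_tol=1e-9, abs_tol=1e-9):
            raise ValueError(
                f"schedule file is inconsistent: N={n} prints nu={printed_nu} "
                f"but N/T_cpmg={entry.nu_cpmg}"
            )
        entries.append(entry)
    return CpmgSchedule(
        t_cpmg=t_cpmg, calibration=cal, n_max=n_max, divisor=divisor, entries=tuple(entries)
    )


# -- intensity tables --------------------------------------------------------


def write_intensity_table(table: IntensityTable, path: str | Path) -> None:
    path = Path(path)
    lines = [
        f"#T_cpmg_s={table.t_cpmg!r}",
        f"#larmor_mhz={table.larmor_mhz!r}",
    ]
    if table.temperature is not None:
        lines.append(f"#temperature={table.temperature}")
    lines.append("\t".join(TABLE_COLUMNS))
    for row in table.data.itertuples(index=False):
        nu = "REF" if pd.isna(row.nu_cpmg_hz) else f"{row.nu_cpmg_hz:.10g}"
        lines.append(
            "\t".join(
                [
                    str(row.residue),
                    str(int(row.plane)),
                    nu,
                    f"{row.intensity:.12g}",
                    str(int(bool(row.is_repeat))),
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n")


def read_intensity_table(path: str | Path) -> IntensityTable:
    path = Path(path)
    meta, body = _read_metadata(path)
    header, *rows = body
    cols = header.split("\t")
    idx = {c: i for i, c in enumerate(cols)}
    records = []
    for r in rows:
        f = r.split("\t")
        nu_raw = f[idx["nu_cpmg_hz"]].strip()
        records.append(
            {
                "residue": f[idx["residue"]],
                "plane": int(f[idx["plane"]]),
                "nu_cpmg_hz": np.nan if nu_raw in ("", "REF") else float(nu_raw),
                "intensity": float(f[idx["intensity"]]),
                "is_repeat": bool(int(f[idx["is_repeat"]])),
            }
        )
    return IntensityTable(
        data=pd.DataFrame(records, columns=TABLE_COLUMNS),
        t_cpmg=float(meta["T_cpmg_s"]),
        larmor_mhz=float(meta["larmor_mhz"]),
        temperature=meta.get("temperature"),
    )


# -- dispersion curves -------------------------------------------------------

_CURVE_HEADER = "residue,larmor_mhz,nu_cpmg_hz,r2eff_s,sigma_s"


def write_curves(curves: Sequence[DispersionCurve], path: str | Path) -> None:
    path = Path(path)
    lines = [_CURVE_HEADER]
    for c in curves:
        for nu, r2, sig in zip(c.nu_cpmg, c.r2eff, c.sigma):
            lines.append(
                f"{c.residue_id},{c.larmor_mhz:.10g},{nu:.10g},{r2:.12g},{sig:.12g}"
            )
    path.write_text("\n".join(lines) + "\n")


def read_curves(path: str | Path) -> list[DispersionCurve]:
    frame = pd.read_csv(path)
    curves = []
    for (residue, field_mhz), group in frame.groupby(
        ["residue", "larmor_mhz"], sort=False
    ):
        group = group.sort_values("nu_cpmg_hz")
        curves.append(
            DispersionCurve(
                residue_id=str(residue),
                larmor_mhz=float(field_mhz),
                nu_cpmg=group["nu_cpmg_hz"].to_numpy(),
                r2eff=group["r2eff_s"].to_numpy(),
                sigma=group["sigma_s"].to_numpy(),
            )
        )
    return curves


# -- spin-system panels ------------------------------------------------------

_PANEL_HEADER = "residue\tp_a\tk_ex_s\tdelta_omega_ppm\tr1_s\tr2_s\toffset_ppm"


def write_panel(residues: Sequence[tuple[str, ExchangeParams]], path: str | Path) -> None:
    path = Path(path)
    lines = [_PANEL_HEADER]
    for residue, p in residues:
        lines.append(
            f"{residue}\t{p.p_a:.10g}\t{p.k_ex:.10g}\t{p.delta_omega_ppm:.10g}"
            f"\t{p.r1:.10g}\t{p.r2:.10g}\t{p.offset_ppm:.10g}"
        )
    path.write_text("\n".join(lines) + "\n")


def read_panel(path: str | Path) -> list[tuple[str, ExchangeParams]]:
    frame = pd.read_csv(path, sep="\t", comment="#")
    residues = []
    for row in frame.itertuples(index=False):
        residues.append(
            (
                str(row.residue),
                ExchangeParams(
                    p_a=float(row.p_a),
                    k_ex=float(row.k_ex_s),
                    delta_omega_ppm=float(row.delta_omega_ppm),
                    r1=float(row.r1_s),
                    r2=float(row.r2_s),
                    offset_ppm=float(row.offset_ppm),
                ),
            )
        )
    return residues


# -- fit reports -------------------------------------------------------------


def _result_record(result: FitResult) -> dict:
    rec = {
        "residue": result.residue_id,
        "classification": result.classification,
        "converged": result.converged,
        "n_points": result.n_points,
        "chi2": None if math.isnan(result.chi2) else result.chi2,
        "tau_ex_us": None if math.isnan(result.tau_ex) else result.tau_ex * 1e6,
        "tau_ex_err_us": None
        if math.isnan(result.tau_ex_err)
        else result.tau_ex_err * 1e6,
        "flags": list(result.flags),
        "fields": {},
    }
    for field_mhz, ff in sorted(result.field_fits.items()):
        rec["fields"][f"{field_mhz:g}"] = {
            "phi_ex_ppm2": ff.phi_ex_ppm2,
            "phi_ex_err_ppm2": None
            if math.isnan(ff.phi_ex_err_ppm2)
            else ff.phi_ex_err_ppm2,
            "r2_0_s": ff.r2_0,
            "r2_0_err_s": None if math.isnan(ff.r2_0_err) else ff.r2_0_err,
        }
    if result.flat_summary is not None:
        rec["flat_summary"] = {
            f"{field_mhz:g}": vals for field_mhz, vals in sorted(result.flat_summary.items())
        }
    return rec


def write_fit_report(results: Sequence[FitResult], path: str | Path, config=None) -> None:
    payload = {"residues": [_result_record(r) for r in results]}
    if config is not None:
        payload["config"] = {
            "inclusion_threshold": config.inclusion_threshold,
            "mc_runs": config.mc_runs,
            "seed": config.seed,
        }
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def read_fit_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def format_fit_table(results: Sequence[FitResult]) -> str:
    """Human-readable summary table of fit results."""
    header = (
        f"{'residue':<10}{'class':<10}{'tau_ex_us':>12}{'err':>10}"
        f"{'field':>8}{'phi_ppm2':>12}{'err':>12}{'R2_0':>9}{'err':>8}  flags"
    )
    lines = [header, "-" * len(header)]
    for r in results:
        identifiable = r.classification == "exchange" and not math.isnan(r.tau_ex)
        tau = f"{r.tau_ex * 1e6:.2f}" if identifiable else "-"
        terr = f"{r.tau_ex_err * 1e6:.2f}" if not math.isnan(r.tau_ex_err) else "-"
        if not r.field_fits:
            lines.append(
                f"{r.residue_id:<10}{r.classification or 'n/a':<10}{tau:>12}{terr:>10}"
                f"{'':>8}{'':>12}{'':>12}{'':>9}{'':>8}  {','.join(r.flags)}"
            )
            continue
        first = True
        for field_mhz, ff in sorted(r.field_fits.items()):
            perr = (
                f"{ff.phi_ex_err_ppm2:.2e}" if not math.isnan(ff.phi_ex_err_ppm2) else "-"
            )
            rerr = f"{ff.r2_0_err:.2f}" if not math.isnan(ff.r2_0_err) else "-"
            lines.append(
                f"{r.residue_id if first else '':<10}"
                f"{(r.classification or 'n/a') if first else '':<10}"
                f"{tau if first else '':>12}{terr if first else '':>10}"
                f"{field_mhz:>8g}{ff.phi_ex_ppm2:>12.2e}{perr:>12}"
                f"{ff.r2_0:>9.2f}{rerr:>8}"
                f"  {','.join(r.flags) if first else ''}"
            )
            first = False
    return "\n".join(lines)


# -- configuration -----------------------------------------------------------


def read_config(path: str | Path) -> dict[str, object]:
    """Flat key=value configuration; comma-separated values become lists."""
    out: dict[str, object] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        if "," in value:
            out[key] = [float(v) for v in value.split(",") if v.strip()]
        else:
            try:
                out[key] = float(value) if "." in value or "e" in value.lower() else int(value)
            except ValueError:
                out[key] = value
    return out
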