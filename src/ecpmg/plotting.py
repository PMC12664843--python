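"""Optional plot export of dispersion curves with their fits."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np

from .extraction import DispersionCurve
from .fitting import FitResult, model_r2eff

__all__ = ["plot_dispersion_fits"]


def plot_dispersion_fits(
    curves: Sequence[DispersionCurve],
    results: Sequence[FitResult],
    out_dir: str | Path,
) -> list[Path]:
    """One PNG per residue: measured points with errors plus the fitted model."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    by_residue: dict[str, list[DispersionCurve]] = {}
    for c in curves:
        if len(c):
            by_residue.setdefault(c.residue_id, []).append(c)
    result_map = {r.residue_id: r for r in results}
    written = []
    for residue, group in by_residue.items():
        fig, ax = plt.subplots(figsize=(5, 3.5))
        result = result_map.get(residue)
        for curve in sorted(group, key=lambda c: c.larmor_mhz):
            pts = ax.errorbar(
                curve.nu_cpmg / 1e3, curve.r2eff, yerr=curve.sigma,
                fmt="o", ms=3.5, capsize=2, label=f"{curve.larmor_mhz:g} MHz",
            )
            if result is not None and result.converged:
                ff = result.field_fits.get(curve.larmor_mhz)
                if ff is not None:
                    nu = np.geomspace(curve.nu_cpmg[0], curve.nu_cpmg[-1], 200)
                    ax.plot(
                        nu / 1e3,
                        model_r2eff(nu, ff.r2_0, ff.phi_ex_ppm2, result.tau_ex,
                                    curve.larmor_mhz),
                        "-", color=pts[0].get_color(), lw=1,
                    )
        ax.set_xscale("log")
        ax.set_xlabel(r"$\nu_\mathrm{CPMG}$ (kHz)")
        ax.set_ylabel(r"$R_{2,\mathrm{eff}}$ (s$^{-1}$)")
        title = residue
        if result is not None and result.classification:
            title += f" ({result.classification})"
        ax.set_title(title)
        ax.legend(frameon=False, fontsize=8)
        fig.tight_layout()
        path = out / f"{residue}.png"
        fig.savefig(path, dpi=150)
        plt.close(fig)
        written.append(path)
    return written
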