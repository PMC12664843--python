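"""Residue-specific Luz–Meiboom dispersion fitting with Monte-Carlo errors.

The fast-exchange (k_ex >> delta_omega) closed form for the effective rate in
a CPMG experiment is

    R2,eff(nu) = R2,0 + phi_ex * tau_ex * [1 - 4 nu tau_ex * tanh(1/(4 nu tau_ex))]

with phi_ex = p_A p_B delta_omega^2 the population-weighted chemical-shift
variance (rad^2/s^2) and tau_ex = 1/k_ex the exchange lifetime.  phi_ex is
carried in ppm^2 to remove the field dependence; the conversion multiplies by
the squared angular Larmor frequency, (2 pi f_MHz)^2, since 1 ppm equals
f_MHz Hz at a proton frequency of f_MHz.

Curves from one residue measured at one or two static fields are fit jointly:
a single tau_ex is shared while phi_ex (ppm^2) and R2,0 are per-field.
Fitting is weighted least squares (weights 1/sigma^2) with a deterministic
multi-start over a log-spaced tau_ex grid.  Parameter uncertainties are
estimated by refitting Monte-Carlo resamples of the best-fit model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

from .extraction import DispersionCurve

__all__ = [
    "FitConfig",
    "FieldFit",
    "FitResult",
    "exchange_bracket",
    "luz_meiboom_rex",
    "model_r2eff",
    "classify_curve",
    "fit_dispersion",
    "monte_carlo_errors",
    "subsample_curve",
]

_SERIES_CUTOFF = 20.0


def exchange_bracket(x: float | np.ndarray) -> float | np.ndarray:
    """Stable evaluation of ``1 - x * tanh(1/x)`` for ``x >= 0``.

    The bracket decays like ``1/(3 x^2)`` for large ``x``; direct evaluation
    there loses all significant digits to cancellation, so a series expansion
    takes over above ``x = 20`` (both branches agree to ~1e-13 at the switch).
    At ``x = 0`` the limit is 1.
    """
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0):
        raise ValueError("exchange_bracket requires x >= 0")
    out = np.empty_like(arr)
    small = arr < _SERIES_CUTOFF
    xs = arr[small]
    with np.errstate(divide="ignore"):
        inv = np.where(xs > 0, 1.0 / np.where(xs > 0, xs, 1.0), np.inf)
    out[small] = 1.0 - xs * np.tanh(inv)
    xl = arr[~small]
    x2 = xl * xl
    out[~small] = 1.0 / (3.0 * x2) - 2.0 / (15.0 * x2 * x2) + 17.0 / (315.0 * x2 * x2 * x2)
    return float(out) if np.isscalar(x) else out


def luz_meiboom_rex(
    nu_cpmg: float | np.ndarray, phi_rad2: float, tau_ex: float
) -> float | np.ndarray:
    """Exchange contribution (1/s) in angular units of phi_ex (rad^2/s^2)."""
    return phi_rad2 * tau_ex * exchange_bracket(4.0 * np.asarray(nu_cpmg, float) * tau_ex)


def ppm2_to_rad2(phi_ppm2: float | np.ndarray, larmor_mhz: float) -> float | np.ndarray:
    """Convert a chemical-shift variance from ppm^2 to rad^2/s^2."""
    return phi_ppm2 * (2.0 * np.pi * larmor_mhz) ** 2


def model_r2eff(
    nu_cpmg: float | np.ndarray,
    r2_0: float,
    phi_ex_ppm2: float,
    tau_ex: float,
    larmor_mhz: float,
) -> float | np.ndarray:
    """Fast-exchange dispersion model with phi_ex in field-independent ppm^2."""
    rex = luz_meiboom_rex(nu_cpmg, ppm2_to_rad2(phi_ex_ppm2, larmor_mhz), tau_ex)
    return r2_0 + rex


@dataclass
class FitConfig:
    """Knobs of the dispersion fit.

    ``inclusion_threshold`` (1/s) is the minimum fitted dispersion amplitude,
    evaluated at the highest field present, for a residue to be classified as
    exchanging (strict inequality; at or below it the curve is called flat).
    """

    inclusion_threshold: float = 1.0
    mc_runs: int = 500
    seed: int = 0
    tau_bounds: tuple[float, float] = (5e-7, 1e-2)
    phi_bounds: tuple[float, float] = (0.0, 1.0)
    r2_bounds: tuple[float, float] = (0.0, 200.0)
    tau_grid_us: tuple[float, ...] = (2.0, 5.0, 10.0, 20.0, 50.0, 100.0, 200.0)
    ftol: float = 1e-12
    xtol: float = 1e-12
    default_sigma: float = 0.2

    def __post_init__(self) -> None:
        if self.mc_runs < 1:
            raise ValueError("mc_runs must be >= 1")
        for lo, hi in (self.tau_bounds, self.phi_bounds, self.r2_bounds):
            if not (lo < hi and hi > 0):
                raise ValueError("bounds must be positive-ordered")


@dataclass
class FieldFit:
    """Per-field parameters of a residue fit."""

    larmor_mhz: float
    phi_ex_ppm2: float
    r2_0: float
    phi_ex_err_ppm2: float = float("nan")
    r2_0_err: float = float("nan")


@dataclass
class FitResult:
    """Outcome of a residue-specific (possibly joint multi-field) fit."""

    residue_id: str
    classification: Optional[str]
    tau_ex: float
    field_fits: dict[float, FieldFit]
    chi2: float
    converged: bool
    n_points: int
    tau_ex_err: float = float("nan")
    flags: list[str] = field(default_factory=list)
    flat_summary: Optional[dict[float, dict[str, float]]] = None
    mc_runs_done: int = 0
    # internal: packed parameter vector and field order, used as the MC restart
    param_vector: Optional[np.ndarray] = None
    field_order: tuple[float, ...] = ()


def _effective_sigma(curves: Sequence[DispersionCurve]) -> list[np.ndarray]:
    """Weights for the least squares: 1/sigma, with zero sigmas replaced.

    Noise-free synthetic curves carry sigma = 0; the fit then degenerates to
    an unweighted one (sigma = 1), or to the smallest positive sigma present
    if the zeros are mixed with real uncertainties.
    """
    positives = np.concatenate([c.sigma[c.sigma > 0] for c in curves]) if any(
        np.any(c.sigma > 0) for c in curves
    ) else np.array([])
    fill = float(positives.min()) if positives.size else 1.0
    return [np.where(c.sigma > 0, c.sigma, fill) for c in curves]


def _pack(tau: float, per_field: Sequence[tuple[float, float]]) -> np.ndarray:
    flat = [tau]
    for r2_0, phi in per_field:
        flat.extend([r2_0, phi])
    return np.asarray(flat)


def _unpack(x: np.ndarray) -> tuple[float, list[tuple[float, float]]]:
    tau = float(x[0])
    per_field = [(float(x[i]), float(x[i + 1])) for i in range(1, len(x), 2)]
    return tau, per_field


def _residuals(
    x: np.ndarray,
    curves: Sequence[DispersionCurve],
    sigmas: Sequence[np.ndarray],
    data: Sequence[np.ndarray],
) -> np.ndarray:
    tau, per_field = _unpack(x)
    chunks = []
    for (r2_0, phi), curve, sigma, y in zip(per_field, curves, sigmas, data):
        model = model_r2eff(curve.nu_cpmg, r2_0, phi, tau, curve.larmor_mhz)
        chunks.append((model - y) / sigma)
    return np.concatenate(chunks)


def _initial_guesses(
    curve: DispersionCurve, tau: float, config: FitConfig
) -> tuple[float, float]:
    """Seed (R2_0, phi_ppm2) from the curve plateau and low-frequency amplitude."""
    k = min(3, len(curve))
    plateau = float(np.mean(curve.r2eff[-k:]))
    amp = max(float(np.mean(curve.r2eff[:k])) - plateau, 1e-3)
    bracket = float(exchange_bracket(4.0 * curve.nu_cpmg[0] * tau))
    phi_rad2 = amp / (tau * max(bracket, 1e-12))
    phi_ppm2 = phi_rad2 / (2.0 * np.pi * curve.larmor_mhz) ** 2
    r2_0 = float(np.clip(plateau, *config.r2_bounds))
    phi_ppm2 = float(np.clip(phi_ppm2, *config.phi_bounds))
    return r2_0, phi_ppm2


def _fit_once(
    x0: np.ndarray,
    curves: Sequence[DispersionCurve],
    sigmas: Sequence[np.ndarray],
    data: Sequence[np.ndarray],
    config: FitConfig,
):
    n_fields = len(curves)
    lo = [config.tau_bounds[0]] + [config.r2_bounds[0], config.phi_bounds[0]] * n_fields
    hi = [config.tau_bounds[1]] + [config.r2_bounds[1], config.phi_bounds[1]] * n_fields
    x0 = np.clip(x0, np.asarray(lo) + 0.0, np.asarray(hi) - 0.0)
    return least_squares(
        _residuals,
        x0,
        args=(curves, sigmas, data),
        bounds=(lo, hi),
        method="trf",
        ftol=config.ftol,
        xtol=config.xtol,
    )


def _model_amplitude(
    x: np.ndarray, curves: Sequence[DispersionCurve]
) -> tuple[float, float]:
    """Dispersion amplitude of the fitted model at the highest field present."""
    tau, per_field = _unpack(x)
    idx = int(np.argmax([c.larmor_mhz for c in curves]))
    curve = curves[idx]
    r2_0, phi = per_field[idx]
    lo = model_r2eff(curve.nu_cpmg[0], r2_0, phi, tau, curve.larmor_mhz)
    hi = model_r2eff(curve.nu_cpmg[-1], r2_0, phi, tau, curve.larmor_mhz)
    return float(lo - hi), curve.larmor_mhz


def fit_dispersion(
    curves: Sequence[DispersionCurve],
    config: Optional[FitConfig] = None,
) -> FitResult:
    """Fit one residue's curves (one or two fields) to the fast-exchange model.

    A single exchange lifetime tau_ex is shared across fields; phi_ex (ppm^2)
    and R2,0 are per-field.  The optimizer is restarted from every value of a
    fixed log-spaced tau_ex grid and the lowest chi-square wins (grid order
    breaks exact ties), which makes the fit deterministic.
    """
    config = config or FitConfig()
    if not curves:
        raise ValueError("no curves given")
    residues = {c.residue_id for c in curves}
    if len(residues) != 1:
        raise ValueError(f"curves must share one residue, got {sorted(residues)}")
    fields = [c.larmor_mhz for c in curves]
    if len(set(fields)) != len(fields) or len(fields) > 2:
        raise ValueError("expected one curve per field, at most two fields")
    curves = sorted(curves, key=lambda c: c.larmor_mhz)
    residue = curves[0].residue_id

    n_params = 1 + 2 * len(curves)
    n_points = sum(len(c) for c in curves)
    if n_points < n_params + 1:
        return FitResult(
            residue_id=residue,
            classification=None,
            tau_ex=float("nan"),
            field_fits={},
            chi2=float("nan"),
            converged=False,
            n_points=n_points,
            flags=["too_few_points"],
        )

    sigmas = _effective_sigma(curves)
    data = [c.r2eff for c in curves]
    best = None
    for tau_us in config.tau_grid_us:
        tau = tau_us * 1e-6
        x0 = _pack(tau, [_initial_guesses(c, tau, config) for c in curves])
        try:
            res = _fit_once(x0, curves, sigmas, data, config)
        except Exception:  # pragma: no cover - optimizer blow-up
            continue
        if res.success and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        return FitResult(
            residue_id=residue,
            classification=None,
            tau_ex=float("nan"),
            field_fits={},
            chi2=float("nan"),
            converged=False,
            n_points=n_points,
            flags=["non_convergence"],
        )

    tau, per_field = _unpack(best.x)
    chi2 = float(2.0 * best.cost)
    field_fits = {
        c.larmor_mhz: FieldFit(larmor_mhz=c.larmor_mhz, phi_ex_ppm2=phi, r2_0=r2_0)
        for c, (r2_0, phi) in zip(curves, per_field)
    }
    amplitude, _ = _model_amplitude(best.x, curves)
    flags: list[str] = []
    if amplitude > config.inclusion_threshold:
        classification = "exchange"
        flat_summary = None
    else:
        classification = "flat"
        flags.append("tau_unidentifiable")
        flat_summary = {
            c.larmor_mhz: {
                "mean_r2eff": float(np.mean(c.r2eff)),
                "rmsd": float(np.sqrt(np.mean((c.r2eff - np.mean(c.r2eff)) ** 2))),
            }
            for c in curves
        }
    return FitResult(
        residue_id=residue,
        classification=classification,
        tau_ex=tau,
        field_fits=field_fits,
        chi2=chi2,
        converged=True,
        n_points=n_points,
        flags=flags,
        flat_summary=flat_summary,
        param_vector=best.x.copy(),
        field_order=tuple(c.larmor_mhz for c in curves),
    )


def classify_curve(
    curve: DispersionCurve, config: Optional[FitConfig] = None
) -> FitResult:
    """Classify a single curve as flat or exchanging.

    Requires at least five points spanning a decade in frequency; otherwise
    the classification is withheld (``classification is None`` with a reason
    in ``flags``).  The amplitude criterion is evaluated on the fitted model,
    not on raw points, whose max-min span is inflated by noise.
    """
    config = config or FitConfig()
    if len(curve) < 5 or (
        len(curve) and curve.nu_cpmg[-1] < 10.0 * curve.nu_cpmg[0]
    ):
        return FitResult(
            residue_id=curve.residue_id,
            classification=None,
            tau_ex=float("nan"),
            field_fits={},
            chi2=float("nan"),
            converged=False,
            n_points=len(curve),
            flags=["insufficient_sampling"],
        )
    return fit_dispersion([curve], config)


def monte_carlo_errors(
    result: FitResult,
    curves: Sequence[DispersionCurve],
    config: Optional[FitConfig] = None,
) -> FitResult:
    """Monte-Carlo parameter uncertainties by refitting model-based resamples.

    Each run draws synthetic rates as best-fit model + Gaussian(0, sigma_point)
    per point and refits starting from the best-fit parameters; the reported
    error of each parameter is its standard deviation across runs.  Runs are
    seeded from ``config.seed`` and fully reproducible.  If more than 20% of
    refits fail the errors are flagged unreliable.
    """
    config = config or FitConfig()
    if not result.converged or result.param_vector is None:
        result.flags.append("mc_skipped_not_converged")
        return result
    curves = sorted(curves, key=lambda c: c.larmor_mhz)
    if tuple(c.larmor_mhz for c in curves) != result.field_order:
        raise ValueError("curves do not match the fields of the fit result")
    sigmas_fit = _effective_sigma(curves)
    tau, per_field = _unpack(result.param_vector)
    models = [
        model_r2eff(c.nu_cpmg, r2_0, phi, tau, c.larmor_mhz)
        for c, (r2_0, phi) in zip(curves, per_field)
    ]
    rng = np.random.default_rng(config.seed)
    samples: list[np.ndarray] = []
    failures = 0
    for _ in range(config.mc_runs):
        noisy = [m + rng.standard_normal(m.size) * c.sigma for m, c in zip(models, curves)]
        try:
            res = _fit_once(result.param_vector, curves, sigmas_fit, noisy, config)
        except Exception:  # pragma: no cover
            failures += 1
            continue
        if res.success:
            samples.append(res.x)
        else:
            failures += 1
    result.mc_runs_done = config.mc_runs
    if failures > 0.2 * config.mc_runs or len(samples) < 2:
        result.flags.append("mc_unreliable")
    if len(samples) >= 2:
        arr = np.vstack(samples)
        errs = arr.std(axis=0, ddof=1)
        result.tau_ex_err = float(errs[0])
        for i, f in enumerate(result.field_order):
            result.field_fits[f].r2_0_err = float(errs[1 + 2 * i])
            result.field_fits[f].phi_ex_err_ppm2 = float(errs[2 + 2 * i])
    return result


def subsample_curve(
    curve: DispersionCurve, n_points: int, seed: int
) -> DispersionCurve:
    """Seeded random subsample of a curve's unique points (method reproduction)."""
    if n_points >= len(curve):
        return curve
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(len(curve), size=n_points, replace=False))
    return DispersionCurve(
        residue_id=curve.residue_id,
        larmor_mhz=curve.larmor_mhz,
        nu_cpmg=curve.nu_cpmg[idx],
        r2eff=curve.r2eff[idx],
        sigma=curve.sigma[idx],
        n_avg=curve.n_avg[idx],
        flags=list(curve.flags) + ["subsampled"],
    )
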