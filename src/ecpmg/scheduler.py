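"""Timing schedules for relaxation-compensated constant-time CPMG experiments.

A constant-time CPMG experiment records one reference plane (no CPMG period)
and a series of planes in which ``N`` refocusing blocks per half fill a fixed
period ``T_CPMG``, giving a CPMG frequency ``nu_CPMG = N / T_CPMG``.  With the
[0013] refocusing phase cycle the magnetization spends, on average, three
quarters of each 180-degree pulse transverse and one quarter longitudinal.
The schedules built here compensate for that mixing:

* the echo delay on either side of each pulse is shortened to
  ``tau_CP = T_CPMG/(4 N) - 0.75 tau90``, so the total *transverse* time is
  exactly ``T_CPMG`` for every ``N``; and
* a purely longitudinal delay ``Delta = (N_max - N) tau90`` pads the total
  *longitudinal* time to the constant ``N_max tau90``, so that longitudinal
  relaxation contributes identically to every plane (including the reference,
  which gets the maximal ``Delta = N_max tau90``) and cancels in the intensity
  ratio.

Feasibility is bounded by ``tau_CP >= 0``, i.e. ``N <= T_CPMG / (3 tau90)``;
with a 40 ms constant time and an 8.4 microsecond 90-degree pulse this admits
CPMG frequencies of almost 40 kHz.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

__all__ = [
    "ScheduleError",
    "PulseCalibration",
    "ScheduleEntry",
    "CpmgSchedule",
    "TimeBudget",
    "compute_entry",
    "max_admissible_n",
    "build_schedule",
    "time_budget",
    "nutation_drift_percent",
]


class ScheduleError(ValueError):
    """A requested CPMG schedule cannot be realized."""


@dataclass(frozen=True)
class PulseCalibration:
    """Hard-pulse calibration of one spectrometer channel.

    Parameters
    ----------
    tau90 : float
        Length of the 90-degree hard pulse in seconds.
    larmor_mhz : float
        Larmor frequency of the observed nucleus in MHz.
    """

    tau90: float
    larmor_mhz: float = 600.0

    def __post_init__(self) -> None:
        if not self.tau90 > 0:
            raise ScheduleError(f"tau90 must be positive, got {self.tau90}")
        if not self.larmor_mhz > 0:
            raise ScheduleError(f"larmor_mhz must be positive, got {self.larmor_mhz}")

    @property
    def tau180(self) -> float:
        """Length of the 180-degree pulse (twice the 90-degree length)."""
        return 2.0 * self.tau90


@dataclass(frozen=True)
class ScheduleEntry:
    """One acquisition plane of a constant-time CPMG schedule.

    ``tau_cp`` is ``None`` for the reference plane (there is no echo delay to
    speak of), deliberately not ``0.0`` so that accidental arithmetic on it
    fails loudly.
    """

    N: int
    nu_cpmg: float
    tau_cp: Optional[float]
    delta: float
    is_reference: bool = False
    is_repeat: bool = False


def compute_entry(
    N: int,
    t_cpmg: float,
    calibration: PulseCalibration,
    n_max: int,
    is_repeat: bool = False,
) -> ScheduleEntry:
    """Compute one schedule entry from its loop counter.

    Implements the compensated timing: ``nu = N/T``, ``tau_CP = T/(4N) -
    0.75 tau90`` and ``Delta = (N_max - N) tau90``.  ``N = 0`` yields the
    reference plane with the maximal compensation delay.

    Raises
    ------
    ScheduleError
        If ``tau_CP`` would be negative; the message names the largest
        admissible ``N``.
    """
    if t_cpmg <= 0:
        raise ScheduleError(f"T_cpmg must be positive, got {t_cpmg}")
    if N < 0:
        raise ScheduleError(f"loop counter must be non-negative, got {N}")
    if N > n_max:
        raise ScheduleError(f"loop counter N={N} exceeds N_max={n_max}")
    tau90 = calibration.tau90
    if N == 0:
        return ScheduleEntry(
            N=0,
            nu_cpmg=0.0,
            tau_cp=None,
            delta=n_max * tau90,
            is_reference=True,
            is_repeat=is_repeat,
        )
    tau_cp = t_cpmg / (4.0 * N) - 0.75 * tau90
    if tau_cp < 0:
        n_bound = math.floor(t_cpmg / (3.0 * tau90))
        raise ScheduleError(
            f"N={N} gives a negative echo delay tau_CP; the echo cannot "
            f"accommodate the pulse. Maximum admissible N is {n_bound}."
        )
    return ScheduleEntry(
        N=N,
        nu_cpmg=N / t_cpmg,
        tau_cp=tau_cp,
        delta=(n_max - N) * tau90,
        is_reference=False,
        is_repeat=is_repeat,
    )


def max_admissible_n(
    t_cpmg: float,
    calibration: PulseCalibration,
    divisor: int = 16,
    user_cap: Optional[int] = None,
) -> int:
    """Largest loop counter divisible by ``divisor`` with ``tau_CP >= 0``.

    The feasibility bound is ``N <= T_CPMG / (3 tau90)`` (the point where the
    compensated echo delay vanishes).  An optional ``user_cap`` lowers the
    result further.
    """
    if divisor not in (1, 4, 16):
        raise ScheduleError(f"divisor must be 1, 4 or 16, got {divisor}")
    if t_cpmg <= 0:
        raise ScheduleError(f"T_cpmg must be positive, got {t_cpmg}")
    bound = t_cpmg / (3.0 * calibration.tau90)
    n = int(math.floor(bound / divisor)) * divisor
    # guard against floating-point edge cases on either side of the bound
    while n >= divisor and t_cpmg / (4.0 * n) - 0.75 * calibration.tau90 < 0:
        n -= divisor
    while t_cpmg / (4.0 * (n + divisor)) - 0.75 * calibration.tau90 >= 0:
        n += divisor
    if user_cap is not None:
        n = min(n, int(math.floor(user_cap / divisor)) * divisor)
    if n < divisor:
        raise ScheduleError(
            f"no admissible N >= {divisor}: the feasibility bound "
            f"T_cpmg/(3*tau90) = {bound:.4g} is too small"
        )
    return n


@dataclass(frozen=True)
class CpmgSchedule:
    """Full set of acquisition planes for one constant-time CPMG experiment."""

    t_cpmg: float
    calibration: PulseCalibration
    n_max: int
    divisor: int
    entries: tuple[ScheduleEntry, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        refs = [e for e in self.entries if e.is_reference]
        if len(refs) != 1:
            raise ScheduleError(
                f"schedule must contain exactly one reference entry, found {len(refs)}"
            )
        nonref = [e for e in self.entries if not e.is_reference]
        for e in nonref:
            if e.N <= 0 or e.N % self.divisor:
                raise ScheduleError(
                    f"entry N={e.N} is not a positive multiple of divisor {self.divisor}"
                )
        primary = sorted((e.N for e in nonref if not e.is_repeat))
        if any(a >= b for a, b in zip(primary, primary[1:])):
            raise ScheduleError("non-repeat entries must have strictly increasing N")
        realized = max((e.N for e in nonref), default=0)
        if realized != self.n_max:
            raise ScheduleError(
                f"N_max={self.n_max} does not match largest realized N={realized}"
            )

    @property
    def reference(self) -> ScheduleEntry:
        return next(e for e in self.entries if e.is_reference)

    @property
    def cpmg_entries(self) -> tuple[ScheduleEntry, ...]:
        return tuple(e for e in self.entries if not e.is_reference)

    @property
    def nu_max(self) -> float:
        return self.n_max / self.t_cpmg


def _nearest_multiple(n_exact: float, divisor: int, n_min: int, n_cap: int) -> int:
    """Nearest multiple of ``divisor`` to ``n_exact``, ties toward larger."""
    lower = int(math.floor(n_exact / divisor)) * divisor
    upper = lower + divisor
    if n_exact - lower < upper - n_exact:
        n = lower
    else:
        n = upper  # ties round up
    return max(n_min, min(n, n_cap))


def build_schedule(
    nu_targets: Sequence[float],
    t_cpmg: float,
    calibration: PulseCalibration,
    divisor: int = 16,
    repeats: Sequence[float] = (),
    user_cap: Optional[int] = None,
) -> CpmgSchedule:
    """Realize target CPMG frequencies as an admissible schedule.

    Each target is mapped to the nearest loop counter divisible by
    ``divisor`` (ties toward larger ``N``); a reference plane is prepended and
    repeat planes (independent re-acquisitions used downstream for error
    estimation) are appended, flagged ``is_repeat``.
    """
    n_adm = max_admissible_n(t_cpmg, calibration, divisor, user_cap)
    nu_max = n_adm / t_cpmg

    def realize(nu: float) -> int:
        if nu <= 0:
            raise ScheduleError(f"target frequency must be positive, got {nu}")
        if nu > nu_max * (1 + 1e-12):
            raise ScheduleError(
                f"target {nu:.6g} Hz exceeds the feasibility bound; maximum "
                f"admissible frequency is {nu_max:.6g} Hz"
            )
        return _nearest_multiple(nu * t_cpmg, divisor, divisor, n_adm)

    primary_n: list[int] = []
    repeat_n: list[int] = []
    for nu in nu_targets:
        n = realize(nu)
        if n in primary_n:
            warnings.warn(
                f"target {nu:.6g} Hz realizes an already-scheduled N={n}; "
                "flagging it as a repeat plane",
                stacklevel=2,
            )
            repeat_n.append(n)
        else:
            primary_n.append(n)
    for nu in repeats:
        repeat_n.append(realize(nu))

    all_n = primary_n + repeat_n
    n_max = max(all_n, default=0)
    entries = [compute_entry(0, t_cpmg, calibration, n_max)]
    for n in sorted(primary_n):
        entries.append(compute_entry(n, t_cpmg, calibration, n_max))
    for n in sorted(repeat_n):
        entries.append(compute_entry(n, t_cpmg, calibration, n_max, is_repeat=True))
    return CpmgSchedule(
        t_cpmg=t_cpmg,
        calibration=calibration,
        n_max=n_max,
        divisor=divisor,
        entries=tuple(entries),
    )


class TimeBudget(NamedTuple):
    transverse: float
    longitudinal: float
    total: float


def time_budget(
    entry: ScheduleEntry, schedule: CpmgSchedule, compensated: bool = True
) -> TimeBudget:
    """Transverse/longitudinal time accounting over both CPMG halves plus Delta.

    Per refocusing block the pulse contributes 3/4 of ``tau180`` to the
    transverse budget and 1/4 to the longitudinal budget; echo delays are
    transverse and ``Delta`` is longitudinal.  For compensated entries with
    ``N >= 1`` the budgets are constants: transverse ``= T_CPMG`` and
    longitudinal ``= N_max tau90``, which is the whole point of the scheme.
    The uncompensated variant uses ``tau_CP = T/(4N) - tau90`` and no
    ``Delta``, leaving a longitudinal budget ``N tau90`` that grows with
    ``N`` — the source of the linear-decay artifact.
    """
    cal = schedule.calibration
    tau180 = cal.tau180
    if entry.is_reference:
        longitudinal = schedule.n_max * cal.tau90 if compensated else 0.0
        return TimeBudget(0.0, longitudinal, longitudinal)
    n = entry.N
    if compensated:
        if entry.tau_cp is None:
            raise ScheduleError("non-reference entry lacks tau_cp")
        delay_time = 4.0 * n * entry.tau_cp
        delta = entry.delta
    else:
        tau_cp_u = schedule.t_cpmg / (4.0 * n) - cal.tau90
        if tau_cp_u < 0:
            raise ScheduleError(
                f"uncompensated echo delay is negative at N={n} "
                f"(nu={entry.nu_cpmg:.4g} Hz)"
            )
        delay_time = 4.0 * n * tau_cp_u
        delta = 0.0
    pulse_time = 2.0 * n * tau180
    transverse = delay_time + 0.75 * pulse_time
    longitudinal = 0.25 * pulse_time + delta
    return TimeBudget(transverse, longitudinal, transverse + longitudinal)


def nutation_drift_percent(tau90_start: float, tau90_end: float) -> float:
    """Relative change (%) between two nutation-derived 90-degree pulse lengths.

    Convenience for probe-detuning checks: a negative value means the pulse
    shortened (the effective RF field increased) at the higher CPMG frequency.
    """
    if tau90_start <= 0:
        raise ScheduleError("tau90_start must be positive")
    return 100.0 * (tau90_end - tau90_start) / tau90_start
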