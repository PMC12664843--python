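# Methods

`ecpmg` implements the computational side of an amide-proton extreme-CPMG
(E-CPMG) relaxation-dispersion experiment: a constant-time CPMG experiment in
which the refocusing-pulse repetition rate is driven from a few hundred Hz up
to the hard-pulse limit (tens of kHz on the proton channel), so that a single
measurement spans the regimes conventionally covered separately by low-power
CPMG and high-power spin-lock experiments.

## Timing model

Every acquisition plane shares one constant CPMG period `T_CPMG` (default
40 ms) split into two symmetric halves of `N` refocusing blocks each, so the
CPMG frequency is `nu_CPMG = N / T_CPMG`.  Each block is
`tau_CP – 180°(psi) – tau_CP`.  The refocusing pulses carry the [0013] phase
cycle (first half `y, y, -x, x`; second half `-y, y, -x, -x`; a 16-pulse
supercycle by cyclic permutation of the basic block), which suppresses
off-resonance and Hartmann–Hahn artifacts at high pulse rates but mixes
relaxation pathways: averaged over the basic block the magnetization is
transverse for 3/4 of each pulse and longitudinal for 1/4
(`transverse_fraction` computes this directly from ideal rotations).

Uncorrected, that mixing makes the measured rate decrease linearly with
frequency, `R2,meas = R2 - (R2 - R1) * nu * tau180 / 2`
(`linear_decay_slope`), which becomes significant above ~2 kHz.  The
compensated timing removes it by construction:

* `tau_CP = T_CPMG/(4N) - 0.75 * tau90`, so the total transverse time is
  exactly `T_CPMG` for every `N`;
* `Delta = (N_max - N) * tau90`, a purely longitudinal delay that pads the
  total longitudinal time to the constant `N_max * tau90` (the reference
  plane, `N = 0`, gets the maximal `Delta`).

`time_budget` verifies both conservation laws to sub-nanosecond accuracy;
they hold as exact algebraic identities of the three timing formulas.
Feasibility requires `tau_CP >= 0`, i.e. `N <= T_CPMG / (3 * tau90)`; with
`tau90 = 8.4 us` and `T_CPMG = 40 ms` the largest counter divisible by 16 is
1584 (39.6 kHz).  Loop counters are multiples of 4 (the basic phase block),
or of 16 at E-CPMG frequencies to complete the supercycle; one divisor
applies per schedule.  Targets are rounded to the nearest admissible counter
with ties toward larger `N`.

## Spin dynamics

Two-site exchange `A <-> B` is parameterized by the major population `p_A`,
exchange rate `k_ex = 1/tau_ex`, shift difference `delta_omega` (ppm),
and shared rates `R1`, `R2` (a single `R2,0` per residue per field is fit
downstream, so per-state rates would not be identifiable).  Two simulators
share one interface (`run_cpmg_plane`):

* **Geometric (scalar) model** — books decay time exactly as the
  compensation intends: echo delays at `R2` (plus the Luz–Meiboom exchange
  contribution), pulse intervals at `0.75 R2 + 0.25 R1`, `Delta` at `R1`,
  everything normalized to the reference plane computed the same way.  With
  delta pulses it evaluates to exactly `R2 + Rex(nu)` and serves as the
  closed-form oracle; with finite pulses the exchange contribution is booked
  on the echo delays only.  It requires an on-resonance spin.
* **Bloch–McConnell model** — piecewise-constant propagation of the six
  magnetization components (`Mx, My, Mz` per state) through every delay and
  pulse.  Pulses have duration `tau180 = 2 tau90` and RF amplitude
  `omega_1 = pi / tau180` about the axis given by the phase cycle; delta
  pulses are ideal instantaneous rotations with the full echo period as free
  evolution.  Relaxation is homogeneous (decay toward zero): the observable
  is decay *relative to the reference plane*, so equilibrium-recovery terms
  cancel and are omitted.  The mid-sequence coherence-transfer element is
  idealized as an instantaneous 180° about y; during `Delta` the
  magnetization is stored purely longitudinally.  The reported intensity is
  the magnitude of the total transverse magnetization, normalized to the
  reference plane.

Verified properties: with all rates zero every propagator is orthogonal
(norms conserved to 1e-12); compensated curves without exchange are flat to
< 1e-9 1/s (geometric) and < 0.1 1/s (finite-pulse Bloch–McConnell,
0.2–30 kHz); uncompensated curves reproduce the analytic linear-decay slope
within 2%; results are invariant under global inversion of the phase cycle;
and delta-pulse propagation in fast exchange (`k_ex >= 10 delta_omega`)
matches the Luz–Meiboom closed form within 2% of the exchange amplitude.

## Rate extraction and errors

`R2,eff(nu) = -ln[I(nu)/I(ref)] / T_CPMG`.  Negative rates (intensity above
the reference) are returned and flagged, never clipped.  Per-point
uncertainties come from repeat planes: for each frequency acquired more than
once the intensities are converted to rates, and the pooled per-residue sigma
is the root mean square of the per-frequency sample standard deviations (a
duplicate pair differing by `d` contributes `d / sqrt(2)`).  Pooling is per
residue, not per point, because an experiment carries only 2–4 repeat
planes.  Residues without repeats fall back to a configured default sigma
(0.2 1/s) with a logged warning.  Repeat measurements are averaged into
single points for fitting; the pre-averaging rates feed the error estimate.

## Dispersion fitting

The fast-exchange (Luz–Meiboom) closed form

    R2,eff(nu) = R2,0 + phi_ex * tau_ex * [1 - 4 nu tau_ex * tanh(1/(4 nu tau_ex))]

is fit per residue, either to one field or jointly to two fields with a
single shared `tau_ex` and per-field `phi_ex` and `R2,0`.  `phi_ex =
p_A p_B delta_omega^2` is carried in ppm²; conversion to rad²/s² multiplies
by `(2 pi f_MHz)^2` with the configured spectrometer frequency (nominal 600
or 800 unless set otherwise).  The bracket `1 - x tanh(1/x)` switches to its
series `1/(3x^2) - 2/(15x^4) + 17/(315x^6)` above `x = 20`, where direct
evaluation loses accuracy to cancellation.

Fitting is weighted least squares (weights `1/sigma^2`; zero sigmas from
noise-free synthetic data degenerate to unit weights, or to the smallest
positive sigma present when mixed) using bounded trust-region optimization,
restarted from a fixed log-spaced `tau_ex` grid {2, 5, 10, 20, 50, 100,
200} us with `R2,0` seeded from the high-frequency plateau and `phi_ex` from
the low-frequency amplitude; the lowest chi-square wins and grid order breaks
ties, so the fit is deterministic.  Bounds: `tau_ex` in [0.5 us, 10 ms],
`phi_ex` in [0, 1] ppm², `R2,0` in [0, 200] 1/s.

A residue is classified *exchanging* when the fitted model's amplitude
`model(nu_min) - model(nu_max)`, evaluated at the highest field present,
strictly exceeds the inclusion threshold (default 1 1/s); the amplitude is
measured on the fitted model rather than raw points because the raw max-min
span is noise-inflated.  Otherwise it is *flat* and reported with its mean
`R2,eff` and RMSD per field, with `tau_ex` marked unidentifiable.
Classification requires at least five points spanning a decade in frequency.
No multiple-testing correction is applied.  Joint fitting concatenates the
fields' residuals with no weighting beyond the per-point `1/sigma^2`.
An optional seeded subsample utility (`subsample_curve`) supports reproducing
analyses that used a random subset of points; by default all points are used.

Monte-Carlo uncertainties: each of `mc_runs` (default 500) resamples draws
synthetic rates as best-fit model plus Gaussian noise of the per-point sigma
and refits from the best-fit starting values; the reported error of each
parameter is its standard deviation across runs.  Runs are seeded and
reproducible; if more than 20% of refits fail the errors are flagged
unreliable.  Calibration: over 200 simulated single-residue datasets with
known truth and exact sigmas, the truth falls within one reported sigma of
the estimate in ~67% of cases.  Two caveats are inherent to this error
chain and documented by the test suite: the per-residue sigma estimate rests
on only 3–4 repeat pairs (a chi-distributed estimate with ~30% relative
spread), and intensity noise of fixed absolute size makes low-intensity
(high-rate) points noisier than the pooled sigma, so Monte-Carlo errors
conditioned on the estimated sigma understate the true parameter scatter by
~20–30% on realistic synthetic panels.

## Synthetic fixture

The default preset emulates a perdeuterated-ubiquitin-style two-field study
at 277 K: 20 flat residues (`R2,0` uniform in [8, 25] 1/s, `R1` in
[0.8, 1.5] 1/s), a cluster of six residues exchanging at `tau_ex = 55 us`
with assorted `phi_ex` of 0.002–0.010 ppm², and one faster site at 12.5 us
(`phi_ex = 0.015 ppm²`); exchanging sites share `p_A = 0.95`.  Schedules use
`T_CPMG = 40 ms` with calibrations of 8.4 us (600 MHz) and 7.6 us (800 MHz),
35 unique frequencies plus four repeat planes at 600 MHz and 24 plus three
at 800 MHz — the plane counts of the emulated acquisition.  Intensity noise
is additive Gaussian with a standard deviation of 0.004 of the reference
intensity, calibrated from first principles so the panel-averaged `R2,eff`
uncertainty is 0.2 1/s at `T_CPMG = 40 ms`.  All residue labels and
parameter values are synthetic stand-ins; generation is fully seeded and
byte-reproducible.

The generator emulates Gaussian intensity noise, duplicate planes and the
field dependence of the exchange contribution.  It does **not** emulate
proton–proton cross-relaxation oscillations at low frequencies, solvent
exchange at elevated temperature, RF-field inhomogeneity, selective-pulse
imperfections in the transfer element, or baseline/peak-overlap effects of
real spectra — so passing recovery tests demonstrate the correctness of the
analysis chain under its own noise model, not robustness to those artifacts.

## Problem sizes and numerical choices in the test suite

Simulation-based tests use schedules of 9–20 planes with loop counters up to
1200 (finite-pulse propagation multiplies ~2N six-by-six matrices per
plane); the recovery test fits the full 27-residue two-field panel with
500-run Monte-Carlo per exchanging residue; the error-calibration test uses
200 datasets of 24 points with 100-run Monte-Carlo each.  Reference-plane
normalization is computed with the same model as the plane itself, so model
systematics cancel.  Durations are carried in seconds; schedules are
serialized with loop counters plus the exact timing inputs, and readers
rebuild delays from the counters, making the text round trip lossless.

## Limitations

Only the fast-exchange closed form is fit (no general two-site
Carver–Richards or slow-exchange treatment), and no global fit of a single
timescale across residues is attempted.  The spectrometer-side concerns —
pulse-program code, heat compensation, water suppression, coherence-transfer
delays — are out of scope, as is everything upstream of peak-intensity
tables (spectral processing, peak picking).  The rise of measured rates
above ~22 kHz reported on some hardware has no model here and is not
simulated.
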