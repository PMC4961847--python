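# Methods

## Binding model

A prey-conjugated nanoparticle at bulk concentration `C` binds immobilized
bait with coverage `θ(t)` obeying the Langmuir rate equation

    dθ/dt = k_on·C·(1 − θ) − k_off·θ,

whose solution from θ(0) = 0 is `θ(t) = θ_eq·(1 − exp(−k_obs·t))` with
`k_obs = k_on·C + k_off` and `θ_eq = k_on·C/k_obs`. The rates are those of
the *bivalent* particle–surface interaction (superscript "bi" throughout
the API): a particle carries many prey copies, but geometry restricts
engagement to effectively two, and the avid interaction is what the sensor
observes. The model presumes the reaction-limited regime — continuous flow
replenishes particles at the surface fast enough that `C` is the bulk
concentration (see Transport below). Sensor signals are proportional to θ
and are kept in arbitrary units; only ratios and rates are interpreted.

## Analysis chain and its parameters

**Reference subtraction.** The per-time-point mean over each channel's
reference sensors is subtracted from every trace in that channel. Dedicated
reference sensors are used when the layout declares them; otherwise the
negative-control sensors (murine IgG, BSA), whose signals stay low and
constant, stand in. Subtraction removes *any* channel-common signal
exactly, so fitted rates are invariant to baseline steps and drift — a
robustness property the sensing modality is designed for.

**Onset synchronization.** Channels are aligned so binding starts at the
configured onset (default 60 s). Automatic detection, when requested, takes
the first time the channel-mean probe signal exceeds the baseline mean plus
5 baseline SDs (baseline = first max(5, n/10) samples), rounded to the
sampling grid; undetectable (flat) channels keep the configured onset with
a warning. The threshold rule is deterministic and testable; the detected
onset is bait-strength dependent by at most a couple of samples, which the
fixed-t0 fit tolerates.

**Exponential fit.** `S(t) = A·(1 − exp(−k_obs·(t − t0)))` is fit by
trust-region least squares with analytic Jacobian over the first 80 samples
with `t ≥ t0` (5.5-s sampling ⇒ a 440-s window); t0 is fixed, A and k_obs
are bounded below by 0. Initialization is deterministic: A₀ = max windowed
signal, k₀ = ln2 / (time to half of A₀). Parameter SEs come from the
Jacobian at the optimum (`s²(JᵀJ)⁻¹`). Non-convergence is reported via a
flag, never an exception; traces with fewer than 8 post-onset points are
excluded with a logged reason. Whether the window starts at the onset
sample or one later is a convention; here it starts at the first sample
with `t ≥ t0`.

**Duplicate aggregation.** Duplicate sensors are summarized as mean ± SD
per (bait, channel); a singleton reports SD as missing, not zero. The
duplicate mean per (bait, channel) enters the pooled regression (one point
per channel per experiment).

**Rate decoupling.** Unweighted OLS of k_obs on the calibrated molar
concentration across channels and experiments gives k_on^bi (slope),
k_off^bi (intercept) and `K_D^bi` with a delta-method SE using the full
slope/intercept covariance. A negative intercept (off-rate below the noise
floor) is reported unclamped with a warning — truncation would bias
downstream pooling.

**Calibration.** Absorbance at 425 nm vs standard concentration (defaults
1.0, 0.9, 0.8, 0.6, 0.4, 0.2, 0.1 nM, duplicates as individual points) by
OLS with a free intercept (blank absorbance is nonzero in practice).
Inverse prediction `ĉ = (A − b)/m` carries the classical inverse-regression
SE `(s/m)·sqrt(1/k + 1/n + (ĉ − c̄)²/Sxx)`; predictions outside the standard
range or below zero are returned with warnings, never clipped.

**Avidity conversion.** With effective local concentration `c_eff` — the
concentration at which a tethered particle's remaining site sees the
surface bait once one site is bound — detailed balance across the v-step
binding ladder gives `K_D^bi = (K_D^mono)^v / c_eff^(v−1)`, inverted as
`K_D^mono = (K_D^bi·c_eff^(v−1))^(1/v)` (geometric-mean form, v = 2
default). The exact avidity correction is geometry-dependent, so the form
is deliberately simple and pluggable, and `c_eff` has **no default**:
K_D^mono scales as √c_eff, and silently choosing one would fabricate
affinities. `valency_sensitivity` tabulates K_D^mono under v ∈ {1, 2, 3};
its max/min spread `(c_eff/K_D^bi)^(2/3)` exceeds 10 whenever
`K_D^bi/c_eff < 10⁻³`, quantifying how strongly inferred affinities depend
on the assumed binding mode.

## Transport

Diffusivity from Stokes–Einstein (`D = k_B·T/(3πηd_h)`; 46-nm particle in
water at 25 °C → 1.07e-11 m²/s). For a channel of width `W` and height `H`
carrying flow `Q` over a sensor of length `L`: channel Péclet
`Pe_H = Q/(D·W)`, shear Péclet `Pe_s = 6(L/H)²·Pe_H`, mass-transfer
coefficient `k_M = F·D/L` with the Lévêque-type collection factor
`F = 0.81·Pe_s^{1/3}` for `Pe_s > 1` and the full-collection limit `F = 1`
below (`Pe_s < 10⁻²` flags the report approximate). The Damköhler number
`Da = k_on·b_m/k_M` (bait site density `b_m`, no default — it is
assay-specific) classifies the regime: reaction-limited below 0.1,
transport-influenced to 1, transport-limited above. Both thresholds are
order-of-magnitude conventions, cross-checked against the two-compartment
oracle below.

**Two-compartment oracle.** Quasi-steady balance between transport to a
near-surface compartment and reaction gives

    dθ/dt = [k_on·C·(1 − θ) − k_off·θ] / [1 + Da·(1 − θ)],

integrated with LSODA at rtol 1e-10. It converges to the Langmuir solution
as `k_M → ∞` and quantifies what finite transport does to the *fitted*
rate: the measured suppression of k̂_obs is ≈ 0.7% at Da = 0.01, 3.5% at
0.05, 6.9% at 0.1, 47% at 1 and 98% at 10, growing strictly with Da. Note
the boundary behaviour: the initial-rate suppression is `1/(1+Da)` (≈ 9% at
Da = 0.1), partially averaged down over the fit window, so the "< 5% error"
reading of the reaction-limited verdict is guaranteed only for Da ≲ 0.07;
the 0.1 threshold is kept as the conventional order-of-magnitude boundary.

## Synthetic data

The generator emulates the acquisition design of a four-channel chip: 16
sensors per channel, six baits in duplicate (four probes, two negative
controls) plus four dedicated reference sensors, an identical
immobilization pattern in every channel, dilution fractions
1.00/0.75/0.50/0.25 of the eluted concentration, 5.5-s sampling, binding
onset at 60 s, flat non-binder traces and no baseline step at sample
introduction. Noise is additive homoscedastic Gaussian
(`sigma_rel`, default 0.02 of the saturation amplitude) — the minimal model
and the one least squares assumes; duplicate-sensor amplitude heterogeneity
is multiplicative log-normal with CV `amp_cv` (default 0.05), which spreads
amplitudes without biasing rates. Per-sensor random streams are spawned
from the master seed by (channel, sensor) keys, so adding sensors never
perturbs existing traces and identical seeds give bit-identical datasets.

Default ground truth is `k_on^bi = 1e7 M⁻¹s⁻¹`, `k_off^bi = 1e-3 s⁻¹`
(`K_D^bi = 0.1 nM`) with a 1-nM eluate. The choice is deliberate on three
grounds: (i) k_obs spans ~3× across the dilution series and `k_obs·T`
spans 1.5–4.8 over the 80-point window, so the top channels saturate
visibly and both A and k_obs are well identified — the per-trace Cramér–Rao
bound on k_obs is a few percent at the default noise, whereas
ten-fold-slower kinetics in the same window would leave the rate
fundamentally unidentifiable (CRLB 24–200%); (ii) `K_D^bi` lies inside the
concentration series, so equilibrium plateaus differ visibly across
channels; (iii) through the avidity model at `c_eff = 0.27 M` it
corresponds to a monovalent K_D ≈ 5 µM, the low-affinity scale the platform
targets. Real instrument amplitudes and noise spectra are not public;
`sigma_rel`, `amp_cv` and the calibration line (slope 0.5 per nM, intercept
0.05) are stand-ins, so passing tests demonstrate correctness of the
analysis under the stated statistical model, not performance on any
particular instrument's noise.

The calibration-plate generator writes standards plus unknown wells with
i.i.d. Gaussian absorbance noise; the two-compartment variant substitutes
the throttled ODE for the closed form, per bait.

## Validation studies and problem sizes

`mnpkin.validation` drives the seeded studies used by the test suite and
`scripts/acceptance.py`: 100 repetitions of the full pipeline (3 pooled
experiments each, ~19k curve fits total) for rate-recovery medians and
95%-CI coverage; 1,000 calibration plates for inverse-prediction coverage;
a 4-point Damköhler sweep on noiseless two-compartment traces; a 3×3 rate
grid for the closed-form-vs-ODE check at 1e-8 absolute tolerance. These
sizes give stable Monte-Carlo estimates (binomial SE on a 93% coverage at
n = 100 is ±2.6%) while keeping a full run to a few minutes.

## Known limitations

- The dissociation phase (buffer washout) is deliberately unsupported: the
  bivalent off-rate is recovered from the regression intercept, and its
  relative error is the dominant error term in K_D^bi.
- The avidity conversion is a single-parameter effective-concentration
  model; linker flexibility, site-density heterogeneity and higher-order
  valency effects are outside its scope, which is why the valency
  sensitivity table accompanies every conversion.
- The transport analysis assumes a shallow rectangular channel, fully
  developed laminar flow and a square sensor; the collection-factor
  correlation is accurate to tens of percent, consistent with the
  order-of-magnitude use of Da.
- Unweighted OLS in the rate regression ignores the channel-dependent
  variance of k̂_obs (low-concentration channels are noisier); weighting by
  duplicate SDs is available via `ObservedRateRegression` inputs but is not
  the default, matching the plain linear-regression convention of this
  assay type.
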