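# Methods

This note records the models, measurement conventions, parameter defaults
and numerical choices behind `rettephys`, and what the synthetic-data
generators do and do not emulate.

## Conventions

Canonical units package-wide: time ms, potential mV, current pA, capacitance
pF, current density pA/pF, charge density pC/pF. Inward current is negative;
where a figure-style magnitude is wanted (window current, late-current group
summaries) the sign flip is explicit and documented at the call site.
Sampling defaults to dt = 0.1 ms (10 kHz digitisation). Sweep tables are
plain CSV (`time_ms` plus one column per protocol key) with a JSON sidecar;
values are serialised at 17 significant digits and re-read with a
round-trip-exact float parser, so write→read is bit-exact.

## ECG

R peaks are detected by amplitude threshold on the rectified, median-centred
signal — a configurable fraction (default 0.6) of its 98th percentile — with
a 30 ms refractory period; peaks inside declared noise intervals are
dropped. QT end cannot be delineated reliably from the T wave in these
recordings, so QT (and QRS onset/end) always come from fiducial
annotations. Per-animal values average the first run of five consecutive
complexes whose span avoids noise intervals; the two QT rate corrections
are applied per complex and then averaged. For physiological RR jitter
(CV ≈ 5%) the Jensen gap between "mean of per-complex QTc" and "QTc of mean
QT/RR" is below 0.2 ms for the square-root form; the per-complex convention
is the package's fixed choice. The linear correction takes RR in ms; with
murine RR ≈ 126–131 ms the correction term 0.3173·(170 − RR) is positive,
which is the only reading that places the corrected value above the raw QT
as published group tables show.

## Action potentials

The APD time origin is the instant of maximum dV/dt (not stimulus onset),
which removes stimulus-latency jitter. dV/dt uses a 3-point moving average
(edge-replicated so segment boundaries cannot fabricate spikes) followed by
central differences; mV/ms is reported as V/s. The repolarization reference
is the overshoot-to-RMP amplitude: APD_x is the first downward crossing of
overshoot − (x/100)·amplitude after the peak, linearly interpolated between
samples (sub-sample accuracy; at 10 kHz the interpolation error is ≪ the
0.5 ms tolerance used in round-trip tests, which is dominated by waveform
shape). RMP is the mean over the 10 ms window ending at stimulus onset.
A missing crossing (segment ends before repolarization completes) yields
NaN for that APD_x, flagged in `missing`, rather than an error.

BVR divides the summed absolute successive APD90 differences by the number
of difference terms (N−1) and √2, making it the classic Poincaré short-term
variability; dividing by the number of beats (N) is available via
`denominator="beats"` since the defining phrase "n beats" admits either
reading. Series longer than 15 beats are truncated to 15; fewer than 10
(configurable) is an error. For iid Gaussian per-beat jitter of standard
deviation σ the expectation is E[BVR] = σ·√(2/π), which the tests verify by
Monte Carlo.

## Fast sodium current

Peak current per sweep is the most-negative baseline-subtracted value in
the test step (baseline: 10 ms pre-step mean). The reversal potential is
the zero-current intercept of a least-squares line through every I–V point
positive to the voltage of minimum current (≥ 3 required); the ascending
limb is slightly curved where activation has not saturated, so the
extrapolation is treated as approximate (±2 mV on synthetic data) and any
analysis that needs an exact E_rev can supply one. Chord conductance
excludes points within 1 mV of E_rev, where the transform is singular.

Both Boltzmann fits (activation on G/Gmax over −80…−20 mV, availability on
I/Imax over −150…−50 mV) are unweighted nonlinear least squares with
data-driven starts: midpoint from the interpolated half-maximum crossing,
slope factor from the 25–75% level spread divided by 2.2, and a free scale
factor initialised at 1. The scale absorbs the sampling noise of the single
normalisation point (Gmax or Imax); it converges to 1 on ideal data and is
reported with the fit. Parameter tolerance is 1e-10; k is constrained
positive. Noiseless protocol-grid curves refit to the generating parameters
to machine precision (the property suite checks residual < 1e-10 across the
physiological (V05, k) range).

Availability and recovery families are read at a fixed latency: the peak
latency of the largest-magnitude sweep, with a ±0.2 ms averaging window.
A per-sweep minimum would acquire a negative extreme-value bias whenever the
underlying current is small relative to noise (the minimum of hundreds of
noise samples); the fixed-latency read is unbiased, and because every sweep
of a protocol shares one waveform shape the narrow-window attenuation
cancels exactly in the I/Imax and P2/P1 ratios.

The inactivation time constant is a single-exponential fit (amplitude,
τ, offset) opening 0.2 ms after the current peak and closing where the
current has decayed to 5% of peak (capped at step end); both ends are
config-exposed since the originating procedure does not pin them down. A
flat post-peak segment or a τ far exceeding the fit window raises a fit
error rather than returning an unresolved constant.

Recovery from inactivation is fitted with
R(t) = 1 − (A_f·e^(−t/τ_fast) + A_s·e^(−t/τ_slow)), parameterised as
τ_slow = τ_fast + δ with δ > 0 so the time constants cannot cross;
amplitudes are bounded in [0, 1.5] and a sum above 1.05 warns. Initial τ_fast
comes from log-linear regression over the first time decade, with a small
multi-start ladder as fallback.

The window current is evaluated on the −120…+20 mV grid at 2 mV steps as
a(V)·h(V)·Gmax·(V − E_rev) and reported sign-flipped as a magnitude;
voltages positive to E_rev give physically outward values of order
10⁻⁶·Gmax there, clipped to zero so the curve is non-negative and closes at
both ends. Gmax is the maximum measured chord conductance over the
protocol, not a fitted quantity, so absolute window amplitudes inherit its
noise; peak location and strain comparisons are the robust outputs.

## Late sodium current

The Na⁺-sensitive current is a pointwise control − sodium-free subtraction
(grids must match; no implicit resampling). The 300/600 ms densities are
±5 ms windowed means (config-exposed; 0 gives a point sample) — the
originating measurements do not state whether reads were points or windows,
and the windowed mean is the noise-robust choice at 10 kHz. The integral is
trapezoidal over [step+350, step+800] ms; pA/pF·ms = fC/pF, reported ÷1000
as pC/pF, so a constant −0.5 pA/pF gives −0.225 pC/pF. All three measures
are linear in the trace, hence linear in the generator's late fraction.
Percentage inhibition is 100·(1 − |post|/|pre|) per measure; a zero control
measure is undefined and raises.

## Respiration

The scoring rule keeps a minute-wise reference: the reference applied to
every breath of minute m is the mean expiration time of the *non-apnoeic*
breaths of minute m−1; a breath is apnoeic when its expiration time exceeds
factor × reference (factor 4 by default). Excluding apnoeic breaths from
the reference prevents a long apnoea from masking its successors. "Taken
every minute" could also mean a per-breath trailing 60 s mean; that variant
is selectable (`mode="trailing"`) but the minute-wise reading is the
default. Consecutive apnoeic breaths merge into one episode whose length is
the summed expiration time of its member breaths, and an episode is scored
if its first breath falls in the analysis window (default: minutes 20–40,
after a 20 min adaptation that is classified but never scored). The
implementation is verified breath-for-breath against an independent literal
re-implementation of the rule on 1000 random series. The rule is ratio
based, so rescaling all expiration times leaves the count unchanged, and
the count is monotone non-increasing in the factor.

The APD90-vs-apnoea-length association uses the Pearson correlation with
the two-sided p from t = r√((n−2)/(1−r²)); a constant variable makes r
undefined and raises.

## Group statistics

Cells are the analysis unit; animal identity is carried for reporting
(nested counts) but no mixed-effects model is fitted, matching the
originating reporting style. The unpaired comparison is pooled-variance or
Welch t, chosen explicitly or by an F test of variances at 0.05 (the
"as appropriate" criterion is not otherwise specified; the F-test rule is
this package's documented choice). Zero-variance degeneracies return
flagged results (statistic 0/p 1 when means agree, ±∞/p 0 otherwise)
instead of NaN. Multi-group ANOVA machinery is deliberately out of scope —
only the two-sample, paired and correlation procedures the pipeline needs
are exposed.

## Synthetic data

The sodium-channel generator is a minimal quasi-steady-state model:
instantaneous activation a∞(V), one voltage-dependent inactivation time
constant τ(V) = τ(−40)·exp(−(V+40)/30 mV), and a voltage-independent
non-inactivating fraction f_late standing in for the burst-mode gating that
produces the late current. Test-step current:

    I(V,t) = gmax · a∞(V) · (V − E_rev) · [(1 − f_late)·e^(−t/τ(V)) + f_late]

with availability scaling h∞(V_cond) for the conditioning protocol and the
biexponential recovered fraction for the paired-pulse protocol. Defaults
are the wild-type kinetics the analysis reports (V05 −47.4 mV, k 3.6 mV;
availability −83.1/6.5 mV; τ(−40) 2.6 ms; recovery 11.0/362.0 ms, fast
fraction 0.85; E_rev 0 mV for symmetrical 5 mM Na⁺; gmax 1 pA/pF per mV,
giving a ≈ −35 pA/pF peak density; f_late 0.005, i.e. late current a few
tenths of a percent of peak, matching the observed ≈ −0.1 pA/pF late
density). The mutant preset shifts gating (−45.4/3.9, −79.6/5.1), slows
τ(−40) to 3.1 ms, speeds fast recovery to 8.6 ms, scales gmax by 0.75 and
triples f_late. An optional exponential rise filter is available for
visually realistic upstrokes but defaults to off: any causal rise couples
the sampled peak to τ(V) and systematically distorts the activation curve
measured back from the family, which would contaminate parameter-recovery
checks with a generator artefact rather than an analysis property.

The AP generator produces a logistic upstroke (steepness 0.2 ms, giving
V̇max ≈ 150 V/s at wild-type amplitude) followed by a monotone
piecewise-cubic (PCHIP) repolarization through the APD25/50/75/90 anchor
points. A two-exponential repolarization family was considered and
rejected: after peak normalisation it has three effective degrees of
freedom, which cannot pass through four independent APD targets (for the
wild-type targets the best two-exponential fit misses APD90 by tens of ms).
The monotone interpolant hits all four targets exactly by construction, so
generator error never masks analysis error in round-trip tests. Per-beat
variability is injected as Gaussian jitter on the APD90 anchor.

The ECG generator writes P-QRS-T complexes as Gaussian bumps on an
isoelectric baseline, with fiducials emitted as exact ground truth (QRS
onset 40% of the QRS width before the R peak; T peak at 75% of QT so QT end
falls after the T-wave peak); optional high-frequency bursts are injected
and declared as noise intervals. The breathing generator emits regular
breath events with lognormal expiration-time jitter (median = base Te,
default 0.2 s at 140 breaths/min) and replaces selected breaths with
apnoeas of requested lengths.

All generators take explicit seeds and touch no global random state.

**What the generators do not emulate** — and hence what passing tests do
not show about real data: capacity transients, series-resistance and
voltage-clamp escape artefacts, m³-type activation latency, temperature
drift, electrode offset, T-wave morphology variation and motion artefacts
on the ECG, and respiratory flow waveforms (breath events are emitted
directly). Group means from real animals and cells (ECG tables, AP tables,
late-current bar values) are not reproducible from this package because the
raw recordings are not publicly deposited; strain-level claims are
exercised as directional tests on synthetic cohorts at the study's cell
counts instead.

## Problem sizes

The property suite uses the sizes the checks were designed at: 1000 random
breath series for the apnoea-rule equivalence, 200 noisy replicates (noise
2% of the −40 mV peak) for kinetic parameter-recovery bias, 2000 draws for
the BVR expectation, and 41 vs 28 cells for the two-cohort comparison. The
full test suite runs in well under a minute on one CPU.
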