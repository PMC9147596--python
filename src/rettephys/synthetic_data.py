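"""Ground-truth signal generators for every pipeline stage.

The generators emulate the study conditions the analysis stages were built
for: voltage-clamp sodium-current sweep families under the three protocols
(I-V activation, availability, paired-pulse recovery) plus the 1 s late-
current step, 1 Hz action-potential trains with controlled APD targets and
beat-to-beat jitter, ECG-like traces with prescribed RR/QRS/QT and exact
fiducial annotations, and breath-event series with injected apnoeas.

The sodium-channel model is deliberately minimal: instantaneous activation
a_inf(V) (optionally smoothed by a short exponential rise filter), a single
voltage-dependent inactivation time constant, and a voltage-independent
non-inactivating fraction ``f_late`` standing in for the burst-mode gating
that produces the late current (its mechanism is not modelled).  Test-step
current:

    I(V, t) = gmax * a_inf(V) * (V - erev)
              * [(1 - f_late) * exp(-t / tau_inact(V)) + f_late]

scaled by the availability sigmoid h_inf(V_cond) for the availability
protocol and by the biexponential recovery fraction for the paired-pulse
protocol.  Default parameter values are the wild-type kinetics the analysis
stages report; an ``RTT_PARAMS`` preset carries the mutant kinetics with a
reduced conductance scale and a threefold late fraction.

All generators take explicit seeds and are bit-reproducible; no global
random state is touched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import PchipInterpolator

from .core_io import EcgAnnotation, ComplexFiducials, SweepFamily, Trace
from .respiration import BreathRecord

RECOVERY_INTERVALS_MS = (0.1, 0.3, 1.0, 3.2, 10.0, 31.6, 100.0, 316.2, 1000.0, 3162.0)


@dataclass
class NaChannelParams:
    """Minimal fast/late sodium-channel model parameters.

    ``gmax`` is the conductance scale in pA/pF per mV of driving force, so
    generated sweeps are current densities.  ``tau_inact(V)`` decreases
    e-fold per ``tau_inact_efold`` mV of depolarisation, anchored at -40 mV.
    """

    gmax: float = 1.0
    erev: float = 0.0            # symmetrical Na+ -> 0 mV
    act_vhalf: float = -47.4
    act_k: float = 3.6
    inact_vhalf: float = -83.1
    inact_k: float = 6.5
    tau_inact_minus40: float = 2.6   # ms
    tau_inact_efold: float = 30.0    # mV per e-fold change
    f_late: float = 0.005
    tau_fast_rec: float = 11.0       # ms
    tau_slow_rec: float = 362.0      # ms
    a_fast_rec: float = 0.85

    def __post_init__(self) -> None:
        if not (self.act_k > 0 and self.inact_k > 0):
            raise ValueError("slope factors must be positive")
        if not 0 <= self.f_late < 1:
            raise ValueError(f"f_late must be in [0, 1), got {self.f_late}")
        if not 0 < self.tau_fast_rec < self.tau_slow_rec:
            raise ValueError("recovery requires 0 < tau_fast < tau_slow")
        if not 0 <= self.a_fast_rec <= 1:
            raise ValueError("a_fast_rec must be in [0, 1]")

    def a_inf(self, v):
        return 1.0 / (1.0 + np.exp((self.act_vhalf - v) / self.act_k))

    def h_inf(self, v):
        return 1.0 - 1.0 / (1.0 + np.exp((self.inact_vhalf - v) / self.inact_k))

    def tau_inact(self, v):
        return self.tau_inact_minus40 * np.exp(-(v + 40.0) / self.tau_inact_efold)

    def recovered_fraction(self, t):
        a_s = 1.0 - self.a_fast_rec
        return 1.0 - (self.a_fast_rec * np.exp(-t / self.tau_fast_rec)
                      + a_s * np.exp(-t / self.tau_slow_rec))


#: wild-type kinetics (defaults of NaChannelParams)
WT_PARAMS = NaChannelParams()
#: mutant (Mecp2-null) kinetics: shifted/steepened gating, slower inactivation
#: at -40 mV, faster fast recovery, reduced conductance scale, 3x late fraction
RTT_PARAMS = NaChannelParams(
    gmax=0.75, act_vhalf=-45.4, act_k=3.9, inact_vhalf=-79.6, inact_k=5.1,
    tau_inact_minus40=3.1, f_late=0.015, tau_fast_rec=8.6, tau_slow_rec=311.5,
    a_fast_rec=0.85,
)


def _step_current(params: NaChannelParams, v: float, dur_ms: float, dt: float,
                  rise_tau_ms: float) -> np.ndarray:
    """Test-step current density; t = 0 falls exactly on the step onset."""
    t = np.arange(0.0, dur_ms - dt / 2, dt)
    decay = (1.0 - params.f_late) * np.exp(-t / params.tau_inact(v)) + params.f_late
    i = params.gmax * params.a_inf(v) * (v - params.erev) * decay
    if rise_tau_ms > 0:
        i = i * (1.0 - np.exp(-t / rise_tau_ms))
    return i


def gen_ina_family(params: NaChannelParams, protocol: str,
                   noise_sd: float = 0.0, dt: float = 0.1, seed: int = 0,
                   rise_tau_ms: float = 0.0) -> SweepFamily:
    """Generate a sodium-current sweep family under one of the four protocols.

    Protocols (all currents are densities, pA/pF, inward negative):

    - ``IV_ACTIVATION``: 250 ms steps from -80 to 0 mV in 10 mV increments
      after a 20 ms zero-current baseline.
    - ``AVAILABILITY``: 40 ms test commands to -40 mV scaled by the
      availability h_inf at conditioning voltages -150..-50 mV (the 1.5 s
      conditioning pulse itself carries no current and is not emitted).
    - ``RECOVERY``: 1 s P1 command to -40 mV, a variable interpulse gap
      (0.1 ... 3162 ms), then a 40 ms P2 command scaled by the recovered
      fraction; sweeps are padded to a common length.
    - ``LATE_STEP``: 1 s command to -20 mV from -120 mV holding, 50 ms
      baseline, 100 ms tail.

    ``rise_tau_ms`` optionally smooths the instantaneous activation with an
    exponential rise for visual realism; the default 0 emits the ideal
    instantaneous-peak family, because any causal rise filter couples the
    sampled peak amplitude to tau_inact(V) and systematically distorts the
    activation curve the analysis measures back.  Gaussian noise of
    ``noise_sd`` pA/pF is added with the given seed; a fixed seed is
    bit-reproducible.
    """
    rng = np.random.default_rng(seed)

    def trace(samples, label):
        if noise_sd > 0:
            samples = samples + rng.normal(0.0, noise_sd, samples.size)
        return Trace(samples, dt=dt, t0=0.0, units="pA/pF", label=label)

    sweeps: dict[float, Trace] = {}
    if protocol == "IV_ACTIVATION":
        base_n = int(round(20.0 / dt))
        for v in np.arange(-80.0, 0.0 + 1e-9, 10.0):
            step = _step_current(params, float(v), 250.0, dt, rise_tau_ms)
            sweeps[float(v)] = trace(np.concatenate([np.zeros(base_n), step]),
                                     f"{v:g} mV")
        meta = {"step_start_ms": 20.0, "step_dur_ms": 250.0}
    elif protocol == "AVAILABILITY":
        base_n = int(round(20.0 / dt))
        test = _step_current(params, -40.0, 40.0, dt, rise_tau_ms)
        for vc in np.arange(-150.0, -50.0 + 1e-9, 10.0):
            h = float(params.h_inf(float(vc)))
            sweeps[float(vc)] = trace(
                np.concatenate([np.zeros(base_n), h * test]), f"cond {vc:g} mV")
        meta = {"step_start_ms": 20.0, "step_dur_ms": 40.0, "test_v_mv": -40.0}
    elif protocol == "RECOVERY":
        base_n = int(round(20.0 / dt))
        p1 = _step_current(params, -40.0, 1000.0, dt, rise_tau_ms)
        p2_full = _step_current(params, -40.0, 40.0, dt, rise_tau_ms)
        max_gap_n = int(round(max(RECOVERY_INTERVALS_MS) / dt))
        total_n = base_n + p1.size + max_gap_n + p2_full.size
        for interval in RECOVERY_INTERVALS_MS:
            gap_n = int(round(interval / dt))
            r = float(params.recovered_fraction(interval))
            samples = np.zeros(total_n)
            samples[base_n:base_n + p1.size] = p1
            j = base_n + p1.size + gap_n
            samples[j:j + p2_full.size] = r * p2_full
            sweeps[float(interval)] = trace(samples, f"gap {interval:g} ms")
        meta = {"p1_start_ms": 20.0, "p1_dur_ms": 1000.0, "p2_dur_ms": 40.0}
    elif protocol == "LATE_STEP":
        base_n = int(round(50.0 / dt))
        tail_n = int(round(100.0 / dt))
        step = _step_current(params, -20.0, 1000.0, dt, rise_tau_ms)
        samples = np.concatenate([np.zeros(base_n), step, np.zeros(tail_n)])
        sweeps[-20.0] = trace(samples, "late step -20 mV")
        meta = {"step_start_ms": 50.0, "step_dur_ms": 1000.0}
    else:
        raise ValueError(f"gen_ina_family cannot generate protocol '{protocol}'")
    return SweepFamily(sweeps, protocol, meta=meta)


# ---------------------------------------------------------------------------
# action-potential trains

@dataclass
class ApShapeParams:
    """Targets and shape controls for synthetic 1 Hz AP trains.

    The repolarization time course is a monotone piecewise-cubic through the
    four APD targets (times from the upstroke at which 25/50/75/90% of the
    peak-to-resting amplitude has been recovered), preceded by a logistic
    upstroke of steepness ``upstroke_tau``.  Per-beat jitter is applied to
    the APD90 anchor as Normal(0, jitter_sd).
    """

    rmp: float = -72.2       # mV
    peak: float = 48.0       # mV (overshoot)
    upstroke_tau: float = 0.2  # logistic steepness, ms
    apd25: float = 2.1
    apd50: float = 6.7
    apd75: float = 71.1
    apd90: float = 115.6
    jitter_sd: float = 0.0   # ms, on APD90
    n_beats: int = 15
    seed: int = 0
    cycle_ms: float = 1000.0
    stim_offset_ms: float = 20.0

    def __post_init__(self) -> None:
        apds = (self.apd25, self.apd50, self.apd75, self.apd90)
        if any(b <= a for a, b in zip(apds, apds[1:])):
            raise ValueError(
                f"APD targets must be strictly increasing "
                f"(apd25 < apd50 < apd75 < apd90), got {apds}")
        if self.peak <= self.rmp:
            raise ValueError("peak must exceed the resting potential")
        if self.jitter_sd < 0:
            raise ValueError("jitter sd must be non-negative")
        if self.apd90 * 1.3 > self.cycle_ms - self.stim_offset_ms - 20:
            raise ValueError("cycle too short for the requested APD90")


def _one_beat(p: ApShapeParams, apd90_k: float, dt: float) -> np.ndarray:
    """One beat on the local grid [0, cycle_ms); stimulus at stim_offset_ms."""
    n = int(round(p.cycle_ms / dt))
    t = dt * np.arange(n)
    amp = p.peak - p.rmp
    t_up = p.stim_offset_ms + 1.0          # instant of maximum dV/dt
    t_peak_rel = 3.0 * p.upstroke_tau      # logistic clamped to peak here
    sig3 = 1.0 / (1.0 + math.exp(-3.0))

    v = np.full(n, p.rmp)
    # upstroke: scaled logistic reaching exactly `peak` at t_up + t_peak_rel
    up = (t >= p.stim_offset_ms) & (t < t_up + t_peak_rel)
    v[up] = p.rmp + amp * (1.0 / (1.0 + np.exp(-(t[up] - t_up) / p.upstroke_tau))) / sig3

    # monotone repolarization through the APD anchors (times from t_up)
    anchors_t = [t_peak_rel, p.apd25, p.apd50, p.apd75, apd90_k,
                 min(apd90_k * 1.3, p.cycle_ms - p.stim_offset_ms - 15.0),
                 p.cycle_ms - p.stim_offset_ms - 5.0]
    anchors_f = [1.0, 0.75, 0.50, 0.25, 0.10, 0.02, 0.0]
    interp = PchipInterpolator(anchors_t, anchors_f)
    rep = (t >= t_up + t_peak_rel) & (t <= t_up + anchors_t[-1])
    v[rep] = p.rmp + amp * interp(t[rep] - t_up)
    return v


def gen_ap_train(params: ApShapeParams, dt: float = 0.1):
    """Generate a 1 Hz AP train; returns (Trace, stimulus times in ms).

    The noiseless first beat measures back its APD targets to within 0.5 ms;
    per-beat APD90 jitter is Normal(0, jitter_sd), seeded.
    """
    rng = np.random.default_rng(params.seed)
    beats = []
    stim_times = []
    for k in range(params.n_beats):
        eps = rng.normal(0.0, params.jitter_sd) if params.jitter_sd > 0 else 0.0
        apd90_k = max(params.apd90 + eps, params.apd75 + 1.0)
        beats.append(_one_beat(params, apd90_k, dt))
        stim_times.append(k * params.cycle_ms + params.stim_offset_ms)
    trace = Trace(np.concatenate(beats), dt=dt, t0=0.0, units="mV",
                  label="AP train")
    return trace, stim_times


# ---------------------------------------------------------------------------
# ECG

@dataclass
class EcgShapeParams:
    """Parameters of the Gaussian-bump synthetic ECG (times ms, amplitudes mV)."""

    rr: float = 130.7
    qrs: float = 10.8
    qt: float = 51.9
    p_amp: float = 0.10
    q_amp: float = -0.12
    r_amp: float = 1.0
    s_amp: float = -0.15
    t_amp: float = 0.25
    noise_burst_rate: float = 0.0   # bursts per second
    noise_burst_dur: float = 40.0   # ms
    noise_burst_amp: float = 0.4    # mV
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.qrs < self.qt:
            raise ValueError(f"QRS ({self.qrs}) must be shorter than QT ({self.qt})")
        if not self.qt < self.rr:
            raise ValueError(f"QT ({self.qt}) must be shorter than RR ({self.rr})")


def _gauss(t, centre, sigma, amp):
    return amp * np.exp(-0.5 * ((t - centre) / sigma) ** 2)


def gen_ecg(params: EcgShapeParams, duration_ms: float, dt: float = 0.1):
    """Synthetic ECG trace plus exact fiducial annotations.

    Each complex is a P-QRS-T sequence of Gaussian bumps on an isoelectric
    baseline; the annotation fiducials are the generator's own construction
    values (QRS onset 40% of the QRS width before the R peak, QT end QT after
    QRS onset, T peak at 75% of QT so the QT end falls after it).  Optional
    high-frequency noise bursts are injected at the given rate and returned
    as declared noise intervals.
    """
    rng = np.random.default_rng(params.seed)
    n = int(round(duration_ms / dt))
    t = dt * np.arange(n)
    v = np.zeros(n)
    complexes = []
    first_r = 50.0
    k = 0
    while True:
        r = first_r + k * params.rr
        qrs_on = r - 0.4 * params.qrs
        qt_end = qrs_on + params.qt
        if qt_end + 10.0 > duration_ms:
            break
        qrs_end = qrs_on + params.qrs
        v += _gauss(t, r, params.qrs / 7.0, params.r_amp)
        v += _gauss(t, qrs_on + 0.12 * params.qrs, params.qrs / 10.0, params.q_amp)
        v += _gauss(t, qrs_end - 0.12 * params.qrs, params.qrs / 10.0, params.s_amp)
        v += _gauss(t, r - 0.25 * params.rr, 4.0, params.p_amp)
        v += _gauss(t, qrs_on + 0.75 * params.qt, 0.09 * params.qt, params.t_amp)
        complexes.append(ComplexFiducials(k, qrs_on, r, qrs_end, qt_end))
        k += 1
    noise_intervals = []
    if params.noise_burst_rate > 0:
        n_bursts = rng.poisson(params.noise_burst_rate * duration_ms / 1000.0)
        for start in np.sort(rng.uniform(0, duration_ms - params.noise_burst_dur,
                                         n_bursts)):
            end = start + params.noise_burst_dur
            sel = (t >= start) & (t < end)
            v[sel] += params.noise_burst_amp * np.sin(2 * np.pi * 0.3 * t[sel]) \
                * rng.normal(1.0, 0.3)
            noise_intervals.append((float(start), float(end)))
    trace = Trace(v, dt=dt, t0=0.0, units="mV", label="synthetic ECG")
    return trace, EcgAnnotation(complexes, noise_intervals)


# ---------------------------------------------------------------------------
# breathing

def gen_breaths(base_te: float = 0.2, rate: float = 140.0, apnoeas=(),
                duration_s: float = 2400.0, jitter_cv: float = 0.05,
                seed: int = 0, adaptation_s: float = 1200.0,
                analysis_s: float = 1200.0) -> BreathRecord:
    """Regular breath events with lognormal expiration-time jitter.

    ``apnoeas`` is a list of (time s, length s); at each requested time the
    nearest normal breath is replaced by one with expiration time ``length``.
    Requesting two apnoeas on the same breath raises ``ValueError``.
    """
    interval = 60.0 / rate
    onsets = np.arange(0.0, duration_s, interval)
    rng = np.random.default_rng(seed)
    if jitter_cv > 0:
        sigma = math.sqrt(math.log(1.0 + jitter_cv ** 2))
        te = rng.lognormal(math.log(base_te), sigma, onsets.size)
    else:
        te = np.full(onsets.size, base_te)
    spans: list[tuple[float, float]] = []
    used = set()
    for at, length in apnoeas:
        if not 0 <= at < duration_s:
            raise ValueError(f"apnoea time {at} s outside the record")
        if any(at < e and s < at + length for s, e in spans):
            raise ValueError(f"overlapping apnoeas near {at} s")
        spans.append((at, at + length))
        idx = int(np.argmin(np.abs(onsets - at)))
        if idx in used:
            raise ValueError(f"overlapping apnoeas near {at} s")
        used.add(idx)
        te[idx] = length
    return BreathRecord(onsets, te, adaptation_s=adaptation_s,
                        analysis_s=analysis_s)
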