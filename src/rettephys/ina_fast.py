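"""Fast sodium-current analysis.

Covers the full voltage-clamp workflow for fast I_Na: peak current-voltage
relation, reversal-potential extrapolation from the ascending limb, the
conductance transform G = I/(V - E_rev), Boltzmann fits of activation
(G/Gmax) and availability (I/Imax), single-exponential inactivation time
constants, the steady-state "window" current (product of the activation and
availability sigmoids with Gmax and driving force), and biexponential
recovery from inactivation.

All fits are unweighted nonlinear least squares (scipy ``curve_fit``) with
data-driven initial guesses: midpoints from the interpolated half-maximum
crossing, slope factors from the 25-75% level spread divided by 2.2, and
time constants from log-linear regression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import linregress

from .core_io import (FitError, InsufficientDataError, PipelineConfig,
                      SweepFamily, Trace, UnitError)


@dataclass
class IvPoint:
    vm: float            # command voltage, mV
    peak_density: float  # pA/pF, inward negative


@dataclass
class BoltzmannFit:
    v_half: float
    k: float
    scale: float
    residual_sse: float
    kind: str            # "activation" or "availability"
    converged: bool = True


@dataclass
class InactivationTauFit:
    tau: float           # ms
    amplitude: float     # pA/pF, signed
    offset: float        # pA/pF
    residual_sse: float
    t_fit_start: float
    t_fit_end: float


@dataclass
class RecoveryFit:
    tau_fast: float
    tau_slow: float
    a_fast: float
    a_slow: float
    residual_sse: float


@dataclass
class WindowCurve:
    """Window-current magnitude on a fixed voltage grid (sign removed)."""

    grid: np.ndarray
    values: np.ndarray

    @property
    def peak_v(self) -> float:
        return float(self.grid[int(np.argmax(self.values))])


def boltzmann(v, v_half, k):
    """Rising sigmoid 1 / (1 + exp((v_half - v)/k)); 0.5 at v = v_half."""
    return 1.0 / (1.0 + np.exp((v_half - v) / k))


def availability_sigmoid(v, v_half, k):
    """Falling sigmoid 1 - boltzmann(v); full availability at very negative v."""
    return 1.0 - boltzmann(v, v_half, k)


def _step_window(family: SweepFamily):
    try:
        start = float(family.meta["step_start_ms"])
        dur = float(family.meta["step_dur_ms"])
    except KeyError as exc:
        raise KeyError("family.meta must provide 'step_start_ms' and "
                       "'step_dur_ms' for peak measurement") from exc
    return start, dur


def _baseline_peak(trace: Trace, step_start: float, step_dur: float,
                   baseline_ms: float) -> float:
    """Most-negative baseline-subtracted current within the test step."""
    b0 = max(trace.t0, step_start - baseline_ms)
    if step_start - b0 >= trace.dt:
        baseline = float(np.mean(trace.slice(b0, step_start).samples))
    else:
        baseline = 0.0
    seg = trace.slice(step_start, step_start + step_dur)
    return float(np.min(seg.samples - baseline))


def peak_iv(family: SweepFamily,
            config: PipelineConfig | None = None) -> list[IvPoint]:
    """Peak current density per command voltage from an I-V protocol family.

    Sweeps must already be capacitance-normalised (pA/pF); the peak is the
    most-negative baseline-subtracted value within the test step (inward
    current convention).
    """
    cfg = config or PipelineConfig()
    step_start, step_dur = _step_window(family)
    points = []
    for vm in family.keys:
        tr = family.sweeps[vm]
        if not tr.units.endswith("/pF"):
            raise UnitError(f"sweep at {vm} mV has units '{tr.units}'; "
                            f"density-normalise first")
        points.append(IvPoint(vm, _baseline_peak(tr, step_start, step_dur,
                                                 cfg.iv_baseline_ms)))
    return points


def estimate_erev(iv: list[IvPoint],
                  n_points: int | None = None) -> float:
    """Reversal potential extrapolated from the ascending limb of the I-V.

    The ascending limb is every point positive to the voltage of minimum
    (most-negative) current; a least-squares line through those points is
    extrapolated to zero current.  ``n_points`` restricts the limb to its
    first points (counting from the minimum) if given.
    """
    pts = sorted(iv, key=lambda p: p.vm)
    v = np.array([p.vm for p in pts])
    i = np.array([p.peak_density for p in pts])
    v_min = v[int(np.argmin(i))]
    asc = v > v_min
    va, ia = v[asc], i[asc]
    if n_points is not None:
        va, ia = va[:n_points], ia[:n_points]
    if va.size < 3:
        raise InsufficientDataError(
            f"reversal-potential extrapolation needs >= 3 ascending-limb "
            f"points, found {va.size} positive to the I-V minimum at {v_min} mV")
    res = linregress(va, ia)
    if res.slope == 0:
        raise FitError("ascending limb has zero slope; cannot extrapolate E_rev")
    return float(-res.intercept / res.slope)


def conductance(iv: list[IvPoint], erev: float) -> list[tuple[float, float]]:
    """Chord conductance G = I/(V - E_rev) per I-V point.

    Points within 1 mV of the reversal potential are excluded with a warning
    (the transform is singular there).
    """
    out = []
    for p in iv:
        if abs(p.vm - erev) < 1.0:
            warnings.warn(f"excluding I-V point at {p.vm} mV: within 1 mV of "
                          f"E_rev = {erev:.2f} mV", stacklevel=2)
            continue
        out.append((p.vm, p.peak_density / (p.vm - erev)))
    if not out:
        raise InsufficientDataError("all I-V points lie within 1 mV of E_rev")
    return out


def _guess_midpoint(v: np.ndarray, y: np.ndarray, rising: bool):
    """Initial (v_half, k) from interpolated 0.5 / 0.25 / 0.75 level crossings."""
    order = np.argsort(v)
    v, y = v[order], y[order]
    ys = y if rising else y[::-1]
    vs = v if rising else v[::-1]
    # np.interp needs increasing x; ys is (approximately) increasing now
    def level(p):
        return float(np.interp(p, ys, vs))
    v_half = level(0.5)
    k = abs(level(0.75) - level(0.25)) / 2.2
    return v_half, max(k, 0.5)


def _fit_sigmoid(v, y, model, rising, kind, cfg) -> BoltzmannFit:
    # a free scale factor absorbs the noise of the single normalisation point
    # (G_max or I_max); it is 1 for ideal normalised data
    p0 = (*_guess_midpoint(v, y, rising), 1.0)

    def scaled(vv, v_half, k, s):
        return s * model(vv, v_half, k)

    try:
        popt, _ = curve_fit(scaled, v, y, p0=p0,
                            bounds=([-np.inf, 1e-6, 0.1], [np.inf, np.inf, 3.0]),
                            xtol=cfg.fit_xtol, maxfev=20000)
    except RuntimeError as exc:
        raise FitError(f"{kind} Boltzmann fit failed to converge "
                       f"(initial guess v_half={p0[0]:.2f}, k={p0[1]:.2f}): "
                       f"{exc}") from exc
    resid = y - scaled(v, *popt)
    return BoltzmannFit(v_half=float(popt[0]), k=float(popt[1]),
                        scale=float(popt[2]),
                        residual_sse=float(resid @ resid), kind=kind)


def fit_activation(gv: list[tuple[float, float]],
                   v_range: tuple[float, float] | None = None,
                   config: PipelineConfig | None = None) -> BoltzmannFit:
    """Boltzmann fit of normalised conductance G/Gmax over the activation range.

    Gmax is the maximum conductance over the whole protocol (not a fitted
    parameter); the fit uses points within ``v_range`` (default -80..-20 mV).
    """
    cfg = config or PipelineConfig()
    v_range = v_range or cfg.act_fit_range
    v = np.array([p[0] for p in gv], dtype=float)
    g = np.array([p[1] for p in gv], dtype=float)
    gmax = g.max()
    if gmax <= 0:
        raise FitError("non-positive maximum conductance; check sign conventions")
    sel = (v >= v_range[0]) & (v <= v_range[1])
    if sel.sum() < 5:
        raise InsufficientDataError(
            f"activation fit needs >= 5 points in {v_range}, found {int(sel.sum())}")
    return _fit_sigmoid(v[sel], g[sel] / gmax, boltzmann, True, "activation", cfg)


def fit_availability(inact: list[tuple[float, float]],
                     v_range: tuple[float, float] | None = None,
                     config: PipelineConfig | None = None) -> BoltzmannFit:
    """Boltzmann fit of normalised availability I/Imax over the conditioning range."""
    cfg = config or PipelineConfig()
    v_range = v_range or cfg.avail_fit_range
    v = np.array([p[0] for p in inact], dtype=float)
    y = np.array([p[1] for p in inact], dtype=float)
    if np.any(y < -0.05) or np.any(y > 1.1):
        raise ValueError("availability values must lie in [0, 1] (small "
                         "overshoot tolerated)")
    sel = (v >= v_range[0]) & (v <= v_range[1])
    if sel.sum() < 5:
        raise InsufficientDataError(
            f"availability fit needs >= 5 points in {v_range}, found {int(sel.sum())}")
    return _fit_sigmoid(v[sel], y[sel], availability_sigmoid, False,
                        "availability", cfg)


def fit_inactivation_tau(sweep: Trace, step_start: float, step_dur: float,
                         config: PipelineConfig | None = None) -> InactivationTauFit:
    """Single-exponential fit of the current decline after the I_Na peak.

    The fit window opens a configurable offset (default 0.2 ms) after the
    peak and closes where the baseline-subtracted current has decayed to 5%
    of the peak (capped at the step end).
    """
    cfg = config or PipelineConfig()
    b0 = max(sweep.t0, step_start - cfg.iv_baseline_ms)
    baseline = (float(np.mean(sweep.slice(b0, step_start).samples))
                if step_start - b0 >= sweep.dt else 0.0)
    seg = sweep.slice(step_start, step_start + step_dur)
    y = seg.samples - baseline
    t = seg.times
    i_peak = int(np.argmin(y))
    peak = y[i_peak]
    if i_peak >= y.size - 5:
        raise FitError("current peak lies at the end of the step; no decay to fit")
    t_start = t[i_peak] + cfg.tau_fit_start_offset_ms
    decayed = np.flatnonzero(np.abs(y[i_peak:]) <= cfg.tau_fit_end_fraction * abs(peak))
    t_end = t[i_peak + decayed[0]] if decayed.size else t[-1]
    sel = (t >= t_start) & (t <= t_end)
    if sel.sum() < 8:
        raise FitError(f"too few samples in the decay window "
                       f"[{t_start:.2f}, {t_end:.2f}] ms")
    tf, yf = t[sel], y[sel]
    if np.ptp(yf) < 1e-12 * max(abs(peak), 1.0):
        raise FitError("no resolvable decay after the peak (flat segment)")
    c0 = yf[-1]
    a0 = yf[0] - c0
    # log-linear regression for the initial time constant
    pos = (yf - c0) / a0 > 1e-6 if a0 != 0 else np.zeros(yf.size, bool)
    if pos.sum() >= 3:
        lr = linregress(tf[pos], np.log((yf[pos] - c0) / a0))
        tau0 = -1.0 / lr.slope if lr.slope < 0 else (t_end - t_start) / 2
    else:
        tau0 = (t_end - t_start) / 2

    def model(tt, a, tau, c):
        return a * np.exp(-(tt - tf[0]) / tau) + c

    try:
        popt, _ = curve_fit(model, tf, yf, p0=[a0, tau0, c0],
                            bounds=([-np.inf, 1e-6, -np.inf],
                                    [np.inf, np.inf, np.inf]),
                            xtol=cfg.fit_xtol, maxfev=20000)
    except RuntimeError as exc:
        raise FitError(f"inactivation tau fit failed (p0: a={a0:.3g}, "
                       f"tau={tau0:.3g}, c={c0:.3g}): {exc}") from exc
    if popt[1] > 100.0 * (t_end - t_start):
        raise FitError(f"fitted tau {popt[1]:.3g} ms vastly exceeds the fit "
                       f"window; decay unresolved")
    resid = yf - model(tf, *popt)
    return InactivationTauFit(tau=float(popt[1]), amplitude=float(popt[0]),
                              offset=float(popt[2]),
                              residual_sse=float(resid @ resid),
                              t_fit_start=float(tf[0]), t_fit_end=float(tf[-1]))


def window_current(act: BoltzmannFit, inact: BoltzmannFit, gmax: float,
                   erev: float, v_min: float = -120.0, v_max: float = 20.0,
                   v_step: float = 2.0) -> WindowCurve:
    """Steady-state window current on a 2 mV grid between -120 and +20 mV.

    w(V) = a(V) * h(V) * Gmax * (V - E_rev); the output is the sign-flipped
    (inward-positive) magnitude, with the physically outward tail positive to
    E_rev clipped at zero.
    """
    if not gmax > 0:
        raise ValueError(f"gmax must be positive, got {gmax}")
    if not (act.kind == "activation" and inact.kind == "availability"):
        raise ValueError("window_current expects an activation fit and an "
                         "availability fit, in that order")
    grid = np.arange(v_min, v_max + v_step / 2, v_step)
    a = boltzmann(grid, act.v_half, act.k)
    h = availability_sigmoid(grid, inact.v_half, inact.k)
    w = a * h * gmax * (grid - erev)
    return WindowCurve(grid=grid, values=np.clip(-w, 0.0, None))


def _recovery_model(t, a_f, a_s, tau_f, dtau):
    return 1.0 - (a_f * np.exp(-t / tau_f) + a_s * np.exp(-t / (tau_f + dtau)))


def fit_recovery(ratios: list[tuple[float, float]],
                 config: PipelineConfig | None = None) -> RecoveryFit:
    """Biexponential fit of recovery from inactivation, P2/P1 vs interval.

    The model is R(t) = 1 - (A_f exp(-t/tau_fast) + A_s exp(-t/tau_slow));
    tau ordering is enforced by parameterising tau_slow = tau_fast + delta
    with delta > 0.
    """
    cfg = config or PipelineConfig()
    pts = sorted(ratios)
    t = np.array([p[0] for p in pts], dtype=float)
    r = np.array([p[1] for p in pts], dtype=float)
    if t.size < 6:
        raise InsufficientDataError(f"recovery fit needs >= 6 intervals, got {t.size}")
    if np.any(r < -0.05) or np.any(r > 1.1):
        raise ValueError("P2/P1 ratios must lie in [0, 1] (small overshoot tolerated)")
    y0 = 1.0 - r
    total = float(np.clip(y0[0], 0.05, 1.0))
    # log-linear regression over the first time decade for tau_fast
    early = t <= max(10.0 * t[0], t[2])
    pos = early & (y0 > 1e-4)
    if pos.sum() >= 3:
        lr = linregress(t[pos], np.log(y0[pos]))
        tau_f0 = -1.0 / lr.slope if lr.slope < 0 else 10.0
    else:
        tau_f0 = 10.0
    tau_f0 = float(np.clip(tau_f0, t[0], t[-1]))
    last_err = None
    for tf0, split in ((tau_f0, 0.85), (tau_f0 / 3, 0.85), (3 * tau_f0, 0.7),
                       (10.0, 0.5)):
        p0 = [split * total, (1 - split) * total, tf0, 30.0 * tf0]
        try:
            popt, _ = curve_fit(_recovery_model, t, r, p0=p0,
                                bounds=([0.0, 0.0, 1e-6, 1e-6],
                                        [1.5, 1.5, np.inf, np.inf]),
                                xtol=cfg.fit_xtol, maxfev=40000)
            break
        except RuntimeError as exc:
            last_err = exc
    else:
        raise FitError(f"recovery fit failed to converge from all initial "
                       f"guesses (last: {last_err}); tau_fast guess {tau_f0:.3g} ms")
    a_f, a_s, tau_f, dtau = popt
    if a_f + a_s > 1.05:
        warnings.warn(f"recovery amplitudes sum to {a_f + a_s:.3f} > 1",
                      stacklevel=2)
    resid = r - _recovery_model(t, *popt)
    return RecoveryFit(tau_fast=float(tau_f), tau_slow=float(tau_f + dtau),
                       a_fast=float(a_f), a_slow=float(a_s),
                       residual_sse=float(resid @ resid))


# ---------------------------------------------------------------------------
# family-level helpers

def _peak_latency(trace: Trace, step_start: float, step_dur: float,
                  baseline_ms: float) -> float:
    """Latency of the most-negative baseline-subtracted sample within the step."""
    b0 = max(trace.t0, step_start - baseline_ms)
    baseline = (float(np.mean(trace.slice(b0, step_start).samples))
                if step_start - b0 >= trace.dt else 0.0)
    seg = trace.slice(step_start, step_start + step_dur)
    return float(seg.times[int(np.argmin(seg.samples - baseline))] - step_start)


def _read_at_latency(trace: Trace, step_start: float, step_dur: float,
                     latency: float, baseline_ms: float,
                     halfwidth: float = 0.2) -> float:
    """Baseline-subtracted mean current in a narrow window at a fixed latency.

    Reading every sweep of a protocol at the peak latency of its largest
    sweep avoids the negative bias a per-sweep minimum picks up from noise
    when the underlying current is small.
    """
    b0 = max(trace.t0, step_start - baseline_ms)
    baseline = (float(np.mean(trace.slice(b0, step_start).samples))
                if step_start - b0 >= trace.dt else 0.0)
    lo = max(step_start, step_start + latency - halfwidth)
    hi = min(step_start + step_dur, step_start + latency + halfwidth + trace.dt / 2)
    return float(np.mean(trace.slice(lo, hi).samples)) - baseline


def availability_curve(family: SweepFamily,
                       config: PipelineConfig | None = None) -> list[tuple[float, float]]:
    """I/Imax vs conditioning voltage from an availability-protocol family.

    The test-pulse current of every sweep is read at the peak latency of the
    largest-magnitude sweep and normalised to the maximal current observed
    during the protocol.
    """
    cfg = config or PipelineConfig()
    step_start, step_dur = _step_window(family)
    peaks = {vc: _baseline_peak(family.sweeps[vc], step_start, step_dur,
                                cfg.iv_baseline_ms)
             for vc in family.keys}
    ref = min(peaks, key=peaks.get)  # sweep with the largest inward current
    if peaks[ref] >= 0:
        raise FitError("no inward test-pulse current found in availability family")
    lat = _peak_latency(family.sweeps[ref], step_start, step_dur, cfg.iv_baseline_ms)
    reads = {vc: _read_at_latency(family.sweeps[vc], step_start, step_dur, lat,
                                  cfg.iv_baseline_ms)
             for vc in family.keys}
    i_max = reads[ref]
    return [(vc, reads[vc] / i_max) for vc in family.keys]


def recovery_ratios(family: SweepFamily,
                    config: PipelineConfig | None = None) -> list[tuple[float, float]]:
    """P2/P1 peak ratios per interpulse interval from a recovery family."""
    cfg = config or PipelineConfig()
    try:
        p1_start = float(family.meta["p1_start_ms"])
        p1_dur = float(family.meta["p1_dur_ms"])
        p2_dur = float(family.meta["p2_dur_ms"])
    except KeyError as exc:
        raise KeyError("recovery family.meta must provide 'p1_start_ms', "
                       "'p1_dur_ms' and 'p2_dur_ms'") from exc
    out = []
    for interval in family.keys:
        tr = family.sweeps[interval]
        if _baseline_peak(tr, p1_start, p1_dur, cfg.iv_baseline_ms) >= 0:
            raise FitError(f"no inward P1 current in recovery sweep at "
                           f"{interval} ms")
        # read P1 and P2 at P1's peak latency: the two pulses share a
        # waveform, so the narrow-window read cancels exactly in the ratio
        lat = _peak_latency(tr, p1_start, p1_dur, cfg.iv_baseline_ms)
        p1 = _read_at_latency(tr, p1_start, p1_dur, lat, cfg.iv_baseline_ms)
        p2_start = p1_start + p1_dur + interval
        p2 = _read_at_latency(tr, p2_start, p2_dur, lat, baseline_ms=0.0)
        out.append((interval, p2 / p1))
    return out


@dataclass
class IvAnalysis:
    iv: list
    erev: float
    gv: list
    gmax: float
    activation: BoltzmannFit


def analyse_iv(family: SweepFamily, erev: float | None = None,
               config: PipelineConfig | None = None) -> IvAnalysis:
    """Full I-V workflow: peaks, E_rev (unless supplied), conductance, activation fit."""
    cfg = config or PipelineConfig()
    iv = peak_iv(family, cfg)
    if erev is None:
        erev = estimate_erev(iv)
    gv = conductance(iv, erev)
    gmax = max(g for _, g in gv)
    act = fit_activation(gv, config=cfg)
    return IvAnalysis(iv=iv, erev=erev, gv=gv, gmax=gmax, activation=act)
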