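"""Action-potential feature extraction and beat-to-beat variability.

AP durations (APD_x) are measured from the instant of maximum upstroke
velocity to the first downward crossing of the potential that is x% of the
way from the overshoot back to the resting potential, with linear
interpolation between samples.  Triangulation is APD90 - APD25.  Beat-to-beat
variability of repolarization (BVR) is the mean absolute successive
difference of APD90 over 10-15 consecutive beats, divided by sqrt(2) — the
normalised Poincare short-term variability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core_io import EphysError, InsufficientDataError, PipelineConfig, Trace


@dataclass
class ApParams:
    """Single action-potential parameters.

    Potentials in mV, durations in ms, upstroke velocity ``vmax`` in V/s.
    APD values that could not be measured (no crossing before the segment
    end) are NaN and listed in ``missing``.
    """

    rmp: float
    overshoot: float
    amplitude: float
    vmax: float
    apd10: float
    apd25: float
    apd50: float
    apd75: float
    apd90: float
    triangulation: float
    missing: tuple = ()

    def apd(self, x: int) -> float:
        return getattr(self, f"apd{x}")


@dataclass
class BvrResult:
    bvr: float
    n_beats_used: int
    poincare_pairs: list = field(default_factory=list)


def segment_ap_train(trace: Trace, stim_times, pre_ms: float = 0.0) -> list[Trace]:
    """Split a 1 Hz AP train into per-beat segments.

    Each segment runs from its stimulus onset to the next stimulus onset (the
    last to the end of the trace).  ``pre_ms`` shifts every boundary earlier
    by that amount so each segment keeps a pre-stimulus baseline for the
    resting-potential estimate.
    """
    stim_times = list(stim_times)
    if any(b <= a for a, b in zip(stim_times, stim_times[1:])):
        raise ValueError("stimulus times must be strictly increasing")
    if not stim_times:
        raise ValueError("need at least one stimulus time")
    bounds = [max(s - pre_ms, trace.t0) for s in stim_times]
    bounds.append(trace.t0 + trace.duration)
    segments = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        if b <= a:
            raise EphysError(f"overlapping segments at stimulus {a} ms")
        segments.append(trace.slice(a, b))
    return segments


def _smooth(x: np.ndarray, npts: int) -> np.ndarray:
    if npts <= 1:
        return x
    # edge-replicate padding so the boundaries do not fabricate dV/dt spikes
    pad = npts // 2
    xp = np.concatenate([np.full(pad, x[0]), x, np.full(npts - 1 - pad, x[-1])])
    return np.convolve(xp, np.ones(npts) / npts, mode="valid")


def ap_params(ap: Trace, stim_time: float,
              config: PipelineConfig | None = None) -> ApParams:
    """Extract AP parameters from a single-beat segment.

    The resting potential is the mean over the 10 ms window ending at the
    stimulus onset; dV/dt uses a 3-point moving average followed by central
    differences (both configurable).
    """
    cfg = config or PipelineConfig()
    if stim_time - ap.t0 < cfg.ap_baseline_ms - 1e-9:
        raise InsufficientDataError(
            f"need >= {cfg.ap_baseline_ms} ms pre-stimulus baseline, segment "
            f"starts {stim_time - ap.t0:.2f} ms before the stimulus")
    baseline = ap.slice(stim_time - cfg.ap_baseline_ms, stim_time)
    rmp = float(np.mean(baseline.samples))

    v = ap.samples
    t = ap.times
    dvdt = np.gradient(_smooth(v, cfg.ap_smooth_points), ap.dt)  # mV/ms == V/s
    after = t >= stim_time
    i_up = int(np.flatnonzero(after)[0] + np.argmax(dvdt[after]))
    vmax = float(dvdt[i_up])
    t_up = float(t[i_up])

    i_peak = int(i_up + np.argmax(v[i_up:]))
    overshoot = float(v[i_peak])
    amplitude = overshoot - rmp

    apds: dict[int, float] = {}
    missing = []
    for x in (10, 25, 50, 75, 90):
        thr = overshoot - (x / 100.0) * amplitude
        below = np.flatnonzero(v[i_peak:] <= thr)
        if below.size == 0:
            apds[x] = math.nan
            missing.append(f"apd{x}")
            continue
        j = i_peak + below[0]
        if j == i_peak:
            t_cross = t[j]
        else:
            # linear interpolation between the bracketing samples
            v0, v1 = v[j - 1], v[j]
            frac = (v0 - thr) / (v0 - v1)
            t_cross = t[j - 1] + frac * ap.dt
        apds[x] = float(t_cross - t_up)
    return ApParams(
        rmp=rmp, overshoot=overshoot, amplitude=amplitude, vmax=vmax,
        apd10=apds[10], apd25=apds[25], apd50=apds[50], apd75=apds[75],
        apd90=apds[90], triangulation=apds[90] - apds[25],
        missing=tuple(missing),
    )


def bvr(apd90_series, min_beats: int = 10, max_beats: int = 15,
        denominator: str = "differences") -> BvrResult:
    """Beat-to-beat variability of repolarization from an APD90 series (ms).

    ``denominator`` selects the normalisation of the summed absolute
    successive differences: ``"differences"`` divides by the number of
    difference terms (N-1), ``"beats"`` by the number of beats (N); both
    include the sqrt(2) Poincare factor.
    """
    s = np.asarray(list(apd90_series), dtype=float)
    if s.size < 2:
        raise InsufficientDataError("BVR needs at least 2 beats")
    if s.size < min_beats:
        raise InsufficientDataError(
            f"BVR configured for >= {min_beats} beats, got {s.size}")
    s = s[:max_beats]
    diffs = np.abs(np.diff(s))
    if denominator == "differences":
        denom = diffs.size
    elif denominator == "beats":
        denom = s.size
    else:
        raise ValueError(f"unknown BVR denominator '{denominator}'")
    return BvrResult(
        bvr=float(diffs.sum() / (denom * math.sqrt(2.0))),
        n_beats_used=int(s.size),
        poincare_pairs=list(zip(s[:-1], s[1:])),
    )
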