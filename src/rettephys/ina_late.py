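"""Late sodium-current quantification and drug inhibition.

The late (persistent) sodium current is isolated as the sodium-sensitive
current by subtracting the trace recorded after replacing external Na+ with
NMDG from the control trace.  Three complementary measures exclude the large
initial fast transient: the current density at 300 ms and at 600 ms into the
step (each a +/-5 ms windowed mean by default), and the trapezoidal current
integral between 350 and 800 ms, expressed in pC/pF.  Drug effects are
summarised as percentage inhibition of each measure, computed on magnitudes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import AlignmentError, PipelineConfig, Trace


@dataclass
class LateCurrentMeasures:
    density_300: float       # pA/pF
    density_600: float       # pA/pF
    integral_350_800: float  # pC/pF  (pA/pF * ms = fC/pF, divided by 1000)


@dataclass
class InhibitionResult:
    pct_inhibition_300: float
    pct_inhibition_600: float
    pct_inhibition_integral: float


def na_sensitive_current(control: Trace, nmdg: Trace) -> Trace:
    """Pointwise NMDG subtraction: control minus sodium-free trace."""
    if control.dt != nmdg.dt:
        raise AlignmentError(f"dt mismatch: control {control.dt} ms vs "
                             f"NMDG {nmdg.dt} ms (resample before subtracting)")
    if control.n != nmdg.n:
        raise AlignmentError(f"length mismatch: control {control.n} vs "
                             f"NMDG {nmdg.n} samples")
    if control.units != nmdg.units:
        raise AlignmentError(f"unit mismatch: '{control.units}' vs '{nmdg.units}'")
    return Trace(control.samples - nmdg.samples, control.dt, control.t0,
                 control.units, label="Na-sensitive")


def _windowed_mean(trace: Trace, centre: float, halfwidth: float) -> float:
    if halfwidth <= 0:
        i = trace.index_at(centre)
        return float(trace.samples[min(i, trace.n - 1)])
    return float(np.mean(trace.slice(centre - halfwidth, centre + halfwidth).samples))


def late_measures(trace: Trace, step_start: float,
                  config: PipelineConfig | None = None) -> LateCurrentMeasures:
    """The three late-current measures from a density trace (pA/pF).

    ``step_start`` is the onset time of the 1 s depolarising command; the
    trace must span at least 800 ms beyond it.
    """
    cfg = config or PipelineConfig()
    end_needed = step_start + cfg.late_integral_end_ms
    if trace.t0 + trace.duration < end_needed - 1e-9:
        raise ValueError(
            f"trace ends at {trace.t0 + trace.duration:.1f} ms but the late "
            f"measures need data to {end_needed:.1f} ms after the step start")
    hw = cfg.late_window_halfwidth_ms
    d300 = _windowed_mean(trace, step_start + cfg.late_t1_ms, hw)
    d600 = _windowed_mean(trace, step_start + cfg.late_t2_ms, hw)
    seg = trace.slice(step_start + cfg.late_integral_start_ms,
                      step_start + cfg.late_integral_end_ms)
    # trapezoidal integral in (pA/pF)*ms = fC/pF; /1000 -> pC/pF
    integral = float(np.trapezoid(seg.samples, dx=seg.dt)) / 1000.0
    return LateCurrentMeasures(d300, d600, integral)


def pct_inhibition(pre: LateCurrentMeasures,
                   post: LateCurrentMeasures) -> InhibitionResult:
    """Percentage inhibition 100*(1 - |post|/|pre|) for each late measure."""

    def one(a: float, b: float, name: str) -> float:
        if a == 0:
            raise ZeroDivisionError(
                f"control {name} is zero; % inhibition undefined")
        return 100.0 * (1.0 - abs(b) / abs(a))

    return InhibitionResult(
        pct_inhibition_300=one(pre.density_300, post.density_300, "density_300"),
        pct_inhibition_600=one(pre.density_600, post.density_600, "density_600"),
        pct_inhibition_integral=one(pre.integral_350_800, post.integral_350_800,
                                    "integral"),
    )
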