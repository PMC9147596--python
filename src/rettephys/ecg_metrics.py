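"""ECG interval metrics and rate-corrected QT.

Intervals are measured from annotated fiducials (the QT end cannot be
delineated automatically from the recordings this pipeline targets, so it is
always taken from the annotation).  Per-animal values are means over the first
run of consecutive clean complexes (default 5), skipping complexes that
overlap declared breathing-noise intervals; the two rate corrections

    QTc = QT / sqrt(RR / 100)            (square-root form)
    QTc = QT + 0.3173 * (170 - RR)       (linear form, RR in ms)

are applied per complex and then averaged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .core_io import (DetectionError, EcgAnnotation, InsufficientDataError,
                      PipelineConfig, Trace)


@dataclass
class EcgComplexMetrics:
    """Interval metrics for one ECG complex (ms; HR in beats/min)."""

    complex_id: int
    rr: float
    hr: float
    qrs: float
    qt: float
    pr: float | None = None

    def __post_init__(self) -> None:
        if not (self.rr > 0 and self.qrs > 0 and self.qt > 0):
            raise ValueError(f"complex {self.complex_id}: intervals must be positive")
        if not self.qrs < self.qt:
            raise ValueError(f"complex {self.complex_id}: QRS ({self.qrs}) must be "
                             f"shorter than QT ({self.qt})")


@dataclass
class QtcResult:
    """Rate-corrected QT by the square-root (eq1) and linear (eq2) corrections (ms)."""

    qtc_eq1: float
    qtc_eq2: float


@dataclass
class EcgSummary:
    """Per-animal means over consecutive clean complexes."""

    rr: float
    hr: float
    qrs: float
    qt: float
    qtc_eq1: float
    qtc_eq2: float
    n_complexes: int
    pr: float | None = None


def _in_noise(t: float, noise: list[tuple[float, float]]) -> bool:
    return any(a <= t <= b for a, b in noise)


def detect_r_peaks(trace: Trace, config: PipelineConfig | None = None,
                   noise_intervals=()) -> np.ndarray:
    """Detect R-peak times (ms) by amplitude threshold with a refractory period.

    The threshold is a configurable fraction (default 0.6) of the 98th
    percentile of the rectified, median-centred signal; peaks closer than the
    refractory period (default 30 ms) are suppressed, and peaks inside
    declared noise intervals are dropped.
    """
    cfg = config or PipelineConfig()
    x = trace.samples - np.median(trace.samples)
    rect = np.abs(x)
    thr = cfg.rpeak_threshold_frac * np.percentile(rect, cfg.rpeak_percentile)
    if thr <= 0:
        raise DetectionError(
            f"no R peaks: detection threshold is zero (signal range "
            f"{trace.samples.min():.3g}..{trace.samples.max():.3g} {trace.units})")
    distance = max(1, int(round(cfg.rpeak_refractory_ms / trace.dt)))
    idx, _ = find_peaks(rect, height=thr, distance=distance)
    times = trace.t0 + idx * trace.dt
    noise = list(noise_intervals)
    times = np.array([t for t in times if not _in_noise(t, noise)])
    if times.size == 0:
        raise DetectionError(
            f"no R peaks above threshold {thr:.3g} {trace.units} "
            f"(98th percentile of rectified signal: "
            f"{np.percentile(rect, cfg.rpeak_percentile):.3g})")
    return times


def complex_metrics(annotations: EcgAnnotation,
                    r_peaks) -> list[EcgComplexMetrics]:
    """Per-complex RR/HR/QRS/QT from fiducials and detected R-peak times.

    RR(i) is the difference between the detected R peaks matched to complexes
    i+1 and i, so the last complex carries no RR and is not reported.
    Complexes whose span overlaps a noise interval are omitted.
    """
    r_peaks = np.sort(np.asarray(r_peaks, dtype=float))
    comps = sorted(annotations.complexes, key=lambda c: c.r_peak)
    if len(comps) < 2:
        raise InsufficientDataError("need at least 2 annotated complexes")

    def matched_peak(c):
        j = int(np.argmin(np.abs(r_peaks - c.r_peak)))
        return r_peaks[j]

    noise = annotations.noise_intervals
    clean = [c for c in comps
             if not any(a < c.qt_end and c.qrs_on < b for a, b in noise)]
    if len(clean) < 2:
        raise InsufficientDataError(
            f"fewer than 2 clean complexes ({len(clean)} after noise exclusion)")
    clean_ids = {c.complex_id for c in clean}
    out = []
    for c, c_next in zip(comps[:-1], comps[1:]):
        if c.complex_id not in clean_ids:
            continue
        rr = matched_peak(c_next) - matched_peak(c)
        out.append(EcgComplexMetrics(
            complex_id=c.complex_id,
            rr=rr,
            hr=60000.0 / rr,
            qrs=c.qrs_end - c.qrs_on,
            qt=c.qt_end - c.qrs_on,
        ))
    return out


def qtc(qt: float, rr: float) -> QtcResult:
    """Both rate corrections of a QT interval, with QT and RR in ms."""
    if not (qt > 0 and rr > 0):
        raise ValueError(f"QT and RR must be positive, got qt={qt}, rr={rr}")
    return QtcResult(qtc_eq1=qt / math.sqrt(rr / 100.0),
                     qtc_eq2=qt + 0.3173 * (170.0 - rr))


def summarise_ecg(metrics: list[EcgComplexMetrics],
                  n_complexes: int = 5) -> EcgSummary:
    """Average the first run of ``n_complexes`` consecutive clean complexes.

    Consecutive means consecutive ``complex_id`` values (a gap marks a complex
    dropped for noise).  QTc is computed per complex and then averaged.
    """
    if n_complexes < 1:
        raise ValueError("n_complexes must be >= 1")
    ms = sorted(metrics, key=lambda m: m.complex_id)
    run: list[EcgComplexMetrics] = []
    longest = 0
    chosen = None
    for m in ms:
        if run and m.complex_id == run[-1].complex_id + 1:
            run.append(m)
        else:
            run = [m]
        longest = max(longest, len(run))
        if len(run) == n_complexes:
            chosen = list(run)
            break
    if chosen is None:
        raise InsufficientDataError(
            f"need {n_complexes} consecutive clean complexes; longest clean "
            f"run found was {longest}")
    corr = [qtc(m.qt, m.rr) for m in chosen]
    return EcgSummary(
        rr=float(np.mean([m.rr for m in chosen])),
        hr=float(np.mean([m.hr for m in chosen])),
        qrs=float(np.mean([m.qrs for m in chosen])),
        qt=float(np.mean([m.qt for m in chosen])),
        qtc_eq1=float(np.mean([c.qtc_eq1 for c in corr])),
        qtc_eq2=float(np.mean([c.qtc_eq2 for c in corr])),
        n_complexes=n_complexes,
    )
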