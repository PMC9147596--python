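"""Apnoea detection from breath-event series and the APD90 correlation.

A breath is scored as an apnoea when its expiration time exceeds a threshold
multiple (default 4) of the running-average expiration time.  The running
average is taken every minute: the reference applied to the breaths of a
minute is the mean expiration time of the non-apnoeic breaths of the
preceding minute (a per-breath trailing 60 s window is available as an
alternative).  Apnoeic breaths are excluded from subsequent references so a
long apnoea does not inflate its own baseline, and consecutive apnoeic
breaths merge into one episode.  Records follow the plethysmography session
structure: an adaptation window (default 20 min) that is never scored,
followed by the analysis window (default 20 min).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core_io import InsufficientDataError


@dataclass
class BreathRecord:
    """Ordered breath events: onset times and expiration times, in seconds."""

    onsets: np.ndarray
    te: np.ndarray
    adaptation_s: float = 1200.0
    analysis_s: float = 1200.0

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=float)
        self.te = np.asarray(self.te, dtype=float)
        if self.onsets.size != self.te.size:
            raise ValueError("onsets and expiration times must have equal length")
        if self.onsets.size and np.any(np.diff(self.onsets) <= 0):
            raise ValueError("breath onsets must be strictly increasing")
        if np.any(self.te <= 0):
            raise ValueError("expiration times must be positive")


@dataclass
class ApnoeaSummary:
    count: int
    lengths: list = field(default_factory=list)

    @property
    def mean_length(self) -> float:
        return float(np.mean(self.lengths)) if self.lengths else 0.0


def classify_apnoeic_breaths(record: BreathRecord, factor: float = 4.0,
                             mode: str = "per_minute") -> np.ndarray:
    """Boolean apnoea flag per breath, over the whole record.

    Breaths with no defined reference (first minute, or an empty preceding
    window) are never flagged.
    """
    onsets, te = record.onsets, record.te
    n = onsets.size
    flags = np.zeros(n, dtype=bool)
    if mode == "per_minute":
        minute = np.floor(onsets / 60.0).astype(int)
        # chronological pass; the reference of minute m is fixed by minute m-1
        ref_cache: dict[int, float | None] = {}
        for i in range(n):
            m = minute[i]
            if m not in ref_cache:
                prev = (minute == m - 1) & ~flags
                ref_cache[m] = float(np.mean(te[prev])) if prev.any() else None
            ref = ref_cache[m]
            if ref is not None and te[i] > factor * ref:
                flags[i] = True
    elif mode == "trailing":
        for i in range(n):
            window = (onsets >= onsets[i] - 60.0) & (onsets < onsets[i]) & ~flags[:n]
            window &= np.arange(n) < i
            if window.any():
                ref = float(np.mean(te[window]))
                if te[i] > factor * ref:
                    flags[i] = True
    else:
        raise ValueError(f"unknown apnoea mode '{mode}'")
    return flags


def detect_apnoeas(record: BreathRecord, factor: float = 4.0,
                   mode: str = "per_minute") -> ApnoeaSummary:
    """Count and measure apnoea episodes within the analysis window.

    Episode length is the total expiration time of its member breaths;
    consecutive apnoeic breaths merge into one episode.  An episode is
    attributed to the analysis window by the onset of its first breath.
    """
    t_start = record.adaptation_s
    t_end = record.adaptation_s + record.analysis_s
    in_window = (record.onsets >= t_start) & (record.onsets < t_end)
    if not in_window.any():
        raise InsufficientDataError(
            f"no breaths in the analysis window [{t_start}, {t_end}) s")
    flags = classify_apnoeic_breaths(record, factor=factor, mode=mode)
    lengths = []
    i = 0
    n = flags.size
    while i < n:
        if flags[i]:
            j = i
            while j + 1 < n and flags[j + 1]:
                j += 1
            if t_start <= record.onsets[i] < t_end:
                lengths.append(float(np.sum(record.te[i:j + 1])))
            i = j + 1
        else:
            i += 1
    return ApnoeaSummary(count=len(lengths), lengths=lengths)


def apd_apnoea_correlation(pairs) -> tuple[float, float]:
    """Pearson correlation between per-animal mean APD90 and mean apnoea length.

    Returns (r, two-sided p) from the t transform t = r*sqrt((n-2)/(1-r^2)).
    Raises :class:`InsufficientDataError` for < 3 pairs and ``ValueError``
    when either variable is constant (r undefined).
    """
    pairs = list(pairs)
    if len(pairs) < 3:
        raise InsufficientDataError("correlation needs >= 3 animal pairs")
    x = np.array([p[0] for p in pairs], dtype=float)
    y = np.array([p[1] for p in pairs], dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined: one variable is constant")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)
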