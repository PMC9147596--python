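"""Shared data model, file formats and configuration for the pipeline.

Canonical units throughout the package: time in ms, membrane potential in mV,
current in pA, capacitance in pF, current density in pA/pF, charge density in
pC/pF.  Inward current is negative (standard electrophysiology convention).

The on-disk sweep-table format is a plain UTF-8 CSV with header
``time_ms,<key1>,<key2>,...`` where the keys are protocol values (command
voltages in mV or interpulse intervals in ms), accompanied by a JSON sidecar
``<name>.meta.json`` holding ``protocol``, ``capacitance_pF``, ``dt_ms`` and
any protocol timing metadata.  Values are serialised with 17 significant
digits so that a write/read round trip is bit-exact for finite doubles.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

PROTOCOLS = ("IV_ACTIVATION", "AVAILABILITY", "RECOVERY", "LATE_STEP", "AP_TRAIN")


class EphysError(Exception):
    """Base class for pipeline errors."""


class FormatError(EphysError):
    """Malformed input file."""


class SamplingError(EphysError):
    """Non-uniform or invalid time base."""


class UnitError(EphysError):
    """Inconsistent or missing physical units."""


class AlignmentError(EphysError):
    """Traces that must share a time base do not."""


class FitError(EphysError):
    """A nonlinear fit failed to converge or is degenerate."""


class InsufficientDataError(EphysError):
    """Fewer clean data points than the operation requires."""


class DetectionError(EphysError):
    """Event detection found nothing usable."""


@dataclass
class Trace:
    """A uniformly sampled signal.

    Parameters
    ----------
    samples : array-like
        Sample values (mV for voltage, pA or pA/pF for current).
    dt : float
        Sampling interval in ms (default 0.1 ms, i.e. 10 kHz digitisation).
    t0 : float
        Time of the first sample, ms.
    units : str
        Physical units of the samples.
    label : str
        Free-text description.
    """

    samples: np.ndarray
    dt: float = 0.1
    t0: float = 0.0
    units: str = "mV"
    label: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("Trace requires a non-empty 1-D sample array")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("Trace samples must all be finite")
        if not (self.dt > 0):
            raise SamplingError(f"sampling interval must be positive, got {self.dt}")

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.n)

    @property
    def duration(self) -> float:
        return self.dt * self.n

    def index_at(self, t: float) -> int:
        """Index of the sample grid point at or immediately after time ``t``."""
        return int(np.ceil((t - self.t0) / self.dt - 1e-9))

    def slice(self, t_start: float, t_end: float) -> "Trace":
        """Sub-trace on the half-open window ``[t_start, t_end)``."""
        i0 = max(self.index_at(t_start), 0)
        i1 = min(self.index_at(t_end), self.n)
        if i1 <= i0:
            raise ValueError(f"empty slice [{t_start}, {t_end}) of trace '{self.label}'")
        return Trace(self.samples[i0:i1], self.dt, self.t0 + i0 * self.dt,
                     self.units, self.label)


def density_normalise(trace: Trace, capacitance: float | None) -> Trace:
    """Convert a current trace (pA) to current density (pA/pF).

    Raises :class:`UnitError` if the capacitance is missing, or if the trace is
    already expressed as a density (normalising twice is rejected by the unit
    bookkeeping).
    """
    if capacitance is None:
        raise UnitError("cell capacitance is required to normalise to pA/pF; "
                        "supply it in the sweep-table sidecar or as an argument")
    if not capacitance > 0:
        raise ValueError(f"capacitance must be positive, got {capacitance}")
    if trace.units.endswith("/pF"):
        raise UnitError(f"trace '{trace.label}' is already capacitance-normalised "
                        f"({trace.units}); refusing to normalise twice")
    if trace.units != "pA":
        raise UnitError(f"density normalisation expects a current trace in pA, "
                        f"got units '{trace.units}'")
    return Trace(trace.samples / capacitance, trace.dt, trace.t0, "pA/pF", trace.label)


@dataclass
class SweepFamily:
    """A set of traces recorded under one voltage-clamp protocol.

    ``sweeps`` maps the protocol key (command voltage in mV, or interpulse
    interval in ms) to the corresponding :class:`Trace`.  ``meta`` carries
    protocol timing (e.g. ``step_start_ms``) used by the analysis stages.
    """

    sweeps: dict[float, Trace]
    protocol: str
    capacitance: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.protocol not in PROTOCOLS:
            raise ValueError(f"unknown protocol '{self.protocol}'; "
                             f"expected one of {PROTOCOLS}")
        if not self.sweeps:
            raise ValueError("SweepFamily requires at least one sweep")
        dts = {t.dt for t in self.sweeps.values()}
        if len(dts) != 1:
            raise AlignmentError(f"all sweeps must share dt; found {sorted(dts)}")
        if self.capacitance is not None and not self.capacitance > 0:
            raise ValueError(f"capacitance must be positive, got {self.capacitance}")

    @property
    def dt(self) -> float:
        return next(iter(self.sweeps.values())).dt

    @property
    def keys(self) -> list[float]:
        return sorted(self.sweeps)


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix("").with_name(path.with_suffix("").name + ".meta.json")


def _format_key(k: float) -> str:
    return f"{k:g}"


def write_sweep_table(family: SweepFamily, path: str | Path) -> None:
    """Write a sweep family as a CSV sweep table plus JSON sidecar.

    All sweeps must share length (the table has one common time column).
    """
    path = Path(path)
    keys = family.keys
    lengths = {family.sweeps[k].n for k in keys}
    if len(lengths) != 1:
        raise FormatError(f"sweep-table export requires equal-length sweeps; "
                          f"found lengths {sorted(lengths)}")
    first = family.sweeps[keys[0]]
    cols = {"time_ms": first.times}
    for k in keys:
        cols[_format_key(k)] = family.sweeps[k].samples
    df = pd.DataFrame(cols)
    try:
        df.to_csv(path, index=False, float_format="%.17g")
    except OSError as exc:
        raise EphysError(f"cannot write sweep table to {path}: {exc}") from exc
    sidecar = {
        "protocol": family.protocol,
        "dt_ms": family.dt,
        "t0_ms": first.t0,
        "units": first.units,
        "meta": family.meta,
    }
    if family.capacitance is not None:
        sidecar["capacitance_pF"] = family.capacitance
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))


def read_sweep_table(path: str | Path, config: "PipelineConfig | None" = None) -> SweepFamily:
    """Read a sweep-table CSV (and sidecar, if present) into a SweepFamily.

    The first column must be ``time_ms`` on a uniform grid; every further
    column header must parse as a protocol key.  Missing sidecar fields fall
    back to the :class:`PipelineConfig` defaults with a warning.
    """
    path = Path(path)
    cfg = config or PipelineConfig()
    df = pd.read_csv(path, float_precision="round_trip")
    if df.shape[1] < 2 or df.columns[0] != "time_ms":
        raise FormatError(f"{path}: first column must be 'time_ms', "
                          f"got '{df.columns[0]}'")
    keys = []
    for col in df.columns[1:]:
        try:
            keys.append(float(col))
        except ValueError:
            raise FormatError(f"{path}: column header '{col}' is not a numeric "
                              f"protocol key") from None
    t = df["time_ms"].to_numpy(float)
    if t.size < 2:
        raise SamplingError(f"{path}: need at least two time points")
    steps = np.diff(t)
    dt = float(np.median(steps))
    if dt <= 0 or not np.allclose(steps, dt, rtol=1e-6, atol=1e-9):
        raise SamplingError(f"{path}: time column is not a uniform grid")

    sidecar_file = _sidecar_path(path)
    if sidecar_file.exists():
        sidecar = json.loads(sidecar_file.read_text())
    else:
        warnings.warn(f"{path}: sidecar {sidecar_file.name} missing; using "
                      f"config defaults", stacklevel=2)
        sidecar = {}
    protocol = sidecar.get("protocol")
    if protocol is None:
        warnings.warn(f"{path}: sidecar omits 'protocol'; defaulting to "
                      f"{cfg.default_protocol}", stacklevel=2)
        protocol = cfg.default_protocol
    units = sidecar.get("units", "pA")
    t0 = float(t[0])
    sweeps = {}
    for col, k in zip(df.columns[1:], keys):
        sweeps[k] = Trace(df[col].to_numpy(float), dt, t0, units, label=col)
    return SweepFamily(sweeps, protocol,
                       capacitance=sidecar.get("capacitance_pF"),
                       meta=sidecar.get("meta", {}))


@dataclass
class ComplexFiducials:
    """Manually or synthetically annotated fiducial times for one ECG complex (ms)."""

    complex_id: int
    qrs_on: float
    r_peak: float
    qrs_end: float
    qt_end: float

    def __post_init__(self) -> None:
        if not (self.qrs_on < self.r_peak < self.qrs_end <= self.qt_end):
            raise ValueError(
                f"complex {self.complex_id}: fiducials must satisfy "
                f"qrs_on < r_peak < qrs_end <= qt_end, got "
                f"({self.qrs_on}, {self.r_peak}, {self.qrs_end}, {self.qt_end})")


def merge_intervals(intervals) -> list[tuple[float, float]]:
    """Sort and merge overlapping (start, end) intervals."""
    ivs = sorted((float(a), float(b)) for a, b in intervals)
    out: list[tuple[float, float]] = []
    for a, b in ivs:
        if b < a:
            raise ValueError(f"interval end before start: ({a}, {b})")
        if out and a <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], b))
        else:
            out.append((a, b))
    return out


@dataclass
class EcgAnnotation:
    """Per-complex fiducials plus declared noise intervals for an ECG trace."""

    complexes: list[ComplexFiducials]
    noise_intervals: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.noise_intervals = merge_intervals(self.noise_intervals)


def read_annotations(path: str | Path, noise_path: str | Path | None = None) -> EcgAnnotation:
    """Read an annotation CSV (complex_id,qrs_on_ms,r_peak_ms,qrs_end_ms,qt_end_ms)
    plus an optional noise CSV (start_ms,end_ms)."""
    df = pd.read_csv(path)
    required = ["complex_id", "qrs_on_ms", "r_peak_ms", "qrs_end_ms", "qt_end_ms"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing annotation columns {missing}")
    complexes = [ComplexFiducials(int(r.complex_id), r.qrs_on_ms, r.r_peak_ms,
                                  r.qrs_end_ms, r.qt_end_ms)
                 for r in df.itertuples()]
    noise = []
    if noise_path is not None:
        nd = pd.read_csv(noise_path)
        noise = list(zip(nd["start_ms"], nd["end_ms"]))
    return EcgAnnotation(complexes, noise)


def write_annotations(ann: EcgAnnotation, path: str | Path) -> None:
    pd.DataFrame(
        {"complex_id": [c.complex_id for c in ann.complexes],
         "qrs_on_ms": [c.qrs_on for c in ann.complexes],
         "r_peak_ms": [c.r_peak for c in ann.complexes],
         "qrs_end_ms": [c.qrs_end for c in ann.complexes],
         "qt_end_ms": [c.qt_end for c in ann.complexes]}
    ).to_csv(path, index=False, float_format="%.17g")


@dataclass
class PipelineConfig:
    """Every tunable decision of the pipeline, with documented defaults.

    Unknown keys are rejected (constructing with an unexpected keyword raises
    ``TypeError``), so configuration typos fail loudly.
    """

    #: default sampling interval when a file omits it (ms; 10 kHz digitisation)
    default_dt_ms: float = 0.1
    #: protocol assumed when a sweep-table sidecar is missing
    default_protocol: str = "IV_ACTIVATION"

    # --- ECG ---
    #: R-peak threshold as a fraction of the 98th percentile of the rectified signal
    rpeak_threshold_frac: float = 0.6
    #: percentile of the rectified signal used for the detection threshold
    rpeak_percentile: float = 98.0
    #: R-peak detector refractory period (ms)
    rpeak_refractory_ms: float = 30.0
    #: number of consecutive clean complexes averaged per animal
    ecg_n_complexes: int = 5

    # --- action potentials ---
    #: pre-stimulus window for the resting-potential estimate (ms)
    ap_baseline_ms: float = 10.0
    #: moving-average width (samples) applied before dV/dt
    ap_smooth_points: int = 3
    #: minimum and maximum beats entering the BVR statistic
    bvr_min_beats: int = 10
    bvr_max_beats: int = 15
    #: BVR denominator: "differences" (N-1 terms) or "beats" (N)
    bvr_denominator: str = "differences"

    # --- fast sodium current ---
    #: baseline window before the test step for peak measurement (ms)
    iv_baseline_ms: float = 10.0
    #: voltage range of the activation fit (mV)
    act_fit_range: tuple = (-80.0, -20.0)
    #: voltage range of the availability fit (mV)
    avail_fit_range: tuple = (-150.0, -50.0)
    #: offset after the current peak at which the inactivation tau fit starts (ms)
    tau_fit_start_offset_ms: float = 0.2
    #: decay end criterion: fraction of the peak at which the tau fit window closes
    tau_fit_end_fraction: float = 0.05
    #: parameter tolerance of the nonlinear fitters
    fit_xtol: float = 1e-10

    # --- late sodium current ---
    #: half-width of the averaging window around the 300/600 ms reads (ms; 0 = point)
    late_window_halfwidth_ms: float = 5.0
    late_t1_ms: float = 300.0
    late_t2_ms: float = 600.0
    late_integral_start_ms: float = 350.0
    late_integral_end_ms: float = 800.0

    # --- respiration ---
    #: apnoea threshold multiple of the running-average expiration time
    apnoea_factor: float = 4.0
    #: running-average rule: "per_minute" or "trailing" 60 s window
    apnoea_mode: str = "per_minute"

    #: seed for stochastic stages
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        for key in ("act_fit_range", "avail_fit_range"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)
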