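#!/usr/bin/env python
"""ECG intervals and rate-corrected QT for both strains.

Generates a synthetic anaesthetised-mouse ECG for each strain at its
group-mean RR/QRS/QT intervals, detects R peaks, extracts per-complex
metrics, averages five consecutive clean complexes, and applies both QT
rate corrections.  The mutant's QTc exceeds the wild type's by ~5-6 ms
under either correction while heart rate barely differs — the signature of
delayed ventricular repolarization rather than rate change.

Writes results/ecg_intervals.csv.
"""

from pathlib import Path

import pandas as pd

from rettephys.ecg_metrics import complex_metrics, detect_r_peaks, summarise_ecg
from rettephys.synthetic_data import EcgShapeParams, gen_ecg

STRAINS = {
    "WT": EcgShapeParams(rr=130.7, qrs=10.8, qt=51.9),
    "Mecp2-null": EcgShapeParams(rr=125.8, qrs=12.2, qt=56.9),
}


def main() -> None:
    rows = []
    for strain, params in STRAINS.items():
        trace, ann = gen_ecg(params, duration_ms=2000.0)
        peaks = detect_r_peaks(trace)
        s = summarise_ecg(complex_metrics(ann, peaks), n_complexes=5)
        rows.append({"strain": strain, "RR_ms": s.rr, "HR_bpm": s.hr,
                     "QRS_ms": s.qrs, "QT_ms": s.qt,
                     "QTc_eq1_ms": s.qtc_eq1, "QTc_eq2_ms": s.qtc_eq2})
    df = pd.DataFrame(rows).round(2)
    out = Path(__file__).resolve().parents[1] / "results" / "ecg_intervals.csv"
    out.parent.mkdir(exist_ok=True)
    df.to_csv(out, index=False)
    print(df.to_string(index=False))
    d1 = df.QTc_eq1_ms.iloc[1] - df.QTc_eq1_ms.iloc[0]
    d2 = df.QTc_eq2_ms.iloc[1] - df.QTc_eq2_ms.iloc[0]
    print(f"\nQTc prolongation in the mutant: {d1:+.1f} ms (sqrt correction), "
          f"{d2:+.1f} ms (linear correction)")


if __name__ == "__main__":
    main()
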