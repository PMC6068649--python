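"""Bundled reference cohort: 11 haemodialysis patients with AVF stenosis grading.

These are the published measurements the method was developed on: per-patient
vessel diameters (normal ``D`` and lesion ``d``, duplex ultrasound), the
reported degree of stenosis, demographics, the dialysis-access hand, and the
per-patient mean rising/falling slopes of the fistula-hand PPG pulse before
and after one dialysis session.  They serve as fixed reference inputs for the
labelling and feature-selection stages and for regression tests; waveform-level
data are produced by :mod:`ppgavf.synthetic` instead.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

# subject_id, D, d, reported DOS (%), age, gender, HD hand
_PATIENTS = [
    ("P01", 1.04, 0.94, 18.31, 81, "M", "left"),
    ("P02", 1.18, 1.09, 14.67, 78, "M", "left"),
    ("P03", 1.36, 1.17, 25.99, 87, "M", "left"),
    ("P04", 0.80, 0.70, 23.30, 86, "M", "left"),
    ("P05", 1.71, 1.45, 28.10, 65, "M", "left"),
    ("P06", 0.73, 0.59, 34.68, 81, "M", "left"),
    ("P07", 1.16, 0.83, 48.80, 54, "M", "left"),
    ("P08", 1.08, 0.81, 44.30, 67, "M", "left"),
    ("P09", 0.78, 0.58, 44.38, 87, "M", "left"),
    ("P10", 0.88, 0.44, 74.72, 75, "F", "left"),
    ("P11", 0.98, 0.23, 94.50, 86, "M", "left"),
]

# Per-patient mean slopes of the fistula-hand pulse (a.u., rescaled), before
# and after the dialysis session.
_RS_BEFORE = [0.0792, 0.0724, 0.0867, 0.0789, 0.0854, 0.1058, 0.0751, 0.1194, 0.1194, 0.1020, 0.0874]
_RS_AFTER = [0.1139, 0.0917, 0.0865, 0.0778, 0.1023, 0.1058, 0.0958, 0.1307, 0.1243, 0.1035, 0.0867]
_FS_BEFORE = [0.1233, 0.0920, 0.0847, 0.1037, 0.1572, 0.0950, 0.0871, 0.0686, 0.0686, 0.0770, 0.1146]
_FS_AFTER = [0.1348, 0.1254, 0.0714, 0.0930, 0.0937, 0.0950, 0.0757, 0.1255, 0.1254, 0.1254, 0.0790]


def reference_patients() -> pd.DataFrame:
    """Patient table: subject_id, D, d, dos_reported, age, gender, hd_hand."""
    return pd.DataFrame(
        _PATIENTS,
        columns=["subject_id", "D", "d", "dos_reported", "age", "gender", "hd_hand"],
    )


def reference_slopes() -> pd.DataFrame:
    """Per-patient mean rising/falling slopes before and after dialysis."""
    return pd.DataFrame(
        {
            "subject_id": [p[0] for p in _PATIENTS],
            "rs_before": _RS_BEFORE,
            "rs_after": _RS_AFTER,
            "fs_before": _FS_BEFORE,
            "fs_after": _FS_AFTER,
        }
    )


def reference_ages() -> np.ndarray:
    """The 11 subject ages in years."""
    return np.array([p[4] for p in _PATIENTS], dtype=float)
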