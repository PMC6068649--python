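"""Degree-of-stenosis (DOS) computation and severity class assignment.

The degree of stenosis of an arteriovenous fistula is graded from two vessel
diameters measured on B-mode ultrasound: the lumen diameter at the stenotic
lesion ``d`` and the adjacent normal vessel diameter ``D``,

    DOS% = (1 - d^2 / D^2) * 100.

Patients are partitioned into three severity classes: mild (DOS <= 30%,
class 1), moderate (30% < DOS <= 50%, class 2, where dialysis efficiency is
affected) and severe (DOS > 50%, class 3, where surgical revision is usually
indicated).  The published class boundaries overlap at 30% and 50%; this
module resolves them as the half-open intervals [0, 30], (30, 50], (50, 100]
so that assignment is deterministic.  No tabulated patient sits exactly on a
boundary, so the resolution does not change any reported label.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Upper DOS bound (inclusive) of classes 1 and 2; class 3 runs to 100.
CLASS_BOUNDS = (30.0, 50.0)


def dos_percent(d: float, D: float) -> float:
    """Degree of stenosis in percent from lesion and normal diameters.

    Any single consistent length unit may be used: only the ratio d/D enters.

    Raises
    ------
    ValueError
        If ``D <= 0`` or ``d`` lies outside ``[0, D]``.
    """
    if D <= 0:
        raise ValueError(f"normal diameter D must be positive, got {D}")
    if not 0 <= d <= D:
        raise ValueError(f"lesion diameter d must satisfy 0 <= d <= D, got d={d}, D={D}")
    return (1.0 - (d * d) / (D * D)) * 100.0


def dos_class(dos: float) -> int:
    """Severity class 1, 2 or 3 for a DOS percentage.

    Boundary convention: DOS = 30 -> class 1; DOS = 50 -> class 2.
    """
    if not 0 <= dos <= 100:
        raise ValueError(f"DOS must lie in [0, 100], got {dos}")
    if dos <= CLASS_BOUNDS[0]:
        return 1
    if dos <= CLASS_BOUNDS[1]:
        return 2
    return 3


def one_hot(class_label: int) -> np.ndarray:
    """Network target vector for a class: 1 -> [1,0,0], 2 -> [0,1,0], 3 -> [0,0,1]."""
    if class_label not in (1, 2, 3):
        raise ValueError(f"class label must be 1, 2 or 3, got {class_label}")
    target = np.zeros(3)
    target[class_label - 1] = 1.0
    return target


@dataclass(frozen=True)
class PatientRecord:
    """One subject's vascular, demographic and labelling data."""

    subject_id: str
    D: float
    d: float
    dos: float
    class_label: int
    hd_hand: str = "left"
    age: float | None = None
    gender: str | None = None
    #: DOS value as reported in the source table, when one was supplied.
    dos_reported: float | None = None
    #: True when the reported DOS does not round to the recomputed one,
    #: indicating the tabulated diameters were themselves rounded.
    dos_mismatch: bool = False

    @property
    def target(self) -> np.ndarray:
        return one_hot(self.class_label)


def label_patients(table: pd.DataFrame) -> list[PatientRecord]:
    """Compute DOS and severity class for a patient table.

    ``table`` needs columns ``subject_id``, ``D`` and ``d``; optional columns
    ``dos_reported``, ``age``, ``gender``, ``hd_hand`` are carried through.
    When a ``dos_reported`` column is present, rows whose recomputed DOS does
    not round (2 d.p.) to the reported value are flagged via
    ``dos_mismatch`` — flagged, not rejected, since such discrepancies arise
    from rounded diameters in the source table.
    """
    records = []
    for _, row in table.iterrows():
        dos = dos_percent(float(row["d"]), float(row["D"]))
        reported = float(row["dos_reported"]) if "dos_reported" in row and pd.notna(row["dos_reported"]) else None
        mismatch = reported is not None and round(dos, 2) != round(reported, 2)
        records.append(
            PatientRecord(
                subject_id=str(row["subject_id"]),
                D=float(row["D"]),
                d=float(row["d"]),
                dos=dos,
                class_label=dos_class(dos),
                hd_hand=str(row.get("hd_hand", "left")),
                age=float(row["age"]) if "age" in row and pd.notna(row["age"]) else None,
                gender=str(row["gender"]) if "gender" in row and pd.notna(row["gender"]) else None,
                dos_reported=reported,
                dos_mismatch=mismatch,
            )
        )
    return records


def patients_frame(records: list[PatientRecord]) -> pd.DataFrame:
    """Tabular view of labelled patients (one row per subject)."""
    return pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in records],
            "D": [r.D for r in records],
            "d": [r.d for r in records],
            "dos": [r.dos for r in records],
            "class": [r.class_label for r in records],
            "hd_hand": [r.hd_hand for r in records],
            "age": [r.age for r in records],
            "gender": [r.gender for r in records],
            "dos_reported": [r.dos_reported for r in records],
            "dos_mismatch": [r.dos_mismatch for r in records],
        }
    )


def class_counts(records: list[PatientRecord]) -> dict[int, int]:
    """Number of subjects per severity class, as ``{1: n1, 2: n2, 3: n3}``."""
    counts = {1: 0, 2: 0, 3: 0}
    for r in records:
        counts[r.class_label] += 1
    return counts
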