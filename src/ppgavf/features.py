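"""Pulse landmark detection and slope feature extraction.

Each PPG beat is described by a valley–peak–valley triplet: the pulse foot
(V_n at time T_n), the systolic peak (V_p at T_pn) and the next foot
(V_{n+1} at T_{n+1}).  From these, two morphology features are computed:

    rising slope   RS = (V_p - V_n) / (T_pn - T_n)        [a.u./s]
    falling slope  FS = |V_{n+1} - V_p| / (T_{n+1} - T_pn)

The signed falling slope of a descending limb is negative; following the
convention used when the features are tabulated and compared, FS is reported
as a magnitude, with the signed value retained alongside.

A fixed number of beats (12 by default) is taken per recording, slope values
can be min–max rescaled to [0, 1], and each feature/phase is summarised by
its sample mean and variance (n−1 denominator), which are the classifier
inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .recording import PpgRecording

#: Default minimum peak separation (s): one beat at 150 bpm.
DEFAULT_MIN_DISTANCE = 0.4
DEFAULT_BEATS = 12


class Landmark(NamedTuple):
    kind: str  # "valley" | "peak"
    index: int  # sample index
    time: float  # seconds
    value: float  # a.u.


@dataclass(frozen=True)
class BeatFeature:
    """Landmarks and slopes of one pulse."""

    t_n: float
    t_pn: float
    t_n1: float
    v_n: float
    v_p: float
    v_n1: float

    def __post_init__(self) -> None:
        if not self.t_n < self.t_pn < self.t_n1:
            raise ValueError(
                f"landmark times must be ordered T_n < T_pn < T_n+1, got "
                f"{self.t_n}, {self.t_pn}, {self.t_n1}"
            )
        if not (self.v_p > self.v_n and self.v_p > self.v_n1):
            raise ValueError("peak value must lie strictly above both adjacent valleys")

    @property
    def rs(self) -> float:
        return rising_slope(self.v_p, self.v_n, self.t_pn, self.t_n)

    @property
    def fs(self) -> float:
        return falling_slope(self.v_n1, self.v_p, self.t_n1, self.t_pn)

    @property
    def fs_signed(self) -> float:
        return falling_slope(self.v_n1, self.v_p, self.t_n1, self.t_pn, signed=True)


@dataclass(frozen=True)
class RescaleParams:
    """Min/max of the value collection a min–max rescale maps to [0, 1]."""

    min: float
    max: float

    def __post_init__(self) -> None:
        if not self.max > self.min:
            raise ValueError(f"degenerate range: max ({self.max}) must exceed min ({self.min})")


@dataclass(frozen=True)
class FeatureSummary:
    """Sample mean and variance of one feature in one phase."""

    mean: float
    variance: float
    n: int
    phase: str
    feature_name: str

    @property
    def sd(self) -> float:
        return float(np.sqrt(self.variance))


def rising_slope(v_p: float, v_n: float, t_pn: float, t_n: float) -> float:
    """(V_p - V_n) / (T_pn - T_n); requires T_pn > T_n."""
    if t_pn <= t_n:
        raise ValueError(f"peak time T_pn ({t_pn}) must exceed foot time T_n ({t_n})")
    return (v_p - v_n) / (t_pn - t_n)


def falling_slope(v_n1: float, v_p: float, t_n1: float, t_pn: float, signed: bool = False) -> float:
    """Slope from peak to next foot; reported as a magnitude unless ``signed``."""
    if t_n1 <= t_pn:
        raise ValueError(f"next foot time T_n+1 ({t_n1}) must exceed peak time T_pn ({t_pn})")
    slope = (v_n1 - v_p) / (t_n1 - t_pn)
    return slope if signed else abs(slope)


def detect_peaks_valleys(
    recording: PpgRecording,
    min_distance: float = DEFAULT_MIN_DISTANCE,
    min_prominence: float | None = None,
) -> list[Landmark]:
    """Locate alternating pulse feet and systolic peaks.

    Peaks come from local-maximum detection with a minimum separation of
    ``min_distance`` seconds and a minimum prominence (default: 10% of the
    signal's inter-quartile range).  Each foot is then the minimum between
    consecutive accepted peaks; the leading foot is the minimum before the
    first peak and the trailing foot the minimum after the last.  The result
    strictly alternates valley, peak, valley, ... and every peak lies
    strictly above its flanking valleys.  An empty list (no peaks) is a
    valid outcome, not an error.
    """
    x = recording.samples
    if min_prominence is None:
        q75, q25 = np.percentile(x, [75, 25])
        min_prominence = 0.1 * (q75 - q25)
    distance = max(1, int(round(min_distance * recording.rate)))
    peaks, _ = find_peaks(x, distance=distance, prominence=min_prominence or None)
    peaks = list(peaks)

    t = recording.times
    while peaks:
        # foot = minimum before/between/after the accepted peaks
        boundaries = [0, *peaks, x.size - 1]
        valleys = [
            left + int(np.argmin(x[left : right + 1]))
            for left, right in zip(boundaries[:-1], boundaries[1:])
        ]
        # drop peaks not strictly above both flanking feet (flat stretches),
        # then recompute the feet from the surviving peaks
        bad = [
            i
            for i, p in enumerate(peaks)
            if not (valleys[i] < p < valleys[i + 1] and x[p] > x[valleys[i]] and x[p] > x[valleys[i + 1]])
        ]
        if not bad:
            break
        for i in reversed(bad):
            del peaks[i]
    if not peaks:
        return []

    landmarks: list[Landmark] = []
    for i, p in enumerate(peaks):
        landmarks.append(Landmark("valley", valleys[i], t[valleys[i]], x[valleys[i]]))
        landmarks.append(Landmark("peak", p, t[p], x[p]))
    last = valleys[len(peaks)]
    landmarks.append(Landmark("valley", last, t[last], x[last]))
    return landmarks


def select_beats(landmarks: Sequence[Landmark], k: int = DEFAULT_BEATS) -> list[BeatFeature]:
    """First ``k`` complete valley–peak–valley beats, in temporal order.

    Consecutive beats share a foot: landmark 2i is the foot of beat i and
    landmark 2i+2 both ends beat i and starts beat i+1.
    """
    beats: list[BeatFeature] = []
    for i in range(0, len(landmarks) - 2, 2):
        v0, p, v1 = landmarks[i], landmarks[i + 1], landmarks[i + 2]
        if (v0.kind, p.kind, v1.kind) != ("valley", "peak", "valley"):
            raise ValueError("landmark sequence does not alternate valley/peak/valley")
        beats.append(
            BeatFeature(t_n=v0.time, t_pn=p.time, t_n1=v1.time, v_n=v0.value, v_p=p.value, v_n1=v1.value)
        )
    if len(beats) < k:
        raise ValueError(f"only {len(beats)} complete beats available, need {k}")
    return beats[:k]


def rescale(values: Sequence[float], params: RescaleParams | None = None) -> np.ndarray:
    """Min–max rescale to [0, 1]: x -> (x - min) / (max - min).

    ``params`` defaults to the min/max of ``values`` itself; a degenerate
    (max == min) range is rejected.
    """
    values = np.asarray(values, dtype=float)
    if params is None:
        params = RescaleParams(min=float(values.min()), max=float(values.max()))
    return (values - params.min) / (params.max - params.min)


def summarize(values: Sequence[float], phase: str, feature_name: str) -> FeatureSummary:
    """Sample mean and variance (n-1 denominator) of a feature's values."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError(f"variance needs at least 2 values, got {values.size}")
    return FeatureSummary(
        mean=float(values.mean()),
        variance=float(values.var(ddof=1)),
        n=int(values.size),
        phase=phase,
        feature_name=feature_name,
    )


def beat_features(
    recording: PpgRecording,
    k: int = DEFAULT_BEATS,
    min_distance: float = DEFAULT_MIN_DISTANCE,
    min_prominence: float | None = None,
) -> list[BeatFeature]:
    """Detect landmarks and return the first ``k`` beats of a recording."""
    landmarks = detect_peaks_valleys(recording, min_distance, min_prominence)
    return select_beats(landmarks, k=k)


def beat_table(recording: PpgRecording, beats: Sequence[BeatFeature]) -> pd.DataFrame:
    """Per-beat feature table in the package's CSV dialect."""
    return pd.DataFrame(
        {
            "subject_id": recording.subject_id,
            "channel": recording.channel,
            "phase": recording.phase,
            "beat_index": np.arange(len(beats)),
            "t_n": [b.t_n for b in beats],
            "t_pn": [b.t_pn for b in beats],
            "t_n1": [b.t_n1 for b in beats],
            "v_n": [b.v_n for b in beats],
            "v_p": [b.v_p for b in beats],
            "v_n1": [b.v_n1 for b in beats],
            "rs": [b.rs for b in beats],
            "fs": [b.fs for b in beats],
        }
    )
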