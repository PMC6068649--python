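"""Synthetic dual-PPG generator with known ground truth.

Clinical PPG recordings cannot be redistributed, so every downstream stage is
exercised on simulated pulse trains whose beat landmarks and slopes are known
in closed form.  A beat is a piecewise half-cosine: the upstroke rises from
the pulse foot (amplitude 0) to the systolic peak over ``rise_time`` seconds
and the downstroke decays back to 0 over the rest of the period, with a
shape exponent warping the decay.  Landmarks are therefore exact: feet at
multiples of the period with value 0, peak at ``rise_time`` after the foot
with value ``amplitude``, giving

    RS_true = amplitude / rise_time
    FS_true = amplitude / (period - rise_time)

independent of the interpolating shape.  Ground truth is always computed
from the noiseless template — added noise, offset and drift never alter it.

Cohort simulation mirrors the clinical study design: three stenosis-severity
classes with 5/4/2 subjects whose degree of stenosis (DOS) is drawn inside
class-specific ranges matching the observed cohort; the rising slope of the
fistula-hand pulse increases with DOS, and a dialysis session increases it
further in proportion to DOS (the control hand shows no such structure).
No published quantitative DOS-to-pulse-shape model exists, so this mapping
is a configurable stand-in chosen to reproduce the cohort-level class
structure, not a calibrated haemodynamic simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .labels import PatientRecord, dos_class
from .recording import PpgRecording, write_recording

__all__ = [
    "BeatTemplate",
    "NoiseSpec",
    "CohortSpec",
    "Cohort",
    "generate_recording",
    "generate_cohort",
    "sample_cohort_slopes",
]


@dataclass(frozen=True)
class BeatTemplate:
    """Shape parameters of one stereotyped pulse."""

    period: float = 0.8  # s, ~75 bpm
    rise_time: float = 0.15  # s, foot-to-peak
    amplitude: float = 1.0  # a.u.
    fall_shape: float = 1.0  # decay warp exponent; 1 = plain half-cosine

    def __post_init__(self) -> None:
        if not 0 < self.rise_time < self.period:
            raise ValueError(
                f"rise_time must satisfy 0 < rise_time < period, got "
                f"rise_time={self.rise_time}, period={self.period}"
            )
        if self.amplitude <= 0:
            raise ValueError(f"amplitude must be positive, got {self.amplitude}")
        if self.fall_shape <= 0:
            raise ValueError(f"fall_shape must be positive, got {self.fall_shape}")

    @property
    def rs_true(self) -> float:
        """Landmark rising slope (a.u./s) of the noiseless beat."""
        return self.amplitude / self.rise_time

    @property
    def fs_true(self) -> float:
        """Landmark falling-slope magnitude (a.u./s) of the noiseless beat."""
        return self.amplitude / (self.period - self.rise_time)


@dataclass(frozen=True)
class NoiseSpec:
    """Additive disturbances: baseline drift, DC offset and sensor noise."""

    drift_amplitude: float = 0.0  # a.u.
    drift_period: float = 10.0  # s
    offset: float = 0.0  # a.u.
    noise_sd: float = 0.0  # a.u.
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.drift_period <= 0:
            raise ValueError(f"drift_period must be positive, got {self.drift_period}")


def _beat_values(template: BeatTemplate, t_in_beat: np.ndarray) -> np.ndarray:
    """Noiseless beat waveform at times within one period."""
    a, rt, per, q = template.amplitude, template.rise_time, template.period, template.fall_shape
    y = np.empty_like(t_in_beat)
    rising = t_in_beat < rt
    y[rising] = 0.5 * a * (1.0 - np.cos(np.pi * t_in_beat[rising] / rt))
    s = (t_in_beat[~rising] - rt) / (per - rt)
    y[~rising] = 0.5 * a * (1.0 + np.cos(np.pi * np.clip(s, 0.0, 1.0) ** q))
    return y


def generate_recording(
    template: BeatTemplate,
    n_beats: int,
    rate: float = 1000.0,
    noise: NoiseSpec | None = None,
    *,
    rise_jitter: float = 0.0,
    amplitude_jitter: float = 0.0,
    channel: str = "left",
    phase: str = "before_HD",
    subject_id: str = "S00",
    rng: np.random.Generator | None = None,
) -> tuple[PpgRecording, pd.DataFrame]:
    """Render a pulse train and its exact beat-level ground truth.

    ``rise_jitter`` and ``amplitude_jitter`` add per-beat fractional
    (Gaussian) variation to the template's rise time and amplitude, giving
    realistic beat-to-beat slope variance while keeping the per-beat truth
    exact.  Returns the recording and a ground-truth table with one row per
    complete beat (columns ``beat_index, t_n, t_pn, t_n1, v_n, v_p, v_n1,
    rs_true, fs_true``).
    """
    if n_beats < 1:
        raise ValueError(f"n_beats must be >= 1, got {n_beats}")
    if rate <= 0:
        raise ValueError(f"rate must be positive, got {rate}")
    if noise is None:
        noise = NoiseSpec()
    if rng is None:
        rng = np.random.default_rng(noise.seed)

    per = template.period
    n_samples = int(round(n_beats * per * rate)) + 1
    t = np.arange(n_samples) / rate
    clean = np.zeros(n_samples)
    truth_rows = []
    for b in range(n_beats):
        rt = template.rise_time
        amp = template.amplitude
        if rise_jitter > 0:
            rt = float(np.clip(rt * (1.0 + rise_jitter * rng.standard_normal()), 0.05 * per, 0.9 * per))
        if amplitude_jitter > 0:
            amp = float(amp * max(1.0 + amplitude_jitter * rng.standard_normal(), 0.1))
        beat = replace(template, rise_time=rt, amplitude=amp)
        t0 = b * per
        sel = (t >= t0) & (t <= t0 + per) if b == n_beats - 1 else (t >= t0) & (t < t0 + per)
        clean[sel] = _beat_values(beat, t[sel] - t0)
        truth_rows.append(
            {
                "beat_index": b,
                "t_n": t0,
                "t_pn": t0 + rt,
                "t_n1": t0 + per,
                "v_n": 0.0,
                "v_p": amp,
                "v_n1": 0.0,
                "rs_true": beat.rs_true,
                "fs_true": beat.fs_true,
            }
        )

    samples = clean + noise.offset
    if noise.drift_amplitude != 0:
        samples = samples + noise.drift_amplitude * np.sin(2.0 * np.pi * t / noise.drift_period)
    if noise.noise_sd > 0:
        samples = samples + noise.noise_sd * rng.standard_normal(n_samples)

    recording = PpgRecording(
        samples=samples, rate=rate, channel=channel, phase=phase, subject_id=subject_id
    )
    return recording, pd.DataFrame(truth_rows)


@dataclass(frozen=True)
class CohortSpec:
    """Study-design parameters of a simulated cohort.

    The defaults are the conditions the method was developed under: 5/4/2
    subjects in the mild/moderate/severe classes, DOS drawn uniformly within
    ranges spanning the observed per-class values, 12+ beats per recording at
    1 kHz, and a dialysis-induced rising-slope increase that grows with DOS
    (zero on the control hand).
    """

    n_per_class: tuple[int, int, int] = (5, 4, 2)
    dos_ranges: tuple[tuple[float, float], ...] = ((14.0, 29.0), (34.0, 49.0), (74.0, 95.0))
    base_rs: float = 6.0  # a.u./s at DOS = 0, before dialysis
    dos_gain: float = 0.8  # fractional RS increase per 100% DOS
    after_effect: float = 0.5  # fractional RS increase after HD per 100% DOS
    subject_sd: float = 0.03  # between-subject fractional RS spread
    rise_jitter: float = 0.03  # per-beat fractional rise-time jitter
    amplitude_jitter: float = 0.02  # per-beat fractional amplitude jitter
    n_beats: int = 15
    rate: float = 1000.0
    period: float = 0.8  # s
    amplitude: float = 1.0  # a.u.
    noise: NoiseSpec = field(
        default_factory=lambda: NoiseSpec(drift_amplitude=0.1, drift_period=8.0, offset=0.5, noise_sd=0.02)
    )
    hd_hand: str = "left"

    def __post_init__(self) -> None:
        if len(self.n_per_class) != 3 or any(n < 0 for n in self.n_per_class):
            raise ValueError("n_per_class must give a non-negative count for each of 3 classes")
        if sum(self.n_per_class) < 1:
            raise ValueError("cohort must contain at least one subject")
        for cls, (lo, hi) in enumerate(self.dos_ranges, start=1):
            if not 0 <= lo < hi <= 100:
                raise ValueError(f"DOS range for class {cls} must satisfy 0 <= lo < hi <= 100")
            if dos_class(lo) != cls or dos_class(hi) != cls:
                raise ValueError(
                    f"DOS range ({lo}, {hi}) is not contained in class {cls}'s partition interval"
                )


@dataclass
class Cohort:
    """A simulated cohort: labelled patients plus per-hand/phase recordings."""

    patients: list[PatientRecord]
    #: (subject_id, channel, phase) -> (recording, ground-truth beat table)
    recordings: dict[tuple[str, str, str], tuple[PpgRecording, pd.DataFrame]]
    spec: CohortSpec
    seed: int

    def recording(self, subject_id: str, channel: str, phase: str) -> PpgRecording:
        return self.recordings[(subject_id, channel, phase)][0]

    def truth(self, subject_id: str, channel: str, phase: str) -> pd.DataFrame:
        return self.recordings[(subject_id, channel, phase)][1]


def _subject_params(spec: CohortSpec, rng: np.random.Generator) -> list[dict]:
    """Draw per-subject DOS, diameters and phase-specific mean rising slopes."""
    subjects = []
    idx = 0
    for cls, (count, (lo, hi)) in enumerate(zip(spec.n_per_class, spec.dos_ranges), start=1):
        for _ in range(count):
            idx += 1
            dos = float(rng.uniform(lo, hi))
            D = float(rng.uniform(0.7, 1.7))
            d = D * np.sqrt(1.0 - dos / 100.0)
            subj_scale = 1.0 + spec.subject_sd * float(rng.standard_normal())
            rs_before = spec.base_rs * (1.0 + spec.dos_gain * dos / 100.0) * subj_scale
            rs_after = rs_before * (1.0 + spec.after_effect * dos / 100.0)
            rs_control = spec.base_rs * (1.0 + spec.subject_sd * float(rng.standard_normal()))
            subjects.append(
                {
                    "subject_id": f"SYN{idx:02d}",
                    "dos": dos,
                    "D": D,
                    "d": float(d),
                    "class": cls,
                    "rs": {
                        (spec.hd_hand, "before_HD"): rs_before,
                        (spec.hd_hand, "after_HD"): rs_after,
                        (_other_hand(spec.hd_hand), "before_HD"): rs_control,
                        (_other_hand(spec.hd_hand), "after_HD"): rs_control,
                    },
                }
            )
    return subjects


def _other_hand(hand: str) -> str:
    return "right" if hand == "left" else "left"


def generate_cohort(spec: CohortSpec, seed: int) -> Cohort:
    """Simulate a full cohort: recordings for both hands, both phases.

    Deterministic for a fixed seed; each subject consumes an independent
    random substream so cohorts are reproducible subject-by-subject.
    """
    root = np.random.SeedSequence(seed)
    param_rng = np.random.default_rng(root.spawn(1)[0])
    subjects = _subject_params(spec, param_rng)
    streams = root.spawn(len(subjects) + 1)[1:]

    patients: list[PatientRecord] = []
    recordings: dict[tuple[str, str, str], tuple[PpgRecording, pd.DataFrame]] = {}
    for subj, stream in zip(subjects, streams):
        patients.append(
            PatientRecord(
                subject_id=subj["subject_id"],
                D=subj["D"],
                d=subj["d"],
                dos=subj["dos"],
                class_label=subj["class"],
                hd_hand=spec.hd_hand,
            )
        )
        rng = np.random.default_rng(stream)
        for (channel, phase), rs_mean in subj["rs"].items():
            rise = spec.amplitude / rs_mean
            if not 0 < rise < spec.period:
                raise ValueError(
                    f"slope {rs_mean:.3g} a.u./s implies rise time {rise:.3g} s outside the "
                    f"{spec.period} s beat period; adjust base_rs/amplitude"
                )
            template = BeatTemplate(
                period=spec.period, rise_time=rise, amplitude=spec.amplitude
            )
            rec, truth = generate_recording(
                template,
                spec.n_beats,
                spec.rate,
                spec.noise,
                rise_jitter=spec.rise_jitter,
                amplitude_jitter=spec.amplitude_jitter,
                channel=channel,
                phase=phase,
                subject_id=subj["subject_id"],
                rng=rng,
            )
            recordings[(subj["subject_id"], channel, phase)] = (rec, truth)
    return Cohort(patients=patients, recordings=recordings, spec=spec, seed=seed)


def sample_cohort_slopes(spec: CohortSpec, seed: int, n_beats: int | None = None) -> pd.DataFrame:
    """Beat-level rising-slope samples for the fistula hand, without rendering.

    Draws exactly the per-beat slope values the waveform renderer would
    encode (rise-time and amplitude jitter applied to the subject's template)
    and returns them directly — one row per subject with arrays of RS values
    before and after dialysis.  Used for statistical calibration studies
    where rendering and re-detecting thousands of waveforms adds nothing.
    """
    if n_beats is None:
        n_beats = spec.n_beats
    root = np.random.SeedSequence(seed)
    param_rng = np.random.default_rng(root.spawn(1)[0])
    subjects = _subject_params(spec, param_rng)
    streams = root.spawn(len(subjects) + 1)[1:]

    rows = []
    for subj, stream in zip(subjects, streams):
        rng = np.random.default_rng(stream)
        per_phase = {}
        for phase in ("before_HD", "after_HD"):
            rs_mean = subj["rs"][(spec.hd_hand, phase)]
            rise = spec.amplitude / rs_mean
            rts = np.clip(
                rise * (1.0 + spec.rise_jitter * rng.standard_normal(n_beats)),
                0.05 * spec.period,
                0.9 * spec.period,
            )
            amps = spec.amplitude * np.maximum(
                1.0 + spec.amplitude_jitter * rng.standard_normal(n_beats), 0.1
            )
            per_phase[phase] = amps / rts
        rows.append(
            {
                "subject_id": subj["subject_id"],
                "class": subj["class"],
                "dos": subj["dos"],
                "rs_before": per_phase["before_HD"],
                "rs_after": per_phase["after_HD"],
            }
        )
    return pd.DataFrame(rows)


def write_cohort(cohort: Cohort, directory: str | Path) -> None:
    """Write a cohort's recordings and ground truth as plain CSV files."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    from .labels import patients_frame

    patients_frame(cohort.patients).to_csv(directory / "patients.csv", index=False)
    for (sid, channel, phase), (rec, truth) in cohort.recordings.items():
        stem = f"{sid}_{channel}_{phase}"
        write_recording(rec, directory / f"{stem}.csv")
        truth.to_csv(directory / f"{stem}_truth.csv", index=False)
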