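"""Pulse landmark detection, slope features, rescaling and summaries."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ppgavf.clinical import reference_ages
from ppgavf.features import (
    BeatFeature,
    RescaleParams,
    beat_features,
    detect_peaks_valleys,
    falling_slope,
    rescale,
    rising_slope,
    select_beats,
    summarize,
)
from ppgavf.recording import PpgRecording
from ppgavf.synthetic import BeatTemplate, generate_recording


class TestDetection:
    def test_noiseless_train_peaks_within_two_samples_of_truth(self, clean_recording):
        rec, truth = clean_recording
        peaks = [l for l in detect_peaks_valleys(rec) if l.kind == "peak"]
        assert len(peaks) == len(truth)
        for lm, t_pn in zip(peaks, truth.t_pn):
            assert abs(lm.index - round(t_pn * rec.rate)) <= 2

    def test_alternation_and_peak_dominance(self, clean_recording):
        rec, _ = clean_recording
        lms = detect_peaks_valleys(rec)
        kinds = [l.kind for l in lms]
        assert kinds[::2] == ["valley"] * len(kinds[::2])
        assert kinds[1::2] == ["peak"] * len(kinds[1::2])
        for i in range(1, len(lms), 2):
            assert lms[i].value > lms[i - 1].value
            assert lms[i].value > lms[i + 1].value

    def test_monotone_ramp_has_no_peaks(self):
        rec = PpgRecording(np.linspace(0, 1, 500), rate=100.0)
        assert detect_peaks_valleys(rec) == []

    def test_single_triangle_pulse(self):
        y = np.concatenate([np.linspace(0, 1, 50), np.linspace(1, 0, 50)[1:]])
        rec = PpgRecording(y, rate=100.0)
        lms = detect_peaks_valleys(rec, min_distance=0.1)
        assert [l.kind for l in lms] == ["valley", "peak", "valley"]
        assert lms[1].index == 49
        assert lms[0].index == 0 and lms[2].index == y.size - 1


class TestSelectBeats:
    def test_prefix_rule(self, clean_recording):
        rec, _ = clean_recording
        lms = detect_peaks_valleys(rec)
        beats = select_beats(lms, k=12)
        assert len(beats) == 12
        assert beats[0].t_pn < beats[1].t_pn  # temporal order
        # first 12 of the 15 available beats
        all_beats = select_beats(lms, k=15)
        assert [b.t_pn for b in beats] == [b.t_pn for b in all_beats[:12]]

    def test_exactly_k_beats_accepted(self, clean_recording):
        rec, _ = clean_recording
        lms = detect_peaks_valleys(rec)[: 2 * 12 + 1]  # exactly 12 triplets
        assert len(select_beats(lms, k=12)) == 12

    def test_too_few_beats_errors_with_count(self, clean_recording):
        rec, _ = clean_recording
        lms = detect_peaks_valleys(rec)[: 2 * 11 + 1]
        with pytest.raises(ValueError, match="11"):
            select_beats(lms, k=12)


class TestSlopes:
    def test_rising_slope_unit_ramp(self):
        assert rising_slope(1.0, 0.0, 0.1, 0.0) == pytest.approx(10.0)

    def test_rising_slope_offset_invariant(self):
        assert rising_slope(2.5 + 1.0, 2.5, 0.3, 0.1) == pytest.approx(
            rising_slope(1.0, 0.0, 0.3, 0.1)
        )

    def test_falling_slope_magnitude_convention(self):
        # algebraically negative descending limb is reported as a magnitude
        assert falling_slope(0.0, 1.0, 0.2, 0.0) == pytest.approx(5.0)
        assert falling_slope(0.0, 1.0, 0.2, 0.0, signed=True) == pytest.approx(-5.0)

    def test_symmetric_triangle_has_equal_slopes(self):
        beat = BeatFeature(t_n=0.0, t_pn=0.1, t_n1=0.2, v_n=0.0, v_p=1.0, v_n1=0.0)
        assert beat.rs == pytest.approx(beat.fs)

    def test_degenerate_times_rejected(self):
        with pytest.raises(ValueError):
            rising_slope(1.0, 0.0, 0.1, 0.1)
        with pytest.raises(ValueError):
            falling_slope(0.0, 1.0, 0.1, 0.1)

    def test_misordered_landmarks_raise(self):
        with pytest.raises(ValueError):
            BeatFeature(t_n=0.2, t_pn=0.1, t_n1=0.3, v_n=0.0, v_p=1.0, v_n1=0.0)
        with pytest.raises(ValueError):
            BeatFeature(t_n=0.0, t_pn=0.1, t_n1=0.2, v_n=0.0, v_p=-0.5, v_n1=-0.2)


class TestRescale:
    def test_three_point_example(self):
        assert np.allclose(rescale([2.0, 4.0, 6.0]), [0.0, 0.5, 1.0])

    def test_idempotent_with_recomputed_params(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=40)
        once = rescale(v)
        twice = rescale(once)
        assert np.allclose(once, twice, atol=1e-12)

    @given(st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=50).filter(lambda v: max(v) > min(v)))
    def test_matches_elementwise_oracle(self, values):
        v = np.array(values)
        out = rescale(v)
        expected = (v - v.min()) / (v.max() - v.min())
        assert np.allclose(out, expected, atol=1e-12)
        assert out.min() == pytest.approx(0.0) and out.max() == pytest.approx(1.0)

    def test_degenerate_range_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            rescale([3.0, 3.0, 3.0])
        with pytest.raises(ValueError):
            RescaleParams(min=1.0, max=1.0)


class TestSummarize:
    def test_reference_cohort_age_statistics(self):
        s = summarize(reference_ages(), phase="before_HD", feature_name="age")
        assert s.mean == pytest.approx(77.0)
        assert round(s.sd, 1) == 10.8

    def test_constant_vector_zero_variance(self):
        s = summarize([4.0, 4.0, 4.0], "before_HD", "rs")
        assert s.variance == 0.0

    def test_two_value_closed_form(self):
        a, b = 1.3, 4.1
        s = summarize([a, b], "before_HD", "rs")
        assert s.variance == pytest.approx((a - b) ** 2 / 2.0)

    def test_single_value_rejected(self):
        with pytest.raises(ValueError):
            summarize([1.0], "before_HD", "rs")


class TestEndToEnd:
    def test_time_shift_leaves_slopes_unchanged(self, clean_recording):
        rec, _ = clean_recording
        shift = 800  # one full beat period: identical train, new time origin
        shifted = PpgRecording(rec.samples[shift:], rate=rec.rate)
        rs0 = np.array([b.rs for b in beat_features(rec, 12)])
        rs1 = np.array([b.rs for b in beat_features(shifted, 12)])
        assert np.allclose(rs0, rs1, atol=1e-9)
        t0 = np.array([b.t_pn for b in beat_features(rec, 12)])
        t1 = np.array([b.t_pn for b in beat_features(shifted, 12)])
        assert np.allclose(t0[1:] - shift / rec.rate, t1[:-1], atol=1e-9)

    def test_noiseless_extraction_matches_truth_within_two_percent(self):
        rng = np.random.default_rng(9)
        tpl = BeatTemplate()
        rec, truth = generate_recording(
            tpl, 15, 1000.0, rise_jitter=0.04, amplitude_jitter=0.03, rng=rng
        )
        beats = beat_features(rec, 12)
        rs = np.array([b.rs for b in beats])
        fs = np.array([b.fs for b in beats])
        assert np.allclose(rs, truth.rs_true[:12], rtol=0.02)
        assert np.allclose(fs, truth.fs_true[:12], rtol=0.02)

    def test_extracted_slopes_always_positive(self, cohort_features):
        beat_table, _ = cohort_features
        assert (beat_table.rs > 0).all()
        assert (beat_table.fs > 0).all()
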