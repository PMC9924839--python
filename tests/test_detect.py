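import numpy as np
import pytest
from hypothesis import given, strategies as st
from hypothesis.extra import numpy as hnp

import ecglvh as e
from ecglvh.detect import DetectorParams, seconds_to_samples
from ecglvh.synthetic import default_templates


def oracle_preliminary_r(x, params):
    """Independent oracle: enumerate all strict local maxima above mpa,
    then greedily enforce the refractory interval left to right."""
    x = np.asarray(x, float)
    maxima = np.flatnonzero(
        (x[1:-1] > params.mpa) & (x[:-2] < x[1:-1]) & (x[2:] < x[1:-1])
    ) + 1
    picked, last = [], -np.inf
    for j in maxima:
        if j >= last + params.miR:
            picked.append(int(j))
            last = j
    return picked


def gaussian_train(n_peaks=10, spacing=400, amp=1.0, width=6.0, n=None):
    centers = 200 + spacing * np.arange(n_peaks)
    n = n or centers[-1] + 200
    t = np.arange(n)
    x = np.zeros(n)
    for c in centers:
        x += amp * np.exp(-0.5 * ((t - c) / width) ** 2)
    return x, list(centers)


class TestSecondsToSamples:
    @pytest.mark.parametrize(
        "dur,fs,expected", [(0.12, 500, 60), (0.25, 500, 125), (0.6, 500, 300)]
    )
    def test_half_up_rounding_at_500hz(self, dur, fs, expected):
        assert seconds_to_samples(dur, fs) == expected


class TestPreliminaryR:
    def test_all_zero_signal_yields_nothing(self):
        assert e.detect_preliminary_r(np.zeros(1000), 500.0) == []

    def test_refractory_suppresses_close_second_spike(self):
        x = np.zeros(1000)
        x[[100, 300]] = 1.0  # 200 samples apart < miR=300
        assert e.detect_preliminary_r(x, 500.0) == [100]

    def test_gaussian_train_matches_oracle_apices(self):
        x, centers = gaussian_train()
        params = DetectorParams()
        found = e.detect_preliminary_r(x, 500.0, params)
        assert found == centers
        assert found == oracle_preliminary_r(x, params)

    @given(
        x=hnp.arrays(
            float,
            st.integers(3, 400),
            elements=st.floats(-1.5, 1.5, allow_nan=False, width=32),
        ),
        mir=st.integers(1, 80),
    )
    def test_oracle_equivalence_on_arbitrary_signals(self, x, mir):
        params = DetectorParams(miR=mir)
        assert e.detect_preliminary_r(x, 500.0, params) == oracle_preliminary_r(x, params)

    @given(
        x=hnp.arrays(
            float,
            st.integers(3, 300),
            elements=st.floats(-1, 1, allow_nan=False, width=32),
        )
    )
    def test_refractory_and_floor_invariants(self, x):
        params = DetectorParams(miR=25)
        found = e.detect_preliminary_r(x, 500.0, params)
        assert all(b - a >= params.miR for a, b in zip(found, found[1:]))
        assert all(x[j] > params.mpa for j in found)


class TestLocateSValley:
    def test_unique_dip_recovered(self):
        x = np.zeros(500)
        x[100] = 1.0
        x[130] = -0.4
        s, amp = e.locate_s_valley(x, 100, 500.0)
        assert (s, amp) == (130, -0.4)

    def test_monotone_segment_returns_window_end(self):
        x = -np.arange(500.0)
        s, _ = e.locate_s_valley(x, 100, 500.0)
        assert s == 160  # 100 + round(0.12 * 500)

    def test_earliest_index_wins_ties(self):
        x = np.zeros(500)
        x[110] = x[120] = -0.3
        s, _ = e.locate_s_valley(x, 100, 500.0)
        assert s == 110

    def test_r_at_last_sample_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            e.locate_s_valley(np.zeros(100), 99, 500.0)

    def test_window_truncated_at_signal_end(self):
        x = np.zeros(120)
        x[115] = -0.2
        s, _ = e.locate_s_valley(x, 100, 500.0)
        assert s == 115


class TestTCorrection:
    @staticmethod
    def _t_locked_record(t_over_r=1.2, seed=0):
        tpl = default_templates(t_over_r=t_over_r)
        return e.synth_record(
            tpl, start_offset=-0.1, seed=seed, noise_sd=0.0, rr_jitter=0.0
        )

    def test_tall_t_beats_corrected_to_true_r(self):
        seq, truth = self._t_locked_record()
        x = seq.leads["II"]
        prelim = e.detect_preliminary_r(x, 500.0)
        truth_idx = [b.r_index for b in truth["II"].beats]
        # the preliminary scan locked onto T apices, not R peaks
        assert not set(prelim) & set(truth_idx)
        for r in prelim[1:]:  # first beat's R lies before the record
            s, _ = e.locate_s_valley(x, r, 500.0)
            r2, s2 = e.correct_t_misdetection(x, r, s, 500.0)
            assert r2 in truth_idx
            assert r2 < s2 <= r2 + 60

    def test_normal_t_leaves_beat_unchanged(self, clean_record):
        seq, truth = clean_record
        x = seq.leads["II"]
        b = truth["II"].beats[2]
        assert e.correct_t_misdetection(x, b.r_index, b.s_index, 500.0) == (
            b.r_index,
            b.s_index,
        )

    def test_truncated_backward_window_is_not_an_error(self):
        x = np.zeros(500)
        x[40] = 1.0
        x[60] = -0.2
        r2, s2 = e.correct_t_misdetection(x, 40, 60, 500.0)
        assert (r2, s2) == (40, 60)

    def test_idempotent_on_already_corrected_beats(self):
        seq, truth = self._t_locked_record()
        x = seq.leads["V5"]
        for r in e.detect_preliminary_r(x, 500.0)[1:]:
            s, _ = e.locate_s_valley(x, r, 500.0)
            once = e.correct_t_misdetection(x, r, s, 500.0)
            twice = e.correct_t_misdetection(x, *once, 500.0)
            assert twice == once


class TestDetectLead:
    def test_clean_record_recovers_truth_exactly(self, clean_record, clean_annotations):
        _, truth = clean_record
        for lead, ann in clean_annotations.items():
            expected = [(b.r_index, b.s_index) for b in truth[lead].beats]
            got = [(b.r_index, b.s_index) for b in ann.beats]
            assert got == expected

    def test_white_noise_shifts_r_by_at_most_two_samples(self):
        # P suppressed: with deflections only from QRS-T, 5 uV RMS noise
        # leaves every R within +/-2 samples of truth
        tpl = default_templates(p_amp=0.0)
        seq, truth = e.synth_record(tpl, seed=21, noise_sd=0.005, rr_jitter=0.0)
        for lead in ("I", "II", "V2", "V5"):
            ann = e.detect_lead(seq.leads[lead], seq.fs, lead=lead)
            truth_idx = np.array([b.r_index for b in truth[lead].beats])
            got = np.array([b.r_index for b in ann.beats])
            assert got.size == truth_idx.size
            assert np.max(np.abs(got - truth_idx)) <= 2

    def test_p_wave_above_amplitude_floor_captures_the_scan(self):
        # documented failure mode of the published scan: it accepts the
        # FIRST local maximum above mpa, so a P wave above the floor
        # (as in unfiltered real ECG) is detected instead of R
        tpl = default_templates(p_amp=0.1)
        seq, truth = e.synth_record(tpl, seed=22, noise_sd=0.0, rr_jitter=0.0)
        x = seq.leads["II"]
        prelim = e.detect_preliminary_r(x, seq.fs)
        truth_idx = {b.r_index for b in truth["II"].beats}
        assert prelim[0] not in truth_idx

    def test_degenerate_two_sample_signal(self):
        ann = e.detect_lead(np.zeros(2), 500.0)
        assert len(ann.beats) == 0
        assert "beat" in ann.warning

    def test_few_beats_flagged_in_metadata(self):
        x = np.zeros(1000)
        x[500] = 1.0
        ann = e.detect_lead(x, 500.0)
        assert len(ann.beats) == 1
        assert ann.warning is not None

    def test_annotations_satisfy_ordering_invariants(self, clean_annotations):
        for ann in clean_annotations.values():
            ann.validate()  # raises on violation
            r = ann.r_indices
            assert np.all(np.diff(r) > 0)
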