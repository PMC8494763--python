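"""Run extraction, the measure triplet, and decile profiles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import naive_measures, naive_runs, random_stream
from facegaze import (
    BoundsError,
    DegenerateSegmentError,
    DegenerateStreamError,
    GazeStream,
    compute_measures,
    decile_profile,
    decile_table,
    extract_runs,
)


def make_stream(hits, valid=None, dt=0.04):
    return GazeStream("c1", "p1", np.asarray(hits), valid, dt)


class TestExtractRuns:
    def test_hand_enumeration(self):
        runs = extract_runs(make_stream([0, 1, 1, 0, 1]))
        assert [(r.onset_frame, r.length_frames) for r in runs] == [(1, 2), (4, 1)]
        assert runs[0].duration_s == pytest.approx(0.08)

    def test_all_off_and_all_on(self):
        assert extract_runs(make_stream([0, 0, 0])) == []
        runs = extract_runs(make_stream([1] * 10))
        assert [(r.onset_frame, r.length_frames) for r in runs] == [(0, 10)]

    def test_invalid_frame_breaks_a_run(self):
        valid = np.ones(5, dtype=bool)
        valid[2] = False
        runs = extract_runs(make_stream([1, 1, 1, 1, 1], valid))
        assert [(r.onset_frame, r.length_frames) for r in runs] == [(0, 2), (3, 2)]

    def test_bridging_merges_across_short_invalid_gaps(self):
        hits = np.array([1, 1, 0, 1, 1, 1])
        valid = np.array([1, 1, 0, 1, 1, 1], dtype=bool)
        # gap frame is invalid -> bridged when allowed, split otherwise
        assert len(extract_runs(make_stream(hits, valid))) == 2
        merged = extract_runs(
            make_stream(hits, valid), bridge_invalid_frames=1
        )
        assert [(r.onset_frame, r.length_frames) for r in merged] == [(0, 5)]
        # a valid OFF frame is a real interruption and never bridged
        assert (
            len(extract_runs(make_stream(hits), bridge_invalid_frames=3)) == 2
        )

    def test_min_instance_filter(self):
        s = make_stream([1, 0, 1, 1, 0, 1, 1, 1])
        assert len(extract_runs(s)) == 3
        runs = extract_runs(s, min_instance_frames=2)
        assert [(r.onset_frame, r.length_frames) for r in runs] == [(2, 2), (5, 3)]

    def test_boundary_truncation_at_segment_edge(self):
        # run spanning frames 740-760, boundary at 750
        hits = np.zeros(1500, dtype=int)
        hits[740:760] = 1
        s = make_stream(hits)
        first = extract_runs(s, segment=(0, 750))
        second = extract_runs(s, segment=(750, 1500))
        assert [(r.onset_frame, r.length_frames) for r in first] == [(740, 10)]
        assert second == []  # 10 frames of duration but no instance
        m2 = compute_measures(s, segment=(750, 1500))
        assert m2.n_instances == 0
        assert m2.duration_per_min * m2.minutes == pytest.approx(10 * 0.04)

    def test_empty_segment_rejected(self):
        s = make_stream([1, 0, 1])
        with pytest.raises(BoundsError):
            extract_runs(s, segment=(2, 2))
        with pytest.raises(BoundsError):
            compute_measures(s, segment=(3, 1))


class TestComputeMeasures:
    def test_hand_arithmetic_25_runs(self):
        # 1 min of frames, 750 ON in 25 evenly spaced runs of 30 frames
        hits = np.zeros(1500, dtype=int)
        for k in range(25):
            hits[k * 60 : k * 60 + 30] = 1
        m = compute_measures(make_stream(hits))
        assert m.duration_per_min == pytest.approx(30.0, abs=1e-9)
        assert m.frequency_per_min == pytest.approx(25.0, abs=1e-9)
        assert m.mean_dwell_s == pytest.approx(1.2, abs=1e-9)

    def test_all_on_minute(self):
        m = compute_measures(make_stream(np.ones(1500, dtype=int)))
        assert m.duration_per_min == pytest.approx(60.0)
        assert m.frequency_per_min == pytest.approx(1.0)
        assert m.mean_dwell_s == pytest.approx(60.0)

    def test_zero_instances_gives_nan_dwell(self):
        m = compute_measures(make_stream(np.zeros(100, dtype=int)))
        assert m.n_instances == 0 and math.isnan(m.mean_dwell_s)

    def test_degenerate_segment(self):
        s = make_stream([1, 1, 1], np.zeros(3, dtype=bool))
        with pytest.raises(DegenerateSegmentError):
            compute_measures(s)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_identity_and_conservation_on_random_streams(self, seed):
        rng = np.random.default_rng(seed)
        s = random_stream(rng, max_len=400)
        if not s.valid.any():
            return
        m = compute_measures(s)
        if m.n_instances >= 1:
            assert m.duration_per_min == pytest.approx(
                m.frequency_per_min * m.mean_dwell_s, abs=1e-9
            )
            assert m.mean_dwell_s >= s.frame_interval_s - 1e-12
        # conservation: run durations sum to ON-valid seconds
        runs = extract_runs(s)
        assert sum(r.length_frames for r in runs) == int(
            (s.hits & s.valid).sum()
        )
        # frequency bound: every instance occupies at least one frame
        assert m.frequency_per_min <= 60 / s.frame_interval_s
        if s.valid.all():
            # with a full time base, runs also need separating OFF frames
            assert (
                m.frequency_per_min
                <= 60 / (2 * s.frame_interval_s) + 1 / m.minutes
            )


class TestOracleEquivalence:
    """Vectorised implementation vs naive per-frame scan (moderate scale;
    the full-scale sweep lives in the acceptance suite)."""

    @pytest.mark.parametrize("seed", range(4))
    def test_runs_and_measures_match_naive_scan(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(150):
            s = random_stream(rng, max_len=600)
            n = s.n_frames
            a = int(rng.integers(0, n))
            b = int(rng.integers(a + 1, n + 1))
            expected = naive_runs(s.hits, s.valid, (a, b))
            got = [
                (r.onset_frame, r.length_frames)
                for r in extract_runs(s, segment=(a, b))
            ]
            assert got == expected
            exp_m = naive_measures(s.hits, s.valid, s.frame_interval_s, (a, b))
            if exp_m is None:
                with pytest.raises(DegenerateSegmentError):
                    compute_measures(s, segment=(a, b))
            else:
                m = compute_measures(s, segment=(a, b))
                for key, val in exp_m.items():
                    got_v = getattr(m, key)
                    if isinstance(val, float) and math.isnan(val):
                        assert math.isnan(got_v)
                    else:
                        assert got_v == pytest.approx(val, abs=1e-12)

    def test_min_instance_filter_matches_naive(self, rng):
        for _ in range(100):
            s = random_stream(rng, max_len=300)
            expected = naive_runs(s.hits, s.valid, min_instance_frames=3)
            got = [
                (r.onset_frame, r.length_frames)
                for r in extract_runs(s, min_instance_frames=3)
            ]
            assert got == expected


class TestDecileProfile:
    def test_one_saturated_bin(self):
        hits = np.zeros(100, dtype=int)
        hits[:10] = 1
        prof = decile_profile(make_stream(hits), "duration")
        assert prof.values == pytest.approx([60.0] + [0.0] * 9)
        assert prof.bin_minutes.sum() == pytest.approx(100 * 0.04 / 60, abs=1e-9)

    def test_alternating_stream_flat_profile(self):
        hits = np.tile([1, 0], 500)
        prof = decile_profile(make_stream(hits), "duration")
        assert prof.values == pytest.approx([30.0] * 10, abs=0.7)

    def test_constant_stream_zero_variance(self):
        prof = decile_profile(make_stream(np.ones(200, dtype=int)), "duration")
        assert np.var(prof.values) == 0.0

    def test_partition_reconstructs_totals(self, rng):
        for _ in range(25):
            s = random_stream(rng, max_len=2000)
            if s.n_valid < 10:
                continue
            prof = decile_profile(s, "duration")
            total_on_s = float((s.hits & s.valid).sum()) * s.frame_interval_s
            assert float(prof.values @ prof.bin_minutes) == pytest.approx(
                total_on_s, abs=1e-6
            )
            assert prof.bin_minutes.sum() == pytest.approx(s.minutes, abs=1e-9)
            # instance counts are conserved too (truncate-onset attribution)
            freq_prof = decile_profile(s, "frequency")
            n_inst = float(freq_prof.values @ freq_prof.bin_minutes)
            assert n_inst == pytest.approx(len(extract_runs(s)), abs=1e-6)

    def test_deciles_ignore_masked_gaps(self):
        # identical valid content, with and without an embedded gap
        hits = np.tile([1, 1, 0, 0], 25)
        plain = decile_profile(make_stream(hits), "duration")
        with_gap = np.concatenate([hits[:40], np.ones(30, dtype=int), hits[40:]])
        valid = np.ones(130, dtype=bool)
        valid[40:70] = False
        gapped = decile_profile(make_stream(with_gap, valid), "duration")
        assert gapped.values == pytest.approx(plain.values)

    def test_too_short_stream_rejected(self):
        with pytest.raises(DegenerateStreamError):
            decile_profile(make_stream([1] * 9), "duration")

    def test_decile_table_shape(self, default_cohort):
        _, streams, _ = default_cohort
        df = decile_table(streams[:5])
        assert len(df) == 50
        assert set(df.columns) >= {"consultation_id", "decile", "duration",
                                   "frequency", "dwell", "minutes"}
        assert df.groupby("consultation_id")["decile"].count().eq(10).all()
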