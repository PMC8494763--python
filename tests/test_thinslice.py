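"""Thin-slice splitting and remainder-prediction models."""

import numpy as np
import pandas as pd
import pytest

from facegaze import (
    GazeStream,
    SingularFitError,
    ThinSliceModel,
    fit_slice_model,
    slice_length_sweep,
    split_slice,
)


def make_stream(hits, valid=None, cid="c1", pid="p1"):
    return GazeStream(cid, pid, np.asarray(hits), valid)


class TestSplitSlice:
    def test_all_on_three_minutes(self):
        s = make_stream(np.ones(4500, dtype=int))
        sp = split_slice(s, 60.0)
        assert sp.slice_measures.duration_per_min == pytest.approx(60.0)
        assert sp.remainder_measures.duration_per_min == pytest.approx(60.0)
        assert sp.slice_measures.minutes == pytest.approx(1.0)
        assert sp.remainder_measures.minutes == pytest.approx(2.0)

    def test_short_consultation_excluded(self, caplog):
        s = make_stream(np.ones(2250, dtype=int))  # 90 s
        with caplog.at_level("INFO", logger="facegaze.thinslice"):
            assert split_slice(s, 120.0) is None
        assert any("excluding" in r.message for r in caplog.records)

    def test_alternating_frequency_both_sides(self):
        # 25 ON / 25 OFF alternation = 1 s ON, 1 s OFF; 30 instances/min
        hits = np.tile([1] * 25 + [0] * 25, 90)  # 3 minutes
        sp = split_slice(make_stream(hits), 30.0)
        assert sp.slice_measures.frequency_per_min == pytest.approx(30.0, abs=2.1)
        assert sp.remainder_measures.frequency_per_min == pytest.approx(
            30.0, abs=2.1
        )

    def test_slice_counts_valid_frames_only(self):
        hits = np.ones(4500, dtype=int)
        valid = np.ones(4500, dtype=bool)
        valid[:750] = False  # first 30 s invalid
        sp = split_slice(make_stream(hits, valid), 30.0)
        # slice = first 750 *valid* frames, i.e. frames 750..1500
        assert sp.slice_measures.minutes == pytest.approx(0.5)
        assert sp.total_minutes == pytest.approx(2.5)

    def test_run_crossing_split_truncated_and_attributed_once(self):
        hits = np.zeros(3000, dtype=int)
        hits[740:760] = 1  # crosses the 30-s boundary at frame 750
        sp = split_slice(make_stream(hits), 30.0)
        assert sp.slice_measures.n_instances == 1
        assert sp.remainder_measures.n_instances == 0
        on_s = (
            sp.slice_measures.duration_per_min * sp.slice_measures.minutes
            + sp.remainder_measures.duration_per_min
            * sp.remainder_measures.minutes
        )
        assert on_s == pytest.approx(20 * 0.04, abs=1e-9)


def synthetic_split_frame(rng, n=120, n_phys=8, sigma_b=5.0, sigma_e=2.0,
                          beta_minutes=0.0):
    """Gaussian person-trait splits: slice and remainder share a latent trait."""
    trait = rng.normal(30, sigma_b, n)
    minutes = rng.uniform(5, 40, n)
    return pd.DataFrame(
        {
            "consultation_id": [f"c{i}" for i in range(n)],
            "physician_id": [f"p{i % n_phys}" for i in range(n)],
            "slice_value": trait + rng.normal(0, sigma_e, n),
            "remainder_value": trait
            + beta_minutes * minutes
            + rng.normal(0, sigma_e, n),
            "total_minutes": minutes,
        }
    )


class TestThinSliceModel:
    def test_identical_remainder_gives_unit_slope_and_r2_one(self, rng):
        df = synthetic_split_frame(rng)
        df["remainder_value"] = df["slice_value"]
        res = fit_slice_model(df, "duration", slice_seconds=30)
        assert res.slice_coefficient == pytest.approx(1.0, abs=1e-10)
        assert res.duration_covariate_coefficient == pytest.approx(0.0, abs=1e-10)
        assert res.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_pure_noise_remainder(self, rng):
        df = synthetic_split_frame(rng, n=400)
        df["remainder_value"] = rng.normal(30, 5, 400)
        res = fit_slice_model(df, "duration", slice_seconds=30)
        assert res.r_squared < 0.03
        assert res.p_values["slice"] > 0.01

    def test_ols_matches_normal_equations(self, rng):
        df = synthetic_split_frame(rng, beta_minutes=-0.2)
        res = fit_slice_model(df, "frequency", slice_seconds=60)
        X = np.column_stack(
            [np.ones(len(df)), df["slice_value"], df["total_minutes"]]
        )
        y = df["remainder_value"].to_numpy()
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert res.intercept == pytest.approx(beta[0], abs=1e-8)
        assert res.slice_coefficient == pytest.approx(beta[1], abs=1e-8)
        assert res.duration_covariate_coefficient == pytest.approx(
            beta[2], abs=1e-8
        )
        # R^2 equals 1 - SSE/SST from the residuals directly
        resid = y - X @ beta
        r2 = 1 - (resid @ resid) / ((y - y.mean()) @ (y - y.mean()))
        assert res.r_squared == pytest.approx(r2, abs=1e-10)

    def test_sequential_r2_increment_of_minutes_covariate(self, rng):
        df = synthetic_split_frame(rng, n=300, beta_minutes=-0.3)
        X_full = np.column_stack(
            [np.ones(len(df)), df["slice_value"], df["total_minutes"]]
        )
        y = df["remainder_value"].to_numpy()
        res = fit_slice_model(df, "duration", slice_seconds=30)

        def sse(X):
            b, *_ = np.linalg.lstsq(X, y, rcond=None)
            r = y - X @ b
            return r @ r

        sst = ((y - y.mean()) ** 2).sum()
        r2_full = 1 - sse(X_full) / sst
        r2_reduced = 1 - sse(X_full[:, :2]) / sst
        assert res.r_squared == pytest.approx(r2_full, abs=1e-10)
        assert r2_full - r2_reduced > 0.0  # the covariate's own increment

    def test_zero_variance_predictor_rejected(self, rng):
        df = synthetic_split_frame(rng)
        df["slice_value"] = 30.0
        with pytest.raises(SingularFitError):
            fit_slice_model(df, "duration", slice_seconds=30)

    def test_requires_ten_consultations(self, rng):
        df = synthetic_split_frame(rng, n=9)
        with pytest.raises(ValueError, match="at least 10"):
            ThinSliceModel(df, "duration", slice_seconds=30)

    def test_random_effect_detected_when_present(self):
        rng = np.random.default_rng(3)
        df = synthetic_split_frame(rng, n=240, n_phys=12, sigma_e=2.0)
        phys_eff = dict(
            zip([f"p{j}" for j in range(12)], rng.normal(0, 6.0, 12))
        )
        df["remainder_value"] += df["physician_id"].map(phys_eff)
        res = fit_slice_model(
            df, "duration", slice_seconds=30, with_physician_effect=True
        )
        assert res.fit_improved_by_random_effect
        assert res.random_effect_sd == pytest.approx(6.0, rel=0.5)
        assert res.lrt_p_value < 0.01
        assert 0.0 <= res.r_squared <= 1.0

    def test_marginal_r2_close_to_ols_r2_without_clustering(self, rng):
        df = synthetic_split_frame(rng, n=300)
        fixed = fit_slice_model(df, "duration", slice_seconds=30)
        mixed = fit_slice_model(
            df, "duration", slice_seconds=30, with_physician_effect=True
        )
        assert mixed.r_squared == pytest.approx(fixed.r_squared, abs=0.03)
        assert mixed.aic_mixed is not None and mixed.aic_fixed is not None


class TestSweep:
    def test_table_shape_and_stars(self, default_cohort):
        _, streams, _ = default_cohort
        table = slice_length_sweep(streams[:40], slice_seconds=(30.0, 60.0))
        assert len(table) == 6  # 3 measures x 2 slice lengths
        assert set(table["measure"]) == {"duration", "frequency", "dwell"}
        assert ((table["r_squared"] >= 0) & (table["r_squared"] <= 1)).all()
        assert table["slice_sig"].isin(["***", "**", "*", "(NS)"]).all()
        assert (table["r_squared_pct"] == 100 * table["r_squared"]).all()
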