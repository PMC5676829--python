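"""Statistics layer: formula oracles, algebraic identities, calibration."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from socialgaze.stats import (
    DegenerateInputError,
    InsufficientDataError,
    StatsConfig,
    cooks_distance,
    paired_t,
    partial_corr,
    partial_corr_from_r,
    pearson_corr,
    run_association_analysis,
    shapiro_wilk,
    steiger_z,
)


class TestPearson:
    def test_identity_gives_r_one(self):
        x = np.array([1.0, 2.0, 5.0, 7.0, 11.0])
        res = pearson_corr(x, x)
        assert res.r == 1.0

    def test_five_point_hand_formula(self):
        # brute-force product-moment evaluation, written out independently
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 5.0])
        sx = x - x.mean()
        sy = y - y.mean()
        r_hand = float(np.sum(sx * sy) / np.sqrt(np.sum(sx**2) * np.sum(sy**2)))
        t_hand = r_hand * math.sqrt(3 / (1 - r_hand**2))
        res = pearson_corr(x, y)
        assert res.r == pytest.approx(r_hand, abs=1e-12)
        assert res.t_stat == pytest.approx(t_hand, abs=1e-12)
        assert res.df == 3

    def test_monte_carlo_consistency(self):
        rng = np.random.default_rng(42)
        cov = [[1.0, 0.5], [0.5, 1.0]]
        xy = rng.multivariate_normal([0, 0], cov, size=10_000)
        res = pearson_corr(xy[:, 0], xy[:, 1])
        assert res.r == pytest.approx(0.5, abs=0.03)

    def test_pairwise_deletion_records_n(self):
        x = np.array([1.0, 2.0, np.nan, 4.0, 5.0, 6.0])
        y = np.array([2.0, 1.0, 4.0, np.nan, 5.0, 7.0])
        assert pearson_corr(x, y).n == 4

    def test_constant_input_rejected(self):
        with pytest.raises(DegenerateInputError):
            pearson_corr([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])

    def test_type_one_error_calibrated(self):
        # bivariate-normal null, n = 30, 2000 replicates, alpha = .05
        rng = np.random.default_rng(7)
        data = rng.standard_normal((2000, 30, 2))
        rejections = 0
        for rep in range(2000):
            res = pearson_corr(data[rep, :, 0], data[rep, :, 1])
            rejections += res.p_two_tailed < 0.05
        assert 0.035 <= rejections / 2000 <= 0.065


class TestPartial:
    def test_uncorrelated_control_leaves_r(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(2000)
        y = x + rng.standard_normal(2000)
        z = rng.standard_normal(2000)
        res = partial_corr(x, y, z)
        assert res.r == pytest.approx(pearson_corr(x, y).r, abs=0.05)
        assert res.df == 2000 - 3

    def test_equals_residual_residual_pearson(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            n = int(rng.integers(8, 60))
            x = rng.standard_normal(n)
            z = rng.standard_normal(n)
            y = 0.5 * x + 0.3 * z + rng.standard_normal(n)
            # independent oracle: residualize both on z by least squares
            zc = np.column_stack([np.ones(n), z])
            rx = x - zc @ np.linalg.lstsq(zc, x, rcond=None)[0]
            ry = y - zc @ np.linalg.lstsq(zc, y, rcond=None)[0]
            r_oracle = float(np.corrcoef(rx, ry)[0, 1])
            assert partial_corr(x, y, z).r == pytest.approx(r_oracle, abs=1e-10)

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.standard_normal((40, 3)), columns=list("xyz"))
        expected = pingouin.partial_corr(df, x="x", y="y", covar="z")
        res = partial_corr(df["x"], df["y"], df["z"])
        assert res.r == pytest.approx(float(expected["r"].iloc[0]), abs=1e-9)
        assert res.p_two_tailed == pytest.approx(float(expected["p_val"].iloc[0]), abs=1e-9)

    def test_collinear_control_rejected(self):
        x = np.arange(10.0)
        y = np.array([2.0, 1, 4, 3, 6, 5, 8, 7, 10, 9])
        with pytest.raises(DegenerateInputError):
            partial_corr(x, y, 2 * x + 1)


class TestSteiger:
    from hypothesis import given, settings, strategies as st

    @settings(derandomize=True, max_examples=200)
    @given(
        r12=st.floats(-0.95, 0.95),
        r13=st.floats(-0.95, 0.95),
        r23=st.floats(-0.5, 0.95),
        n=st.integers(10, 500),
    )
    def test_antisymmetry_and_null_identity_property(self, r12, r13, r23, n):
        try:
            a = steiger_z(r12, r13, r23, n)
        except DegenerateInputError:
            return  # s_bar >= 1 configurations are rejected by contract
        b = steiger_z(r13, r12, r23, n)
        assert a.z == -b.z
        if r12 == r13:
            assert a.z == 0.0

    def test_equal_correlations_give_zero(self):
        res = steiger_z(0.4, 0.4, 0.2, 30)
        assert res.z == 0.0
        assert res.p_two_tailed == 1.0

    def test_antisymmetry_exact(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            r12, r13, r23 = rng.uniform(-0.9, 0.9, 3)
            a = steiger_z(r12, r13, r23, 40)
            b = steiger_z(r13, r12, r23, 40)
            assert a.z == -b.z

    def test_intermediate_quantities_exposed(self):
        res = steiger_z(0.57, 0.35, 0.36, 21)
        assert res.rbar == pytest.approx(0.46)
        assert res.s_bar == pytest.approx(res.psi_bar / (1 - res.rbar**2) ** 2)

    def test_degenerate_configuration_rejected(self):
        with pytest.raises(DegenerateInputError, match="degenerate"):
            steiger_z(0.99, 0.99, -0.99, 30)

    def test_out_of_range_input_rejected(self):
        with pytest.raises(DegenerateInputError):
            steiger_z(1.0, 0.3, 0.2, 30)

    def test_type_one_error_calibrated(self):
        # trivariate normal null with rho12 = rho13 = 0.4, rho23 = 0.3
        rng = np.random.default_rng(9)
        cov = np.array([[1.0, 0.4, 0.4], [0.4, 1.0, 0.3], [0.4, 0.3, 1.0]])
        chol = np.linalg.cholesky(cov)
        rejections = 0
        n_reps, n = 2000, 50
        for _ in range(n_reps):
            d = rng.standard_normal((n, 3)) @ chol.T
            c = np.corrcoef(d, rowvar=False)
            res = steiger_z(c[0, 1], c[0, 2], c[1, 2], n)
            rejections += res.p_two_tailed < 0.05
        assert 0.035 <= rejections / n_reps <= 0.065


class TestCooksDistance:
    def test_off_line_point_has_max_distance(self):
        x = np.arange(10.0)
        y = 2 * x + 1
        y[6] += 15.0
        diag = cooks_distance(x, y)
        assert int(np.argmax(diag.cooks_d)) == 6
        assert 6 in diag.flagged

    def test_leave_one_out_identity_on_six_points(self):
        # D_i must equal the fitted-value shift when observation i is
        # refit out: sum_j (yhat_j - yhat_j(i))^2 / (p * s^2)
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 9.0])
        y = np.array([1.2, 1.9, 3.4, 3.8, 5.6, 7.0])
        diag = cooks_distance(x, y)
        X = np.column_stack([np.ones(6), x])
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        yhat = X @ beta
        s2 = float(np.sum((y - yhat) ** 2)) / 4
        for i in range(6):
            keep = np.arange(6) != i
            beta_i = np.linalg.lstsq(X[keep], y[keep], rcond=None)[0]
            d_oracle = float(np.sum((yhat - X @ beta_i) ** 2)) / (2 * s2)
            assert diag.cooks_d[i] == pytest.approx(d_oracle, rel=1e-10)

    def test_leverage_sums_to_two(self):
        rng = np.random.default_rng(10)
        x = rng.standard_normal(30)
        y = rng.standard_normal(30)
        diag = cooks_distance(x, y)
        assert float(diag.leverage.sum()) == pytest.approx(2.0)
        assert ((diag.leverage > 0) & (diag.leverage < 1)).all()

    def test_flags_invariant_to_affine_rescaling(self):
        rng = np.random.default_rng(11)
        x = rng.standard_normal(25)
        y = 0.7 * x + rng.standard_normal(25)
        a = cooks_distance(x, y)
        b = cooks_distance(100.0 * x - 3.0, -5.0 * y + 40.0)
        assert np.allclose(a.cooks_d, b.cooks_d)
        assert (a.flagged == b.flagged).all()

    def test_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(12)
        x = rng.standard_normal(40)
        y = 0.5 * x + rng.standard_normal(40)
        diag = cooks_distance(x, y)
        model = sm.OLS(y, sm.add_constant(x)).fit()
        d_sm = model.get_influence().cooks_distance[0]
        assert np.allclose(diag.cooks_d, d_sm)

    def test_constant_predictor_rejected(self):
        with pytest.raises(DegenerateInputError):
            cooks_distance(np.ones(8), np.arange(8.0))


class TestPairedT:
    def test_identical_vectors_give_zero(self):
        a = np.array([1.0, 2.0, 3.0])
        t, df, p = paired_t(a, a)
        assert (t, df, p) == (0.0, 2, 1.0)

    def test_constant_nonzero_difference_rejected(self):
        a = np.array([2.0, 3.0, 4.0, 5.0])
        with pytest.raises(DegenerateInputError):
            paired_t(a, a - 1.0)

    def test_four_pair_hand_computation(self):
        a = np.array([5.0, 7.0, 6.0, 9.0])
        b = np.array([4.0, 6.0, 7.0, 6.0])
        d = a - b  # [1, 1, -1, 3] -> mean 1, sd sqrt(8/3)
        t_hand = 1.0 / (math.sqrt(8 / 3) / 2.0)
        t, df, p = paired_t(a, b)
        assert t == pytest.approx(t_hand, abs=1e-12)
        assert df == 3
        assert 0 < p <= 1


class TestShapiroWilk:
    def test_normal_samples_rarely_rejected(self):
        rng = np.random.default_rng(13)
        passes = sum(
            shapiro_wilk(rng.standard_normal(50))[1] > 0.05 for _ in range(200)
        )
        assert passes / 200 >= 0.90

    def test_lognormal_samples_usually_rejected(self):
        rng = np.random.default_rng(14)
        hits = sum(
            shapiro_wilk(np.exp(1.5 * rng.standard_normal(50)))[1] < 0.05
            for _ in range(200)
        )
        assert hits / 200 >= 0.90

    def test_tiny_sample_rejected(self):
        with pytest.raises(InsufficientDataError):
            shapiro_wilk([1.0, 2.0])


def _toy_tables(n=30, seed=0, b_lat=60.0, b_dwell=-40.0):
    rng = np.random.default_rng(seed)
    srs = rng.normal(49, 19, n)
    spaic = 0.36 * 7.3 / 19 * (srs - 49) + 35 + 6.8 * rng.standard_normal(n)
    latency = 700 + b_lat * (srs - 49) / 19 + 60 * rng.standard_normal(n)
    dwell = 500 + b_dwell * (spaic - 35) / 7.3 + 60 * rng.standard_normal(n)
    summaries = pd.DataFrame(
        {
            "participant_id": [f"p{i}" for i in range(n)],
            "mean_latency_ms": latency,
            "mean_dwell_ms": dwell,
            "mean_latency_silent_ms": latency + rng.normal(50, 30, n),
            "mean_latency_cued_ms": latency - rng.normal(50, 30, n),
            "contrast_eligible": True,
        }
    )
    traits = pd.DataFrame(
        {
            "participant_id": [f"p{i}" for i in range(n)],
            "srs_total": srs,
            "spaic_total": spaic,
        }
    )
    return summaries, traits


class TestAssociationAnalysis:
    def test_planted_sign_pattern_recovered(self):
        summaries, traits = _toy_tables()
        res = run_association_analysis(summaries, traits, StatsConfig(subscale_analysis=False))
        t = res.tests

        def get(analysis, measure, predictor):
            rows = t[
                (t.analysis == analysis) & (t.measure == measure) & (t.predictor == predictor)
            ]
            return float(rows["estimate"].iloc[0])

        assert get("pearson", "latency_to_eyes", "srs") > 0
        assert get("partial", "latency_to_eyes", "srs") > 0
        assert get("pearson", "first_pass_dwell", "spaic") < 0
        assert get("partial", "first_pass_dwell", "spaic") < 0
        assert set(t.analysis) == {"pearson", "partial", "steiger"}
        assert res.contrast is not None and res.contrast["t"] > 0

    def test_cooks_removals_are_logged_per_pair(self):
        summaries, traits = _toy_tables(seed=5)
        # plant one gross bivariate outlier in the latency-srs pair
        summaries.loc[0, "mean_latency_ms"] = 3000.0
        res = run_association_analysis(summaries, traits, StatsConfig(subscale_analysis=False))
        t = res.tests
        removed = t[(t.analysis == "pearson") & (t.measure == "latency_to_eyes") & (t.predictor == "srs")][
            "n_removed_outliers"
        ].iloc[0]
        assert removed >= 1
        assert any("Cook's" in n for n in res.notes)

    def test_insufficient_sample_aborts(self):
        summaries, traits = _toy_tables(n=6)
        with pytest.raises(InsufficientDataError):
            run_association_analysis(summaries, traits)

    def test_missing_spaic_reduces_complete_case_n(self):
        summaries, traits = _toy_tables(n=20, seed=8)
        traits.loc[3, "spaic_total"] = np.nan
        res = run_association_analysis(summaries, traits, StatsConfig(subscale_analysis=False))
        t = res.tests
        n_lat_srs = int(
            t[(t.analysis == "pearson") & (t.measure == "latency_to_eyes") & (t.predictor == "srs")]["n"].iloc[0]
        )
        n_lat_spaic = int(
            t[(t.analysis == "pearson") & (t.measure == "latency_to_eyes") & (t.predictor == "spaic")]["n"].iloc[0]
        )
        assert n_lat_spaic <= 19 < n_lat_srs + 1  # spaic pair lost a case

    def test_all_p_values_two_tailed_in_unit_interval(self):
        summaries, traits = _toy_tables(seed=15)
        res = run_association_analysis(summaries, traits)
        p = res.tests["p"].to_numpy(dtype=float)
        assert ((p > 0) & (p <= 1)).all()
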