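"""Windowed features, censoring, OLS engine, window search, predictivity."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from lifesignal.regression import (
    DegenerateOutcomeError,
    FeatureExtractor,
    SearchError,
    TimeWindow,
    WindowFeatureError,
    fixed_window_regression,
    lattice_windows,
    peak_features_regression,
    predictivity_timecourse,
    regress_lifespan,
    sliding_window_search,
    window_features,
)
from conftest import flat_series, make_dataset


def _features_frame(y, mean, slope):
    return pd.DataFrame(
        {"mean": mean, "slope": slope, "lifespan_h": y},
        index=pd.Index([f"a{i}" for i in range(len(y))], name="animal_id"),
    )


class TestWindowFeatures:
    def test_constant_series(self):
        rows = flat_series("a1", 1, [0, 4, 8, 12], [3.0, 3.0, 3.0, 3.0])
        ds = make_dataset([("a1", 1, 0.0, None, 100.0, False, "none")], rows)
        feats = window_features(ds, "gfp", TimeWindow(0.0, 12.0))
        assert feats.loc["a1", "mean"] == pytest.approx(3.0)
        assert feats.loc["a1", "slope"] == pytest.approx(0.0, abs=1e-15)

    def test_collinear_points_exact_ols(self):
        rows = flat_series("a1", 1, [0, 4, 8], [0.0, 8.0, 16.0])
        ds = make_dataset([("a1", 1, 0.0, None, 100.0, False, "none")], rows)
        feats = window_features(ds, "gfp", TimeWindow(0.0, 8.0))
        assert feats.loc["a1", "slope"] == pytest.approx(2.0)
        assert feats.loc["a1", "mean"] == pytest.approx(8.0)

    def test_death_within_window_censors_not_errors(self):
        rows = flat_series("a1", 1, np.arange(0, 84, 4.0), np.ones(21)) + flat_series(
            "a2", 1, np.arange(0, 200, 4.0), np.ones(50)
        )
        ds = make_dataset(
            [
                ("a1", 1, 0.0, None, 84.0, False, "none"),  # dies mid-window
                ("a2", 1, 0.0, None, 200.0, False, "none"),
            ],
            rows,
        )
        ext = FeatureExtractor(ds, "gfp", "mean")
        feats = ext.features(TimeWindow(72.0, 96.0))
        assert list(feats.index) == ["a2"]
        assert ext.censored_count(TimeWindow(72.0, 96.0)) == 1

    def test_death_exactly_at_window_end_is_censored(self):
        rows = flat_series("a1", 1, np.arange(0, 100, 4.0), np.ones(25))
        ds = make_dataset([("a1", 1, 0.0, None, 96.0, False, "none")], rows)
        feats = FeatureExtractor(ds, "gfp", "mean").features(TimeWindow(72.0, 96.0))
        assert len(feats) == 0

    def test_window_outside_sampling_range_is_error(self):
        rows = flat_series("a1", 1, [0, 4, 8], [1, 2, 3])
        ds = make_dataset([("a1", 1, 0.0, None, 500.0, False, "none")], rows)
        with pytest.raises(WindowFeatureError, match="a1"):
            window_features(ds, "gfp", TimeWindow(100.0, 130.0))

    def test_widening_window_never_adds_animals(self, default_cohort):
        ext = FeatureExtractor(default_cohort.dataset, "gfp", "mean")
        counts = [
            len(ext.features(TimeWindow(120.0, end), strict=False))
            for end in (150.0, 180.0, 210.0, 240.0, 270.0)
        ]
        assert counts == sorted(counts, reverse=True)


class TestRegressionEngine:
    def test_exact_affine_relation_gives_r2_one(self):
        rng = np.random.default_rng(0)
        mean = rng.standard_normal(50)
        slope = rng.standard_normal(50)
        res = regress_lifespan(_features_frame(300 + 40 * mean, mean, slope))
        assert res.r2_mean == pytest.approx(1.0)
        assert res.r2_joint == pytest.approx(1.0)

    def test_null_features_near_k_over_n(self):
        rng = np.random.default_rng(1)
        r2s = []
        for _ in range(40):
            y = rng.standard_normal(1000)
            res = regress_lifespan(
                _features_frame(y, rng.standard_normal(1000), rng.standard_normal(1000))
            )
            r2s.append(res.r2_joint)
        assert np.mean(r2s) == pytest.approx(2 / 999, abs=1e-3)

    def test_matches_statsmodels(self):
        rng = np.random.default_rng(2)
        mean = rng.standard_normal(80)
        slope = rng.standard_normal(80)
        y = 200 + 30 * mean - 15 * slope + rng.standard_normal(80) * 20
        res = regress_lifespan(_features_frame(y, mean, slope))
        X = sm.add_constant(np.column_stack([mean, slope]))
        sm_fit = sm.OLS(y, X).fit()
        assert res.r2_joint == pytest.approx(sm_fit.rsquared, abs=1e-12)
        sm_mean = sm.OLS(y, sm.add_constant(mean)).fit()
        assert res.r2_mean == pytest.approx(sm_mean.rsquared, abs=1e-12)

    def test_joint_r2_at_least_best_single(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            y = rng.standard_normal(40)
            res = regress_lifespan(
                _features_frame(y, rng.standard_normal(40), rng.standard_normal(40))
            )
            assert res.r2_joint >= max(res.r2_mean, res.r2_slope) - 1e-12

    def test_direction_signs(self):
        rng = np.random.default_rng(4)
        mean = rng.standard_normal(200)
        slope = 0.5 * mean + 0.1 * rng.standard_normal(200)
        y = 300 + 50 * mean + 20 * slope
        assert regress_lifespan(_features_frame(y, mean, slope)).direction == "+"
        assert regress_lifespan(_features_frame(-y, mean, slope)).direction == "-"

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(DegenerateOutcomeError):
            regress_lifespan(_features_frame([1.0, 2.0], [0.1, 0.2], [0.0, 0.1]))
        with pytest.raises(DegenerateOutcomeError, match="zero variance"):
            regress_lifespan(
                _features_frame([5.0, 5.0, 5.0], [0.1, 0.2, 0.3], [0.0, 0.1, 0.2])
            )


class TestWindowSearch:
    def test_single_admissible_window_returned(self, default_cohort):
        res = sliding_window_search(
            default_cohort.dataset, "gfp", t_min_h=144.0, t_end_bound_h=156.0
        )
        assert res.window == TimeWindow(144.0, 156.0)

    def test_no_admissible_window_raises(self):
        with pytest.raises(SearchError):
            lattice_windows(72.0, 80.0)

    def test_lattice_has_minimum_width_and_anchor(self):
        wins = lattice_windows(72.0, 132.0)
        assert all(w.width_h >= 12.0 for w in wins)
        assert all((w.start_h - 72.0) % 12.0 == 0 for w in wins)
        assert min(w.start_h for w in wins) == 72.0

    def test_fixed_window_never_beats_search(self, default_cohort):
        ds = default_cohort.dataset
        searched = sliding_window_search(ds, "gfp", t_end_bound_h=216.0)
        fixed = fixed_window_regression(ds, "gfp", TimeWindow(72.0, 216.0))
        assert fixed.r2_joint <= searched.r2_joint + 1e-12

    def test_search_consistent_with_fixed_at_best_window(self, default_cohort):
        searched = sliding_window_search(default_cohort.dataset, "gfp", t_end_bound_h=204.0)
        refit = fixed_window_regression(
            default_cohort.dataset, "gfp", searched.window
        )
        assert refit.r2_joint == searched.r2_joint

    def test_noise_search_inflation_bounded_by_permutation_max_null(
        self, decoupled_cohort
    ):
        """Maximizing over windows inflates null R^2; the permutation max-null
        distribution bounds the inflation."""
        ds = decoupled_cohort.dataset
        searched = sliding_window_search(ds, "gfp", t_end_bound_h=204.0)
        n = searched.n
        assert searched.r2_joint > 2 / (n - 1)  # above the single-window null

        # permutation oracle: shuffle lifespans, redo the full search
        rng = np.random.default_rng(0)
        animals = ds.animals.copy()
        max_nulls = []
        for _ in range(20):
            shuffled = animals.copy()
            perm = rng.permutation(len(shuffled))
            shuffled["death_age_h"] = animals["death_age_h"].to_numpy()[perm]
            shuffled["lifespan_h"] = animals["lifespan_h"].to_numpy()[perm]
            # keep observation ages valid: measurements unchanged, deaths permuted
            meas = ds.measurements
            death = shuffled.set_index("animal_id")["death_age_h"]
            ok = meas["age_h"].to_numpy() <= death.loc[meas["animal_id"]].to_numpy()
            perm_ds = type(ds)(shuffled, meas.loc[ok].reset_index(drop=True))
            max_nulls.append(
                sliding_window_search(perm_ds, "gfp", t_end_bound_h=204.0).r2_joint
            )
        assert searched.r2_joint <= max(max_nulls) + 0.01


class TestPredictivity:
    def test_decoupled_cohort_flat_curve(self, decoupled_cohort):
        """With no planted coupling every point stays within its own null band.

        Under the Gaussian null the sample R^2 with k=2 predictors follows
        Beta(1, (n-3)/2); each curve point must stay below that null's
        99.95% quantile for its own sample size.
        """
        from scipy.stats import beta

        curve = predictivity_timecourse(decoupled_cohort.dataset, "gfp")
        pts = curve.points[curve.points["n"] >= 30]
        bounds = beta.ppf(0.9995, 1, (pts["n"] - 3) / 2)
        assert (pts["r2_joint"].to_numpy() < bounds).all()

    def test_row_count_matches_lattice(self, default_cohort):
        curve = predictivity_timecourse(
            default_cohort.dataset, "gfp", t_max_h=240.0
        )
        # windows [72,96], [84,108], ... start <= 216
        assert len(curve.points) == 13

    def test_buffer_argument_validated(self, default_cohort):
        with pytest.raises(ValueError):
            predictivity_timecourse(
                default_cohort.dataset, "gfp", exclusion_buffer_h=-4.0
            )


class TestPeakFeatures:
    def test_monotone_decline_peaks_at_first_observation(self):
        ages = np.arange(0, 80, 4.0)
        rows = flat_series("a1", 1, ages, 10.0 - 0.05 * ages)
        ds = make_dataset([("a1", 1, 0.0, None, 500.0, False, "none")], rows)
        m = ds.measurements
        sel = m.sort_values(["animal_id", "age_h"])
        idx = sel.groupby("animal_id")["value"].idxmax()
        assert sel.loc[idx, "age_h"].iloc[0] == 0.0

    def test_peak_height_signal_beats_window_mean(self):
        rng = np.random.default_rng(5)
        ages = np.arange(0, 300, 4.0)
        animals, rows = [], []
        for i in range(150):
            h = 1.0 + 0.5 * rng.standard_normal()
            lifespan = 250.0 + 60.0 * (h - 1.0) + 5.0 * rng.standard_normal()
            lifespan = max(lifespan, 150.0)
            keep = ages <= lifespan
            bump = h * np.exp(-(((ages[keep] - 60.0) / 20.0) ** 2))
            noise = 0.01 * rng.standard_normal(keep.sum())
            aid = f"a{i:03d}"
            animals.append((aid, 1, 0.0, None, float(lifespan), False, "none"))
            rows += flat_series(aid, 1, ages[keep], bump + noise)
        ds = make_dataset(animals, rows)
        peak = peak_features_regression(ds, "gfp")
        windowed = fixed_window_regression(ds, "gfp", TimeWindow(120.0, 148.0))
        assert peak.r2_joint > 0.5
        assert peak.r2_joint > windowed.r2_joint + 0.2

    def test_decoupled_cohort_artifact_and_bounded_control(self, decoupled_cohort):
        """Whole-trajectory peak scans carry a survivorship artifact (more
        observations -> stochastically higher, later maxima); bounding the
        scan to a common age range restores the null."""
        ds = decoupled_cohort.dataset
        unbounded = peak_features_regression(ds, "gfp")
        assert unbounded.r2_joint < 0.1  # modest, but not exactly null
        bounded = peak_features_regression(ds, "gfp", max_age_h=144.0)
        assert bounded.r2_joint < 0.02
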