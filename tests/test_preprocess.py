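"""Normalization, binning, smoothing and survival quantiles."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from lifesignal.preprocess import (
    BinningError,
    NormalizationError,
    SmoothingError,
    bin_lifespan_quantiles,
    lowess_trend,
    normalize,
    rescale_time_by_median_lifespan,
    survival_curve,
    survival_quantile_time,
    ztransform_by_replicate,
)

from conftest import flat_series, make_dataset


def _single_series_dataset(values, ages=None, replicate=1, animal="a1", death=1000.0):
    ages = ages if ages is not None else 4.0 * np.arange(len(values))
    rows = flat_series(animal, replicate, ages, values)
    return make_dataset([(animal, replicate, 0.0, None, death, False, "none")], rows)


class TestZTransform:
    def test_hand_computed_population_sd(self):
        ds = _single_series_dataset([1.0, 2.0, 3.0])
        out = ztransform_by_replicate(ds, "gfp")
        np.testing.assert_allclose(
            out.dataset.measurements["value"].to_numpy(),
            [-1.22474487, 0.0, 1.22474487],
            atol=1e-8,
        )

    def test_idempotent_on_standardized_data(self):
        rng = np.random.default_rng(0)
        v = rng.standard_normal(40)
        v = (v - v.mean()) / v.std()
        ds = _single_series_dataset(v)
        out = ztransform_by_replicate(ds, "gfp")
        np.testing.assert_allclose(
            out.dataset.measurements["value"].to_numpy(), v, atol=1e-10
        )

    def test_each_replicate_separately_standardized(self):
        rows = flat_series("a1", 1, [0, 4, 8, 12], [10.0, 11, 12, 13]) + flat_series(
            "a2", 2, [0, 4, 8, 12], [100.0, 102, 104, 106]
        )
        ds = make_dataset(
            [
                ("a1", 1, 0.0, None, 500.0, False, "none"),
                ("a2", 2, 0.0, None, 500.0, False, "none"),
            ],
            rows,
        )
        out = ztransform_by_replicate(ds, "gfp")
        m = out.dataset.measurements
        for rep in (1, 2):
            vals = m.loc[m["replicate_id"] == rep, "value"]
            assert vals.mean() == pytest.approx(0, abs=1e-12)
            assert vals.std(ddof=0) == pytest.approx(1, abs=1e-12)

    def test_zero_variance_names_replicate(self):
        ds = _single_series_dataset([5.0, 5.0, 5.0])
        with pytest.raises(NormalizationError, match="replicate"):
            ztransform_by_replicate(ds, "gfp")

    def test_inverse_restores_original(self, default_cohort):
        ds = default_cohort.dataset
        norm = normalize(ds, "gfp")
        back = norm.invert()
        np.testing.assert_allclose(
            back.measurements["value"].to_numpy(),
            ds.measurements["value"].to_numpy(),
            rtol=1e-12,
        )
        np.testing.assert_allclose(
            back.measurements["age_h"].to_numpy(),
            ds.measurements["age_h"].to_numpy(),
            rtol=1e-12,
        )


class TestTimeRescale:
    def _two_replicates(self, lifespans1, lifespans2):
        animals, rows = [], []
        for i, d in enumerate(lifespans1):
            aid = f"r1_{i}"
            animals.append((aid, 1, 0.0, None, float(d), False, "none"))
            rows += flat_series(aid, 1, [0, 4, 8], [1, 2, 3])
        for i, d in enumerate(lifespans2):
            aid = f"r2_{i}"
            animals.append((aid, 2, 0.0, None, float(d), False, "none"))
            rows += flat_series(aid, 2, [0, 4, 8], [1, 2, 3])
        return make_dataset(animals, rows)

    def test_single_replicate_identity(self, tiny_dataset):
        out = rescale_time_by_median_lifespan(tiny_dataset)
        assert out.time_params["factor"].tolist() == [1.0]

    def test_known_factors(self):
        ds = self._two_replicates([190, 200, 210], [240, 250, 260])
        out = rescale_time_by_median_lifespan(ds)
        fac = out.time_params.set_index("replicate_id")["factor"]
        assert fac[1] == pytest.approx(1.125)
        assert fac[2] == pytest.approx(0.9)

    def test_replicate_medians_align_after_rescale(self):
        ds = self._two_replicates([180, 200, 220, 240], [230, 250, 270])
        out = rescale_time_by_median_lifespan(ds)
        med = out.dataset.animals.groupby("replicate_id")["lifespan_h"].median()
        assert med[1] == pytest.approx(med[2])

    def test_age_order_preserved(self):
        ds = self._two_replicates([200, 210], [250, 260])
        out = rescale_time_by_median_lifespan(ds)
        for _, grp in out.dataset.measurements.groupby("animal_id"):
            assert grp["age_h"].is_monotonic_increasing


class TestBinning:
    def _cohort(self, lifespans):
        animals = [
            (f"a{i:04d}", 1, 0.0, None, float(d), False, "none")
            for i, d in enumerate(lifespans)
        ]
        return make_dataset(animals, [])

    def test_ten_animals_five_bins_of_two(self):
        binning = bin_lifespan_quantiles(self._cohort(range(100, 200, 10)), k=5)
        assert binning.boundaries["n"].tolist() == [2, 2, 2, 2, 2]

    def test_403_animals_sizes(self):
        rng = np.random.default_rng(0)
        binning = bin_lifespan_quantiles(self._cohort(rng.uniform(100, 400, 403)), k=5)
        assert binning.boundaries["n"].tolist() == [81, 81, 81, 80, 80]

    def test_all_ties_stable_and_balanced(self):
        binning = bin_lifespan_quantiles(self._cohort([200.0] * 10), k=5)
        assert binning.boundaries["n"].tolist() == [2, 2, 2, 2, 2]
        # stable tie-break: lexicographic animal_id order
        assert binning.assignment.loc["a0000"] == 1
        assert binning.assignment.loc["a0009"] == 5

    def test_k_exceeding_n_raises(self):
        with pytest.raises(BinningError):
            bin_lifespan_quantiles(self._cohort([100.0, 200.0]), k=5)

    @given(st.permutations(list(range(12))))
    def test_monotone_transform_invariance(self, ranks):
        lifespans = 100 + 10 * np.asarray(ranks, dtype=float)
        a = bin_lifespan_quantiles(self._cohort(lifespans), k=4)
        b = bin_lifespan_quantiles(self._cohort(np.exp(lifespans / 50)), k=4)
        pd.testing.assert_series_equal(a.assignment, b.assignment)


class TestLowess:
    def test_constant_data_constant_trend(self):
        ds = _single_series_dataset(np.full(15, 3.0))
        trend = lowess_trend(ds, "gfp", fraction=0.5)
        np.testing.assert_allclose(trend["value"], 3.0, atol=1e-6)

    def test_linear_data_recovered(self):
        ages = 4.0 * np.arange(30)
        ds = _single_series_dataset(2.0 + 0.05 * ages, ages=ages)
        trend = lowess_trend(ds, "gfp", fraction=0.4)
        interior = trend.iloc[5:-5]
        np.testing.assert_allclose(
            interior["value"], 2.0 + 0.05 * interior["age_h"], atol=1e-6
        )

    def test_small_fraction_tracks_structure_better(self):
        rng = np.random.default_rng(3)
        ages = np.linspace(0, 200, 300)
        truth = np.sin(ages / 20)
        rows = flat_series("a1", 1, ages, truth + 0.1 * rng.standard_normal(300))
        ds = make_dataset([("a1", 1, 0.0, None, 1000.0, False, "none")], rows)
        grid = np.linspace(20, 180, 40)
        t_small = lowess_trend(ds, "gfp", fraction=0.1, grid=grid)
        t_big = lowess_trend(ds, "gfp", fraction=1.0, grid=grid)
        mse_small = np.mean((t_small["value"] - np.sin(grid / 20)) ** 2)
        mse_big = np.mean((t_big["value"] - np.sin(grid / 20)) ** 2)
        assert mse_small < mse_big

    def test_too_few_points_raises(self):
        ds = _single_series_dataset([1.0, 2.0, 3.0])
        with pytest.raises(SmoothingError):
            lowess_trend(ds, "gfp")


class TestSurvival:
    def _cohort(self, lifespans):
        animals = [
            (f"a{i}", 1, 0.0, None, float(d), False, "none")
            for i, d in enumerate(lifespans)
        ]
        return make_dataset(animals, [])

    def test_ninety_percent_survival_is_first_death_of_ten(self):
        ds = self._cohort(range(10, 110, 10))
        assert survival_quantile_time(ds, 0.9) == 10.0

    def test_q_near_one_gives_first_death(self):
        ds = self._cohort([55.0, 80.0, 120.0])
        assert survival_quantile_time(ds, 0.999) == 55.0

    def test_step_function_properties(self):
        ds = self._cohort([10, 30, 30, 50])
        s = survival_curve(ds)
        assert s(0.0) == 1.0
        assert s(50.0) == 0.0
        ts = np.linspace(0, 60, 121)
        assert (np.diff(s(ts)) <= 1e-12).all()
        assert s(30.0) == pytest.approx(0.25)  # both ties counted at 30

    def test_invalid_quantile_rejected(self):
        ds = self._cohort([10, 20])
        with pytest.raises(ValueError):
            survival_quantile_time(ds, 1.5)
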