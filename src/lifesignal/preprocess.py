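"""Normalization and cohort reshaping ahead of pooled regression analysis.

Biological replicates of a longitudinal cohort differ in absolute
fluorescence (imaging session effects) and somewhat in lifespan (batch and
seasonal effects).  Before pooling replicates for regression, expression
values are z-transformed within each replicate and ages are rescaled so
every replicate's median lifespan matches the pooled median.  Both
transforms record their parameters so they can be inverted exactly.

Also provided: rank-based lifespan quantile binning (for quintile-cohort
visualizations), LOWESS trend smoothing (visualization only, never
inference), and the empirical survival curve with its quantile timepoints
(the "90% survival" age bounds window searches).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from .io import Dataset

__all__ = [
    "NormalizationError",
    "SmoothingError",
    "BinningError",
    "NormalizedDataset",
    "CohortBinning",
    "SurvivalCurve",
    "ztransform_by_replicate",
    "rescale_time_by_median_lifespan",
    "normalize",
    "bin_lifespan_quantiles",
    "lowess_trend",
    "survival_curve",
    "survival_quantile_time",
]


class NormalizationError(ValueError):
    """A replicate cannot be normalized (too few animals or zero variance)."""


class SmoothingError(ValueError):
    """Too few observations to fit a trend."""


class BinningError(ValueError):
    """Requested more bins than animals."""


@dataclass
class NormalizedDataset:
    """A dataset plus the parameters of the transforms applied to it.

    ``expression_params`` holds one row per replicate (or per replicate and
    timepoint in per-timepoint mode) with the subtracted mean and dividing
    SD; ``time_params`` holds one row per replicate with the age multiplier.
    Either may be None if that transform was not applied.  ``invert``
    reconstructs the original dataset to floating precision.
    """

    dataset: Dataset
    expression_params: pd.DataFrame | None = None
    time_params: pd.DataFrame | None = None

    def invert(self) -> Dataset:
        meas = self.dataset.measurements.copy()
        animals = self.dataset.animals.copy()
        if self.time_params is not None:
            fac = self.time_params.set_index("replicate_id")["factor"]
            f_meas = fac.loc[meas["replicate_id"]].to_numpy()
            meas["age_h"] = meas["age_h"] / f_meas
            f_ann = fac.loc[animals["replicate_id"]].to_numpy()
            for col in ("hatch_age_h", "first_egg_age_h", "death_age_h", "lifespan_h"):
                animals[col] = animals[col] / f_ann
        if self.expression_params is not None:
            p = self.expression_params
            keys = [c for c in ("replicate_id", "age_h") if c in p.columns]
            sel = (meas["reporter"] == p["reporter"].iloc[0]) & (
                meas["statistic"] == p["statistic"].iloc[0]
            )
            sub = meas.loc[sel].merge(p, on=keys, how="left", suffixes=("", "_p"))
            meas.loc[sel, "value"] = (
                sub["value"] * sub["sd"] + sub["mean"]
            ).to_numpy()
        return Dataset(animals, meas, self.dataset.provenance)


def ztransform_by_replicate(
    dataset: Dataset,
    reporter: str,
    statistic: str = "mean",
    per_timepoint: bool = False,
) -> NormalizedDataset:
    """Z-score one reporter/statistic's values within each replicate.

    By default all (animal x timepoint) values of a replicate are pooled
    into one mean/SD (population convention, 1/n), the literal reading of
    z-transforming "relative to each biological replicate".  With
    ``per_timepoint=True`` the standardization is computed separately at
    each sampling age within the replicate — an alternative reading, kept
    behind this switch.
    """
    meas = dataset.measurements.copy()
    sel = (meas["reporter"] == reporter) & (meas["statistic"] == statistic)
    if not sel.any():
        raise NormalizationError(f"no measurements for {reporter!r}/{statistic!r}")
    sub = meas.loc[sel]
    keys = ["replicate_id", "age_h"] if per_timepoint else ["replicate_id"]
    grouped = sub.groupby(keys)["value"]
    params = grouped.agg(mean="mean", sd=lambda v: v.std(ddof=0), n="size").reset_index()
    bad = params[(params["sd"] == 0) | (params["n"] < 2)]
    if len(bad):
        rep = bad["replicate_id"].iloc[0]
        raise NormalizationError(
            f"replicate {rep!r}: zero variance or fewer than 2 values"
        )
    merged = sub.merge(params, on=keys, how="left")
    meas.loc[sel, "value"] = ((merged["value"] - merged["mean"]) / merged["sd"]).to_numpy()
    params["reporter"] = reporter
    params["statistic"] = statistic
    return NormalizedDataset(
        Dataset(dataset.animals.copy(), meas, dataset.provenance),
        expression_params=params,
    )


def rescale_time_by_median_lifespan(dataset: Dataset) -> NormalizedDataset:
    """Rescale each replicate's clock so median lifespans align.

    Every age in replicate *r* (observation ages and life-stage
    annotations alike) is multiplied by ``pooled_median / median_r``, the
    pooled median taken over all included animals.  After rescaling, each
    replicate's median lifespan equals the pooled median, so pooled windowed
    analyses compare animals at equivalent physiological ages.
    """
    animals = dataset.animals
    alive = ~animals["excluded"].astype(bool)
    if not alive.any():
        raise NormalizationError("no included animals to rescale by")
    pooled_median = float(animals.loc[alive, "lifespan_h"].median())
    rep_median = animals.loc[alive].groupby("replicate_id")["lifespan_h"].median()
    factors = (pooled_median / rep_median).rename("factor").reset_index()

    meas = dataset.measurements.copy()
    fac = factors.set_index("replicate_id")["factor"]
    meas["age_h"] = meas["age_h"] * fac.loc[meas["replicate_id"]].to_numpy()
    ann = animals.copy()
    f_ann = fac.loc[ann["replicate_id"]].to_numpy()
    for col in ("hatch_age_h", "first_egg_age_h", "death_age_h", "lifespan_h"):
        ann[col] = ann[col] * f_ann
    factors["pooled_median"] = pooled_median
    return NormalizedDataset(
        Dataset(ann, meas, dataset.provenance), time_params=factors
    )


def normalize(
    dataset: Dataset, reporter: str, statistic: str = "mean", per_timepoint: bool = False
) -> NormalizedDataset:
    """Standard pre-regression pipeline: z-transform then time rescale."""
    z = ztransform_by_replicate(dataset, reporter, statistic, per_timepoint)
    t = rescale_time_by_median_lifespan(z.dataset)
    return NormalizedDataset(
        t.dataset, expression_params=z.expression_params, time_params=t.time_params
    )


# -- lifespan binning ----------------------------------------------------


@dataclass
class CohortBinning:
    """Rank-based lifespan bins (1 = shortest-lived) for visualization."""

    assignment: pd.Series  # animal_id -> bin index
    boundaries: pd.DataFrame  # bin, n, lifespan_min, lifespan_max

    @property
    def k(self) -> int:
        return int(self.boundaries["bin"].max())


def bin_lifespan_quantiles(dataset: Dataset, k: int = 5) -> CohortBinning:
    """Partition included animals into k lifespan-rank bins.

    Bins are as equal as possible (sizes differ by at most one; the
    longer bins are the shortest-lived ones when n % k != 0).  Ties in
    lifespan are broken by stable animal_id order, so the binning is
    deterministic and invariant under any strictly monotone transform of
    lifespan.
    """
    animals = dataset.animals.loc[~dataset.animals["excluded"].astype(bool)]
    n = len(animals)
    if k > n:
        raise BinningError(f"k={k} exceeds population size {n}")
    order = animals.sort_values(
        ["lifespan_h", "animal_id"], kind="stable"
    ).reset_index(drop=True)
    base, rem = divmod(n, k)
    sizes = [base + (1 if i < rem else 0) for i in range(k)]
    bins = np.repeat(np.arange(1, k + 1), sizes)
    assignment = pd.Series(bins, index=order["animal_id"], name="bin")
    rows = []
    for b in range(1, k + 1):
        life = order.loc[bins == b, "lifespan_h"]
        rows.append(
            {"bin": b, "n": int(len(life)), "lifespan_min": life.min(), "lifespan_max": life.max()}
        )
    return CohortBinning(assignment, pd.DataFrame(rows))


# -- LOWESS trends -------------------------------------------------------


def lowess_trend(
    dataset: Dataset,
    reporter: str,
    statistic: str = "mean",
    fraction: float = 0.3,
    animal_ids=None,
    grid: np.ndarray | None = None,
) -> pd.DataFrame:
    """Locally weighted trend of pooled expression vs age (visualization).

    Pools (age, value) observations across the selected animals and fits a
    LOWESS curve (tricube weights, one robustness iteration) evaluated on a
    regular age grid.  This is a display aid; all inference uses the
    per-animal windowed regression machinery instead.
    """
    m = dataset.measurements
    sel = (m["reporter"] == reporter) & (m["statistic"] == statistic)
    if animal_ids is not None:
        sel &= m["animal_id"].isin(pd.Index(animal_ids))
    sub = m.loc[sel]
    if len(sub) < 10:
        raise SmoothingError(f"need >=10 observations, have {len(sub)}")
    if grid is None:
        grid = np.linspace(sub["age_h"].min(), sub["age_h"].max(), 50)
    fitted = _sm_lowess(
        sub["value"].to_numpy(),
        sub["age_h"].to_numpy(),
        frac=fraction,
        it=1,
        xvals=np.asarray(grid, dtype=float),
    )
    return pd.DataFrame({"age_h": grid, "value": fitted})


# -- survival ------------------------------------------------------------


@dataclass
class SurvivalCurve:
    """Empirical survival step function over included animals.

    ``S(t)`` is the fraction of animals with lifespan strictly greater
    than ``t``; all deaths are observed in this design, so no
    Kaplan-Meier censoring machinery is needed.
    """

    death_ages: np.ndarray  # sorted

    def __call__(self, t) -> np.ndarray | float:
        t = np.asarray(t, dtype=float)
        frac = 1.0 - np.searchsorted(self.death_ages, t, side="right") / self.death_ages.size
        return float(frac) if frac.ndim == 0 else frac

    def quantile_time(self, q: float) -> float:
        """Age of the death that first brings survival down to q or below.

        The "90% survival timepoint" is ``quantile_time(0.9)``: the earliest
        observed death age at which no more than 90% of the population
        remains alive.
        """
        if not 0 < q < 1:
            raise ValueError("q must be in (0, 1)")
        s_after = 1.0 - np.arange(1, self.death_ages.size + 1) / self.death_ages.size
        idx = int(np.argmax(s_after <= q + 1e-12))
        return float(self.death_ages[idx])


def survival_curve(dataset: Dataset) -> SurvivalCurve:
    """Survival step function of the non-excluded population."""
    animals = dataset.animals.loc[~dataset.animals["excluded"].astype(bool)]
    if len(animals) == 0:
        raise ValueError("no included animals")
    return SurvivalCurve(np.sort(animals["lifespan_h"].to_numpy(dtype=float)))


def survival_quantile_time(dataset: Dataset, q: float) -> float:
    """Convenience wrapper: ``survival_curve(dataset).quantile_time(q)``."""
    return survival_curve(dataset).quantile_time(q)
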