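"""Windowed expression features regressed against future lifespan.

The central question: does an individual's reporter expression, summarized
over a time window while (nearly) the whole population is still alive,
predict how long that individual will live?

For a window ``[start, end]`` each animal contributes two features — the
arithmetic mean of its in-window expression values and the ordinary
least-squares slope of expression on age over those values.  Animals that
die before or within the window are censored (excluded from that window's
regression) to avoid truncation effects.  Features are regressed against
lifespan by OLS, singly and jointly; the joint coefficient of
determination R^2 is the headline statistic.

Because reporters differ in temporal dynamics, the informative window is
found by exhaustive search: both endpoints move on a 12-h lattice anchored
at 3 days post-hatch, bounded above by the 90% survival timepoint, minimum
width 12 h, and the window maximizing the joint R^2 is reported.  Searching
for a maximum inflates R^2 on pure noise relative to a single
pre-specified window; the companion fixed-window analysis and the
bootstrap CI contextualize this (and the property is tested explicitly).

Predictivity timecourses slide a fixed-width (24 h) window across life and
plot the joint R^2 against the window's center age, optionally also
excluding animals that die within 24 or 48 h *after* the window, to show
that prediction is not driven purely by imminent death.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import Dataset
from .preprocess import survival_quantile_time
from .stats import BootstrapSpec, bootstrap_ci

__all__ = [
    "TimeWindow",
    "WindowFeatureError",
    "SearchError",
    "DegenerateOutcomeError",
    "FeatureExtractor",
    "RegressionResult",
    "PredictivityCurve",
    "window_features",
    "regress_lifespan",
    "sliding_window_search",
    "fixed_window_regression",
    "predictivity_timecourse",
    "peak_features_regression",
    "results_table",
]

logger = logging.getLogger(__name__)

HOURS_PER_DPH = 24.0


class WindowFeatureError(ValueError):
    """A surviving animal has no observations inside the window."""


class SearchError(ValueError):
    """No admissible window on the search lattice."""


class DegenerateOutcomeError(ValueError):
    """Lifespan (or a predictor) has zero variance."""


@dataclass(frozen=True)
class TimeWindow:
    """A closed age interval [start_h, end_h], hours post-hatch.

    Both endpoints are inclusive: an observation at exactly ``end_h`` is
    in-window, and an animal dying exactly at ``end_h`` is censored
    ("died before or within" the window).
    """

    start_h: float
    end_h: float

    def __post_init__(self) -> None:
        if self.end_h <= self.start_h:
            raise ValueError("window end must exceed start")

    @property
    def width_h(self) -> float:
        return self.end_h - self.start_h

    @property
    def center_h(self) -> float:
        return 0.5 * (self.start_h + self.end_h)

    def as_dph(self) -> str:
        return f"{self.start_h / HOURS_PER_DPH:.1f}-{self.end_h / HOURS_PER_DPH:.1f}"


# -- feature extraction --------------------------------------------------


class FeatureExtractor:
    """Per-animal (mean, slope) features over arbitrary windows, with caching.

    Prefix sums over each animal's age-sorted series make every window's
    mean and OLS slope an O(1) lookup after two binary searches, so
    exhaustive window searches stay cheap.  Only non-excluded animals enter.
    """

    def __init__(
        self, dataset: Dataset, reporter: str, statistic: str = "mean", min_obs: int = 3
    ):
        if min_obs < 2:
            raise ValueError("min_obs must be >= 2 (slope needs two points)")
        self.min_obs = min_obs
        animals = dataset.animals.loc[~dataset.animals["excluded"].astype(bool)]
        m = dataset.measurements
        sel = m[(m["reporter"] == reporter) & (m["statistic"] == statistic)]
        sel = sel[sel["animal_id"].isin(animals["animal_id"])]
        if len(sel) == 0:
            raise ValueError(f"no measurements for {reporter!r}/{statistic!r}")
        sel = sel.sort_values(["animal_id", "age_h"], kind="stable")

        self.animal_ids = sel["animal_id"].unique()
        death = animals.set_index("animal_id")["death_age_h"]
        life = animals.set_index("animal_id")["lifespan_h"]
        self.death_ages = death.loc[self.animal_ids].to_numpy(dtype=float)
        self.lifespans = life.loc[self.animal_ids].to_numpy(dtype=float)

        ages = sel["age_h"].to_numpy(dtype=float)
        values = sel["value"].to_numpy(dtype=float)
        counts = sel.groupby("animal_id", sort=False).size().to_numpy()
        self._offsets = np.concatenate([[0], np.cumsum(counts)])
        self._ages = ages
        # prefix sums padded with a leading zero for O(1) range sums
        self._cs_v = self._prefix(values)
        self._cs_a = self._prefix(ages)
        self._cs_av = self._prefix(ages * values)
        self._cs_aa = self._prefix(ages * ages)

    @staticmethod
    def _prefix(x: np.ndarray) -> np.ndarray:
        out = np.empty(x.size + 1)
        out[0] = 0.0
        np.cumsum(x, out=out[1:])
        return out

    @property
    def n_animals(self) -> int:
        return len(self.animal_ids)

    def features(self, window: TimeWindow, strict: bool = True) -> pd.DataFrame:
        """Features for animals surviving beyond the window.

        Returns a frame indexed by animal_id with columns ``mean``,
        ``slope``, ``n_obs``, ``lifespan_h``; censored animals (dead at or
        before ``window.end_h``, or surviving but with fewer than
        ``min_obs`` in-window observations) are absent.  With ``strict``,
        a surviving animal with *zero* in-window observations raises
        :class:`WindowFeatureError` — that is a window outside the sampled
        age range, not a censoring event.
        """
        mean = np.empty(self.n_animals)
        slope = np.empty(self.n_animals)
        n_obs = np.empty(self.n_animals, dtype=int)
        for i in range(self.n_animals):
            a, b = self._offsets[i], self._offsets[i + 1]
            j0 = np.searchsorted(self._ages[a:b], window.start_h, side="left") + a
            j1 = np.searchsorted(self._ages[a:b], window.end_h, side="right") + a
            m = j1 - j0
            n_obs[i] = m
            if m == 0:
                mean[i] = slope[i] = np.nan
                continue
            sv = self._cs_v[j1] - self._cs_v[j0]
            sa = self._cs_a[j1] - self._cs_a[j0]
            sav = self._cs_av[j1] - self._cs_av[j0]
            saa = self._cs_aa[j1] - self._cs_aa[j0]
            mean[i] = sv / m
            sxx = saa - sa * sa / m
            slope[i] = (sav - sa * sv / m) / sxx if sxx > 0 else np.nan

        survives = self.death_ages > window.end_h
        if strict:
            bad = survives & (n_obs == 0)
            if bad.any():
                aid = self.animal_ids[bad][0]
                raise WindowFeatureError(
                    f"animal {aid!r} survives the window but has no in-window "
                    "observations"
                )
        keep = survives & (n_obs >= self.min_obs) & np.isfinite(slope)
        return pd.DataFrame(
            {
                "mean": mean[keep],
                "slope": slope[keep],
                "n_obs": n_obs[keep],
                "lifespan_h": self.lifespans[keep],
            },
            index=pd.Index(self.animal_ids[keep], name="animal_id"),
        )

    def censored_count(self, window: TimeWindow) -> int:
        return int(np.count_nonzero(self.death_ages <= window.end_h))


def window_features(
    dataset: Dataset,
    reporter: str,
    window: TimeWindow,
    statistic: str = "mean",
    min_obs: int = 3,
) -> pd.DataFrame:
    """One-shot feature extraction (see :class:`FeatureExtractor`)."""
    return FeatureExtractor(dataset, reporter, statistic, min_obs).features(window)


# -- regression ----------------------------------------------------------


def _r2(y: np.ndarray, X: np.ndarray) -> tuple[float, np.ndarray]:
    """OLS R^2 (standard formula, 1 - SSR/SST) and coefficients.

    ``X`` excludes the intercept; predictors and response are centered,
    which is numerically equivalent to fitting with an intercept.
    """
    yc = y - y.mean()
    sst = float(yc @ yc)
    if sst <= 0:
        raise DegenerateOutcomeError("lifespan has zero variance")
    Xc = X - X.mean(axis=0)
    coef, _, _, _ = np.linalg.lstsq(Xc, yc, rcond=None)
    resid = yc - Xc @ coef
    return 1.0 - float(resid @ resid) / sst, coef


@dataclass
class RegressionResult:
    """One row of a reporter-screen table.

    ``direction`` is the shared sign of the two univariate coefficients
    ('+' or '-'), or 'discordant' when mean and slope disagree in sign.
    ``ci95`` is the percentile-bootstrap interval for ``r2_joint`` (None
    when no bootstrap was requested).
    """

    n: int
    r2_mean: float
    r2_slope: float
    r2_joint: float
    direction: str
    window: TimeWindow | None = None
    ci95: tuple[float, float] | None = None
    censored_count: int = 0
    predictors: tuple[str, ...] = ("mean", "slope")


def regress_lifespan(
    features: pd.DataFrame,
    bootstrap: BootstrapSpec | None = None,
    window: TimeWindow | None = None,
    censored_count: int = 0,
    predictors: tuple[str, str] = ("mean", "slope"),
) -> RegressionResult:
    """OLS of lifespan on two windowed features, singly and jointly.

    ``features`` must carry the predictor columns and ``lifespan_h``.  The
    optional bootstrap resamples feature rows (whole animals) and recomputes
    the joint R^2 on each resample.
    """
    n = len(features)
    if n < 3:
        raise DegenerateOutcomeError(f"need >= 3 animals, have {n}")
    y = features["lifespan_h"].to_numpy(dtype=float)
    p1 = features[predictors[0]].to_numpy(dtype=float)
    p2 = features[predictors[1]].to_numpy(dtype=float)
    for name, p in zip(predictors, (p1, p2)):
        if np.var(p) == 0:
            raise DegenerateOutcomeError(f"predictor {name!r} has zero variance")
    r2_1, c1 = _r2(y, p1[:, None])
    r2_2, c2 = _r2(y, p2[:, None])
    X = np.column_stack([p1, p2])
    r2_joint, _ = _r2(y, X)
    if c1[0] > 0 and c2[0] > 0:
        direction = "+"
    elif c1[0] < 0 and c2[0] < 0:
        direction = "-"
    else:
        direction = "discordant"

    ci = None
    if bootstrap is not None:
        def stat(idx: np.ndarray) -> float:
            r2, _ = _r2(y[idx], X[idx])
            return r2

        ci = bootstrap_ci(n, stat, bootstrap).ci
    return RegressionResult(
        n=n,
        r2_mean=r2_1,
        r2_slope=r2_2,
        r2_joint=r2_joint,
        direction=direction,
        window=window,
        ci95=ci,
        censored_count=censored_count,
        predictors=tuple(predictors),
    )


# -- window search -------------------------------------------------------


def lattice_windows(
    t_min_h: float, t_end_bound_h: float, step_h: float = 12.0, min_width_h: float = 12.0
) -> list[TimeWindow]:
    """All candidate windows with endpoints on the search lattice.

    Endpoints are ``t_min + j*step``; the end bound is rounded down to the
    lattice.  Windows are ordered by start then width, which fixes the
    deterministic tie-break (earliest start, then smallest width).
    """
    n_steps = math.floor((t_end_bound_h - t_min_h) / step_h + 1e-9)
    points = [t_min_h + j * step_h for j in range(n_steps + 1)]
    wins = [
        TimeWindow(s, e)
        for i, s in enumerate(points)
        for e in points[i + 1 :]
        if e - s >= min_width_h - 1e-9
    ]
    if not wins:
        raise SearchError(
            f"no admissible window between {t_min_h} h and {t_end_bound_h} h"
        )
    return wins


def sliding_window_search(
    dataset: Dataset,
    reporter: str,
    statistic: str = "mean",
    t_min_h: float = 72.0,
    t_end_bound_h: float | None = None,
    step_h: float = 12.0,
    min_width_h: float = 12.0,
    min_obs: int = 3,
    bootstrap: BootstrapSpec | None = None,
) -> RegressionResult:
    """Exhaustive search for the window maximizing the joint R^2.

    The end bound defaults to the dataset's 90% survival timepoint.
    Censoring is applied independently per window.  Windows where the
    regression is infeasible (fewer than 3 surviving animals, degenerate
    predictors) are skipped; exact ties in R^2 resolve to the earliest
    start, then the smallest width.  The bootstrap CI, if requested, is
    computed for the selected window only.
    """
    if t_end_bound_h is None:
        t_end_bound_h = survival_quantile_time(dataset, 0.90)
    extractor = FeatureExtractor(dataset, reporter, statistic, min_obs)
    best: RegressionResult | None = None
    for win in lattice_windows(t_min_h, t_end_bound_h, step_h, min_width_h):
        try:
            feats = extractor.features(win, strict=False)
            result = regress_lifespan(
                feats, window=win, censored_count=extractor.censored_count(win)
            )
        except DegenerateOutcomeError:
            continue
        if best is None or result.r2_joint > best.r2_joint:
            best = result
    if best is None:
        raise SearchError("no window admitted a regression")
    if bootstrap is not None:
        feats = extractor.features(best.window, strict=False)
        best = regress_lifespan(
            feats,
            bootstrap=bootstrap,
            window=best.window,
            censored_count=best.censored_count,
        )
    return best


def fixed_window_regression(
    dataset: Dataset,
    reporter: str,
    window: TimeWindow,
    statistic: str = "mean",
    min_obs: int = 3,
    bootstrap: BootstrapSpec | None = None,
) -> RegressionResult:
    """Regression over one pre-specified window (no search)."""
    extractor = FeatureExtractor(dataset, reporter, statistic, min_obs)
    feats = extractor.features(window, strict=False)
    return regress_lifespan(
        feats,
        bootstrap=bootstrap,
        window=window,
        censored_count=extractor.censored_count(window),
    )


# -- predictivity over time ----------------------------------------------


@dataclass
class PredictivityCurve:
    """Joint R^2 of a fixed-width window as a function of window center."""

    points: pd.DataFrame  # center_age_h, start_h, end_h, r2_joint, n
    width_h: float
    exclusion_buffer_h: float
    reporter: str
    statistic: str

    def to_tsv(self, path) -> None:
        self.points.to_csv(path, sep="\t", index=False, float_format="%.10g")


def predictivity_timecourse(
    dataset: Dataset,
    reporter: str,
    statistic: str = "mean",
    width_h: float = 24.0,
    step_h: float = 12.0,
    exclusion_buffer_h: float = 0.0,
    t_min_h: float = 72.0,
    t_max_h: float | None = None,
    min_obs: int = 3,
) -> PredictivityCurve:
    """Joint R^2 of each fixed-width sliding window against future lifespan.

    For the window ``[s, s+width]`` only animals with
    ``death_age > s + width + exclusion_buffer`` enter the regression; a
    buffer of 24 or 48 h additionally excludes animals that die shortly
    *after* the window, probing whether predictivity merely reflects
    imminent death.  Windows with fewer than 3 eligible animals are
    omitted (and logged), not errors.
    """
    if exclusion_buffer_h < 0:
        raise ValueError("exclusion_buffer_h must be >= 0")
    extractor = FeatureExtractor(dataset, reporter, statistic, min_obs)
    if t_max_h is None:
        t_max_h = float(extractor.death_ages.max())
    rows = []
    start = t_min_h
    while start + width_h <= t_max_h + 1e-9:
        win = TimeWindow(start, start + width_h)
        feats = extractor.features(win, strict=False)
        if exclusion_buffer_h > 0:
            alive_beyond = extractor.death_ages > win.end_h + exclusion_buffer_h
            keep_ids = extractor.animal_ids[alive_beyond]
            feats = feats.loc[feats.index.isin(keep_ids)]
        try:
            res = regress_lifespan(feats, window=win)
        except DegenerateOutcomeError as exc:
            logger.info("window %s omitted: %s", win.as_dph(), exc)
            start += step_h
            continue
        rows.append(
            {
                "center_age_h": win.center_h,
                "start_h": win.start_h,
                "end_h": win.end_h,
                "r2_joint": res.r2_joint,
                "n": res.n,
            }
        )
        start += step_h
    return PredictivityCurve(
        pd.DataFrame(rows), width_h, exclusion_buffer_h, reporter, statistic
    )


# -- peak features -------------------------------------------------------


def peak_features_regression(
    dataset: Dataset, reporter: str, statistic: str = "mean", max_age_h: float | None = None
) -> RegressionResult:
    """Regress lifespan on (peak expression, age at peak).

    A negative control in spirit: for most reporters neither the maximum
    value an individual ever reaches nor when it reaches it is
    substantially predictive, in contrast to windowed mean/slope.
    Ties at the maximum take the earliest age.

    Beware a survivorship artifact when scanning whole trajectories: a
    longer-lived animal contributes more observations, so its observed
    maximum over measurement noise is stochastically higher and later,
    coupling both peak features to lifespan even without any biological
    signal.  Passing ``max_age_h`` bounds the scan to a common age range
    and censors animals dying at or before it, removing the artifact.
    """
    animals = dataset.animals.loc[~dataset.animals["excluded"].astype(bool)]
    m = dataset.measurements
    sel = m[(m["reporter"] == reporter) & (m["statistic"] == statistic)]
    if max_age_h is not None:
        animals = animals.loc[animals["death_age_h"] > max_age_h]
        sel = sel[sel["age_h"] <= max_age_h]
    sel = sel[sel["animal_id"].isin(animals["animal_id"])]
    sel = sel.sort_values(["animal_id", "age_h"], kind="stable")
    idx = sel.groupby("animal_id", sort=False)["value"].idxmax()  # first max
    peaks = sel.loc[idx, ["animal_id", "age_h", "value"]].rename(
        columns={"age_h": "peak_age_h", "value": "peak_value"}
    )
    feats = peaks.merge(
        animals[["animal_id", "lifespan_h"]], on="animal_id"
    ).set_index("animal_id")
    return regress_lifespan(feats, predictors=("peak_value", "peak_age_h"))


# -- reporting -----------------------------------------------------------


def results_table(results: dict[str, RegressionResult], statistics: dict[str, str] | None = None) -> pd.DataFrame:
    """Screen-style summary table, one row per reporter.

    Columns mirror the conventional reporter-screen layout: sample size,
    summary statistic, window in days post-hatch, the three R^2 values, the
    bootstrap CI of the joint R^2, the direction of correlation and the
    per-window censored count.
    """
    rows = []
    for name, res in results.items():
        ci = "" if res.ci95 is None else f"[{res.ci95[0]:.3f}, {res.ci95[1]:.3f}]"
        rows.append(
            {
                "reporter": name,
                "n": res.n,
                "statistic": "" if statistics is None else statistics.get(name, ""),
                "window_dph": "" if res.window is None else res.window.as_dph(),
                "r2_slope": res.r2_slope,
                "r2_mean": res.r2_mean,
                "r2_joint": res.r2_joint,
                "ci95": ci,
                "direction": res.direction,
                "censored": res.censored_count,
            }
        )
    return pd.DataFrame(rows)
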