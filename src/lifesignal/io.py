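"""On-disk data model for per-animal longitudinal fluorescence measurements.

A cohort is stored as two tab-separated UTF-8 text files:

``measurements.tsv``
    Long format, one row per animal x timepoint x reporter x summary
    statistic, with columns ``animal_id, replicate_id, reporter, statistic,
    age_h, value``.

``annotations.tsv``
    One row per animal, with columns ``animal_id, replicate_id,
    hatch_age_h, first_egg_age_h, death_age_h, excluded, exclusion_reason``.

Ages are hours post-hatch (an animal that hatched before the experiment
started is annotated as hatching at 0).  The long format supports ragged
series: animals die at different ages and contribute different numbers of
timepoints.  Missing first-egg ages are encoded as empty fields.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Dataset",
    "ExclusionPolicy",
    "SchemaError",
    "IntegrityError",
    "ValidationError",
    "ExclusionRateWarning",
    "read_dataset",
    "write_dataset",
    "filter_population",
    "read_external_tables",
    "STATISTICS",
    "EXCLUSION_REASONS",
]

#: Summary statistics a series may carry (see :mod:`lifesignal.imaging`).
STATISTICS = ("mean", "max", "p95", "p99", "mean_over_p99")

#: Admissible manual-exclusion reasons.
EXCLUSION_REASONS = ("offspring", "larval_arrest", "device_failure", "none")

MEASUREMENT_COLUMNS = ("animal_id", "replicate_id", "reporter", "statistic", "age_h", "value")
ANNOTATION_COLUMNS = (
    "animal_id",
    "replicate_id",
    "hatch_age_h",
    "first_egg_age_h",
    "death_age_h",
    "excluded",
    "exclusion_reason",
)


class SchemaError(ValueError):
    """A file's columns do not match the documented schema."""


class IntegrityError(ValueError):
    """A measurement references an animal missing from the annotations."""


class ValidationError(ValueError):
    """A record violates a dataset invariant (names the offending animal)."""


class ExclusionRateWarning(UserWarning):
    """More than 10% of the population was excluded by a filtering policy."""


@dataclass
class Dataset:
    """A validated cohort: annotations plus long-format measurements.

    Attributes
    ----------
    animals : pandas.DataFrame
        One row per animal (columns of ``annotations.tsv``).  A derived
        ``lifespan_h`` column (``death_age_h - hatch_age_h``) is added on
        validation.
    measurements : pandas.DataFrame
        Long-format expression observations (columns of ``measurements.tsv``).
    provenance : str
        Free-text description of where the data came from.
    """

    animals: pd.DataFrame
    measurements: pd.DataFrame
    provenance: str = ""

    def __post_init__(self) -> None:
        self.validate()

    # -- accessors -------------------------------------------------------

    def series(self, animal_id, reporter: str, statistic: str) -> pd.DataFrame:
        """Return one animal's (age_h, value) observations, age-ordered."""
        m = self.measurements
        sel = m[
            (m["animal_id"] == animal_id)
            & (m["reporter"] == reporter)
            & (m["statistic"] == statistic)
        ]
        return sel[["age_h", "value"]].reset_index(drop=True)

    @property
    def reporters(self) -> list[str]:
        return sorted(self.measurements["reporter"].unique())

    @property
    def n_animals(self) -> int:
        return len(self.animals)

    def included(self) -> "Dataset":
        """Drop animals carrying a manual exclusion flag."""
        keep = self.animals.loc[~self.animals["excluded"].astype(bool), "animal_id"]
        return self.subset(keep)

    def subset(self, animal_ids) -> "Dataset":
        ids = pd.Index(animal_ids)
        animals = self.animals[self.animals["animal_id"].isin(ids)].reset_index(drop=True)
        meas = self.measurements[self.measurements["animal_id"].isin(ids)].reset_index(drop=True)
        return Dataset(animals, meas, self.provenance)

    # -- validation ------------------------------------------------------

    def validate(self) -> None:
        a, m = self.animals, self.measurements
        _check_columns(a, ANNOTATION_COLUMNS, allow_extra=("lifespan_h",), path="annotations")
        _check_columns(m, MEASUREMENT_COLUMNS, allow_extra=(), path="measurements")

        if a["animal_id"].duplicated().any():
            dup = a.loc[a["animal_id"].duplicated(), "animal_id"].iloc[0]
            raise ValidationError(f"duplicate animal_id {dup!r} in annotations")

        bad_life = a["death_age_h"] <= a["hatch_age_h"]
        if bad_life.any():
            aid = a.loc[bad_life, "animal_id"].iloc[0]
            raise ValidationError(f"animal {aid!r}: death_age_h <= hatch_age_h")
        self.animals = a = a.assign(lifespan_h=a["death_age_h"] - a["hatch_age_h"])

        bad_reason = ~a["exclusion_reason"].isin(EXCLUSION_REASONS)
        if bad_reason.any():
            aid = a.loc[bad_reason, "animal_id"].iloc[0]
            raise ValidationError(f"animal {aid!r}: unknown exclusion_reason")
        flagged = a["excluded"].astype(bool) & (a["exclusion_reason"] == "none")
        if flagged.any():
            aid = a.loc[flagged, "animal_id"].iloc[0]
            raise ValidationError(f"animal {aid!r}: excluded without a reason")

        if len(m) == 0:
            return
        if not m["statistic"].isin(STATISTICS).all():
            bad = m.loc[~m["statistic"].isin(STATISTICS), "statistic"].iloc[0]
            raise ValidationError(f"unknown summary statistic {bad!r}")
        unknown = ~m["animal_id"].isin(a["animal_id"])
        if unknown.any():
            aid = m.loc[unknown, "animal_id"].iloc[0]
            raise IntegrityError(f"measurement references unknown animal {aid!r}")
        if not np.isfinite(m["value"].to_numpy(dtype=float)).all():
            raise ValidationError("non-finite measurement value")

        death = a.set_index("animal_id")["death_age_h"]
        over = m["age_h"].to_numpy() > death.loc[m["animal_id"]].to_numpy()
        if over.any():
            aid = m.loc[over, "animal_id"].iloc[0]
            raise ValidationError(f"animal {aid!r}: observation after death_age_h")

        # ages strictly increasing within each (animal, reporter, statistic)
        key = ["animal_id", "reporter", "statistic"]
        grouped = m.sort_index().groupby(key, sort=False)["age_h"]
        diffs = grouped.diff()
        noninc = diffs <= 0
        if noninc.any():
            aid = m.loc[noninc, "animal_id"].iloc[0]
            raise ValidationError(f"animal {aid!r}: ages not strictly increasing")


def _check_columns(df: pd.DataFrame, expected, allow_extra, path: str) -> None:
    expected = set(expected) | set(allow_extra)
    for col in df.columns:
        if col not in expected:
            raise SchemaError(f"{path}: unknown column {col!r}")
    missing = set(expected) - set(allow_extra) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing column {sorted(missing)[0]!r}")


# -- file round trip -----------------------------------------------------


def read_dataset(measurements_path, annotations_path, provenance: str | None = None) -> Dataset:
    """Read and validate a cohort from its two TSV files.

    Raises :class:`SchemaError` on unexpected columns,
    :class:`IntegrityError` when measurements reference unannotated animals
    and :class:`ValidationError` on invariant violations (naming the animal).
    """
    meas = pd.read_csv(
        measurements_path, sep="\t", encoding="utf-8", float_precision="round_trip"
    )
    ann = pd.read_csv(
        annotations_path, sep="\t", encoding="utf-8", float_precision="round_trip"
    )
    if "excluded" in ann.columns:
        ann["excluded"] = ann["excluded"].astype(bool)
    if "exclusion_reason" in ann.columns:
        ann["exclusion_reason"] = ann["exclusion_reason"].fillna("none").astype(str)
    if "first_egg_age_h" in ann.columns:
        ann["first_egg_age_h"] = pd.to_numeric(ann["first_egg_age_h"], errors="coerce")
    if provenance is None:
        provenance = f"read from {measurements_path} / {annotations_path}"
    return Dataset(ann, meas, provenance)


def write_dataset(dataset: Dataset, measurements_path, annotations_path) -> None:
    """Serialize a cohort to TSV with full double precision (repr round trip)."""
    ann = dataset.animals.drop(columns=["lifespan_h"], errors="ignore").copy()
    ann["excluded"] = ann["excluded"].astype(bool)
    ann.to_csv(annotations_path, sep="\t", index=False, encoding="utf-8", float_format="%.17g")
    dataset.measurements.to_csv(
        measurements_path, sep="\t", index=False, encoding="utf-8", float_format="%.17g"
    )


# -- population filtering ------------------------------------------------


@dataclass
class ExclusionPolicy:
    """How to subset a population before a windowed analysis.

    ``window=(start_h, end_h)`` drops animals that do not survive past the
    window's end (``death_age_h <= end_h``), the standard censoring rule for
    windowed regressions.  ``apply_flags`` additionally drops animals
    carrying a manual exclusion flag (offspring, larval arrest, device
    failure); it defaults to True.
    """

    window: tuple[float, float] | None = None
    apply_flags: bool = True


def filter_population(dataset: Dataset, policy: ExclusionPolicy) -> tuple[Dataset, dict]:
    """Apply an exclusion policy; return the retained subset and a report.

    The report counts exclusions per reason and carries the overall excluded
    fraction.  A :class:`ExclusionRateWarning` is emitted when more than 10%
    of the population is excluded — analysis windows are normally chosen so
    that at most 10% of animals fail to survive them.
    """
    a = dataset.animals
    reasons = pd.Series("kept", index=a.index, dtype=object)
    if policy.apply_flags:
        flagged = a["excluded"].astype(bool)
        reasons[flagged] = a.loc[flagged, "exclusion_reason"]
    if policy.window is not None:
        start, end = policy.window
        if end <= start:
            raise ValueError("exclusion window end must exceed start")
        died = (a["death_age_h"] <= end) & (reasons == "kept")
        reasons[died] = "died_in_window"

    kept_ids = a.loc[reasons == "kept", "animal_id"]
    counts = reasons[reasons != "kept"].value_counts().to_dict()
    n_total = len(a)
    n_excluded = int(n_total - len(kept_ids))
    frac = n_excluded / n_total if n_total else 0.0
    report = {
        "n_total": n_total,
        "n_excluded": n_excluded,
        "fraction_excluded": frac,
        "by_reason": counts,
        "policy": policy,
    }
    if frac > 0.10:
        warnings.warn(
            f"{frac:.1%} of the population excluded (>10%); "
            "consider a different analysis window",
            ExclusionRateWarning,
            stacklevel=2,
        )
    return dataset.subset(kept_ids), report


# -- import adapter ------------------------------------------------------


def read_external_tables(
    measurements_path,
    annotations_path,
    measurement_columns: dict[str, str],
    annotation_columns: dict[str, str],
    sep: str = "\t",
    provenance: str = "external import",
) -> Dataset:
    """Adapter for externally produced per-animal text files.

    Published per-animal source-data files use their own column headers;
    this adapter renames them onto the schema above.  ``measurement_columns``
    and ``annotation_columns`` map *external* column names to the schema
    names, e.g.::

        read_external_tables(
            "sdata_measures.tsv", "sdata_annotations.tsv",
            measurement_columns={
                "worm": "animal_id", "experiment": "replicate_id",
                "strain": "reporter", "measure": "statistic",
                "timepoint_hours": "age_h", "intensity": "value",
            },
            annotation_columns={
                "worm": "animal_id", "experiment": "replicate_id",
                "hatch": "hatch_age_h", "first_egg": "first_egg_age_h",
                "death": "death_age_h", "exclude": "excluded",
                "reason": "exclusion_reason",
            },
        )

    The mapping is left to the user because external layouts vary; columns
    absent from a mapping's values are filled with schema defaults
    (``excluded=False``, ``exclusion_reason='none'``, missing first-egg age).
    """
    meas = pd.read_csv(
        measurements_path, sep=sep, encoding="utf-8", float_precision="round_trip"
    )
    ann = pd.read_csv(
        annotations_path, sep=sep, encoding="utf-8", float_precision="round_trip"
    )
    meas = meas.rename(columns=measurement_columns)[list(MEASUREMENT_COLUMNS)]
    ann = ann.rename(columns=annotation_columns)
    if "excluded" not in ann.columns:
        ann["excluded"] = False
    if "exclusion_reason" not in ann.columns:
        ann["exclusion_reason"] = "none"
    if "first_egg_age_h" not in ann.columns:
        ann["first_egg_age_h"] = np.nan
    ann = ann[list(ANNOTATION_COLUMNS)]
    ann["excluded"] = ann["excluded"].astype(bool)
    return Dataset(ann, meas, provenance)
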