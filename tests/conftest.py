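"""Shared fixtures: tiny hand-built datasets and session-scoped cohorts."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from lifesignal.io import Dataset
from lifesignal.simulate import SimulationConfig, simulate_cohort

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


def make_dataset(animals_rows, measurement_rows, provenance="test fixture"):
    animals = pd.DataFrame(
        animals_rows,
        columns=[
            "animal_id",
            "replicate_id",
            "hatch_age_h",
            "first_egg_age_h",
            "death_age_h",
            "excluded",
            "exclusion_reason",
        ],
    )
    measurements = pd.DataFrame(
        measurement_rows,
        columns=["animal_id", "replicate_id", "reporter", "statistic", "age_h", "value"],
    )
    return Dataset(animals, measurements, provenance)


def flat_series(animal_id, replicate_id, ages, values, reporter="gfp", statistic="mean"):
    return [
        (animal_id, replicate_id, reporter, statistic, float(a), float(v))
        for a, v in zip(ages, values)
    ]


@pytest.fixture()
def tiny_dataset():
    """Two animals x 10 timepoints, one reporter."""
    ages = np.arange(0, 40, 4.0)
    rows = flat_series("a1", 1, ages, 1.0 + 0.1 * ages) + flat_series(
        "a2", 1, ages, 2.0 - 0.02 * ages
    )
    animals = [
        ("a1", 1, 0.0, 60.0, 200.0, False, "none"),
        ("a2", 1, 0.0, 58.0, 180.0, False, "none"),
    ]
    return make_dataset(animals, rows)


@pytest.fixture(scope="session")
def default_cohort():
    """A mid-size latent-coupled cohort shared by read-only tests."""
    return simulate_cohort(SimulationConfig(n_individuals=400, seed=11))


@pytest.fixture(scope="session")
def decoupled_cohort():
    """Same structure but with expression carrying no lifespan information."""
    from lifesignal.simulate import ReporterSpec

    cfg = SimulationConfig(
        n_individuals=400,
        seed=12,
        lifespan_coupling=(("X", 0.0),),
        reporters=(("gfp", ReporterSpec(level_loading=0.25, slope_loading=0.002)),),
    )
    return simulate_cohort(cfg)
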