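"""Shared fixtures: small synthetic worlds and fitted models.

Session-scoped fixtures keep the expensive objects (worlds, MCMC fits)
shared across test modules; every fixture is seeded so the suite is fully
deterministic.
"""

from __future__ import annotations

import zlib

import numpy as np
import pandas as pd
import pytest

from youthmort.b3 import B3Config, BiasReductionSplineModel
from youthmort.completeness import adjust_vr_series, ggb_fit
from youthmort.screen import fit_logquad, screen_surveys
from youthmort.synthetic import (
    World,
    logquad_reference_pairs,
    make_world,
    stable_population_inputs,
)


def prepare_observations(world: World, seed: int) -> pd.DataFrame:
    """Completeness-adjust and quality-screen a world's observation table."""
    obs = world.observations.copy()
    for country, c_true in world.vr_completeness.items():
        if c_true >= 1.0:
            continue
        census1, census2, deaths = stable_population_inputs(
            true_completeness=c_true,
            seed=seed + zlib.crc32(country.encode()) % 10_000,
        )
        est = ggb_fit(census1, census2, deaths)
        mask = obs["country"] == country
        obs.loc[mask, obs.columns] = adjust_vr_series(obs[mask], est).values
    screen = fit_logquad(logquad_reference_pairs(seed=seed + 5))
    obs, _ = screen_surveys(obs, screen, world.survey_pairs)
    return obs


@pytest.fixture(scope="session")
def small_world() -> World:
    return make_world(n_countries=6, n_regions=2, seed=3)


@pytest.fixture(scope="session")
def small_obs(small_world) -> pd.DataFrame:
    return prepare_observations(small_world, seed=3)


@pytest.fixture(scope="session")
def small_model(small_obs) -> BiasReductionSplineModel:
    cfg = B3Config(chains=2, warmup=200, samples=250, seed=17, projection_year=2022.0)
    model = BiasReductionSplineModel(cfg)
    model.fit(small_obs)
    return model


@pytest.fixture(scope="session")
def vr_only_obs() -> pd.DataFrame:
    """Dense, precise complete-VR observations on an exactly linear trend."""
    years = np.arange(1990.5, 2013.5)
    logq = -4.2 - 0.015 * (years - 2000.0)
    return pd.DataFrame(
        {
            "country": "L",
            "series_id": "L-vr",
            "source_type": "vr_complete",
            "ref_time": years,
            "collection_time": years,
            "age_start": 15,
            "age_width": 10,
            "q": np.exp(logq),
            "se_logq": 0.01,
            "excluded": False,
            "exclusion_reason": "",
        }
    )
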