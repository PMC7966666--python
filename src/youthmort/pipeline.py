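"""End-to-end pipeline: simulate, adjust, screen, fit, split, aggregate, validate.

Stages run in dependency order, each consuming the previous stage's output;
every run is a pure function of (configuration, seed) and the run log
records counts entering and leaving each stage.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as ymio
from .agesplit import RatioSplineSplitter, apply_split, ratio_observations
from .aggregate import aggregate, headline_tables
from .b3 import B3Config, B3Posterior, BiasReductionSplineModel, summarize
from .completeness import adjust_vr_series, ggb_fit
from .screen import fit_logquad, screen_surveys
from .sparse import MixedEffectsLogLog, predict_sparse, training_pairs_from_posteriors
from .synthetic import make_world, stable_population_inputs
from .validation import evaluate, make_training_set

__all__ = ["RunConfig", "run_pipeline", "fit_all_countries"]

_ALL_STAGES = (
    "simulate",
    "completeness",
    "screen",
    "fit",
    "split",
    "aggregate",
    "validate",
)


@dataclass
class RunConfig:
    """Configuration for one reproducible pipeline run."""

    seed: int
    outdir: str
    stages: tuple[str, ...] = _ALL_STAGES
    n_countries: int = 10
    n_regions: int = 3
    years: tuple[int, int] = (1985, 2019)
    cutoff_year: float = 2013.0
    screen_level: float = 0.95
    report_years: tuple[int, ...] = (1990, 2000, 2019)
    chains: int = 2
    warmup: int = 300
    samples: int = 300
    projection_year: float = 2022.0

    def b3_config(self, seed_offset: int = 0) -> B3Config:
        return B3Config(
            chains=self.chains,
            warmup=self.warmup,
            samples=self.samples,
            seed=self.seed + seed_offset,
            projection_year=self.projection_year,
        )

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def fit_all_countries(
    observations: pd.DataFrame,
    config: B3Config,
    u5mr: pd.DataFrame | None = None,
    region_map: pd.DataFrame | None = None,
) -> tuple[dict[str, B3Posterior], BiasReductionSplineModel]:
    """Fit the spline model where data allow and the fallback elsewhere.

    Data-rich countries get the full Bayesian fit; sparse countries are
    predicted from their U5MR series through the mixed-effects regression
    trained on the rich countries' posterior medians.  Returns one
    posterior per country in a shared format plus the fitted spline model.
    """
    model = BiasReductionSplineModel(config)
    model.fit(observations)
    posteriors = dict(model.posteriors_)
    if model.sparse_countries_ and u5mr is not None and region_map is not None:
        pairs = training_pairs_from_posteriors(posteriors, u5mr, region_map)
        mixed = MixedEffectsLogLog()
        mixed.fit(pairs)
        regions = dict(zip(region_map["country"], region_map["region"]))
        years = model.years_grid_
        for country in model.sparse_countries_:
            series = u5mr[u5mr["country"] == country]
            series = series[series["year"].isin(years.astype(int))]
            posteriors[country] = predict_sparse(
                series[["year", "u5mr"]],
                regions.get(country, "?"),
                mixed.fit_,
                country=country,
                n_draws=len(next(iter(posteriors.values())).draws),
                seed=config.seed + 977,
            )
    return posteriors, model


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages and write artifacts under ``outdir``.

    Returns the run log (stage counts, convergence summary, file list), also
    written to ``run_summary.json``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = set(config.stages)
    unknown = stages - set(_ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    log: dict = {"seed": config.seed, "config_hash": config.config_hash(), "stages": {}}

    if "simulate" not in stages:
        raise ValueError("this pipeline runs on simulated worlds: stage 'simulate' is required")
    world = make_world(
        n_countries=config.n_countries,
        n_regions=config.n_regions,
        years=config.years,
        seed=config.seed,
    )
    obs = world.observations.copy()
    truth = world.truth_frame()
    ymio.write_observations(obs, outdir / "observations.csv")
    truth.to_csv(outdir / "truth.csv", index=False)
    world.population.to_csv(outdir / "population.csv", index=False)
    world.region_map.to_csv(outdir / "region_map.csv", index=False)
    log["stages"]["simulate"] = {
        "countries": config.n_countries,
        "observations": len(obs),
    }

    if "completeness" in stages:
        n_adj = 0
        for country, c_true in world.vr_completeness.items():
            if c_true >= 1.0:
                continue
            import zlib

            census1, census2, deaths = stable_population_inputs(
                true_completeness=c_true,
                seed=config.seed + zlib.crc32(country.encode()) % 10_000,
            )
            est = ggb_fit(census1, census2, deaths)
            mask = obs["country"] == country
            obs.loc[mask, obs.columns] = adjust_vr_series(obs[mask], est).values
            n_adj += 1
        log["stages"]["completeness"] = {"countries_adjusted": n_adj}

    if "screen" in stages:
        from .synthetic import logquad_reference_pairs

        ref = logquad_reference_pairs(seed=config.seed + 5)
        scr = fit_logquad(ref, level=config.screen_level)
        obs, report = screen_surveys(obs, scr, world.survey_pairs, config.screen_level)
        report.to_csv(outdir / "screen_report.csv", index=False)
        log["stages"]["screen"] = {
            "series_screened": len(report),
            "series_excluded": int((report["decision"] == "excluded").sum()),
        }

    posteriors: dict[str, B3Posterior] = {}
    model = None
    if "fit" in stages:
        u5mr = truth.rename(columns={"q5_0_true": "u5mr"})[["country", "year", "u5mr"]]
        posteriors, model = fit_all_countries(
            obs, config.b3_config(), u5mr, world.region_map
        )
        ymio.write_posterior_store(posteriors, outdir / "posterior_store.csv")
        summaries = pd.concat(
            [summarize(p) for p in posteriors.values()], ignore_index=True
        )
        ymio.write_summaries(summaries, outdir / "summaries.csv")
        log["stages"]["fit"] = {
            "b3_countries": len(model.posteriors_),
            "sparse_countries": len(model.sparse_countries_),
            "converged": all(
                p.convergence.get("converged", True) for p in model.posteriors_.values()
            ),
        }

    splits = {}
    if "split" in stages:
        if not posteriors:
            raise ValueError("stage 'split' needs stage 'fit' output")
        years_grid = next(iter(posteriors.values())).years
        for country, post in posteriors.items():
            sub = world.obs_5q15[world.obs_5q15["country"] == country]
            splitter = RatioSplineSplitter()
            robs = ratio_observations(sub, post) if len(sub) else sub
            if len(sub) == 0:
                continue
            splitter.fit(robs, years_grid, country)
            splits[country] = apply_split(post, splitter.fit_)
        split_rows = []
        for country, sp in splits.items():
            for name in ("q15_19", "q20_24"):
                arr = getattr(sp, name)
                lo, med, hi = np.percentile(arr, [5, 50, 95], axis=0)
                for j, y in enumerate(sp.years):
                    split_rows.append((country, int(y), name, med[j], lo[j], hi[j]))
        pd.DataFrame(
            split_rows, columns=["country", "year", "band", "median", "ui_lower", "ui_upper"]
        ).to_csv(outdir / "split_summaries.csv", index=False)
        log["stages"]["split"] = {"countries": len(splits)}

    if "aggregate" in stages:
        if not splits:
            raise ValueError("stage 'aggregate' needs stage 'split' output")
        # restrict to the in-truth year range where populations exist
        y0, y1 = config.years
        for country in list(splits.keys()):
            sp = splits[country]
            keep = (sp.years >= y0) & (sp.years <= y1)
            sp.years = sp.years[keep]
            sp.q15_19 = sp.q15_19[:, keep]
            sp.q20_24 = sp.q20_24[:, keep]
            sp.q15_24 = sp.q15_24[:, keep]
        region_map = world.region_map[world.region_map["country"].isin(splits)]
        tables, q_draws = aggregate(splits, world.population, region_map)
        t1, t2 = headline_tables(tables, q_draws, config.report_years)
        t1.to_csv(outdir / "table_probabilities.csv", index=False)
        t2.to_csv(outdir / "table_deaths.csv", index=False)
        log["stages"]["aggregate"] = {"units": len(q_draws)}

    if "validate" in stages:
        training, leftout = make_training_set(obs, config.cutoff_year)
        vmodel = BiasReductionSplineModel(config.b3_config(seed_offset=71))
        vmodel.fit(training)
        report = evaluate(vmodel, leftout, seed=config.seed + 13)
        report.records.to_csv(outdir / "validation_records.csv", index=False)
        summary = report.to_dict()
        summary["cutoff_year"] = config.cutoff_year
        (outdir / "validation_summary.json").write_text(
            json.dumps(summary, indent=2, default=float)
        )
        log["stages"]["validate"] = {
            "n_training": len(training),
            "n_leftout": report.n_leftout,
            "median_error": report.median_error,
            "median_abs_error": report.median_abs_error,
            "coverage90": report.coverage90,
        }

    (outdir / "run_summary.json").write_text(json.dumps(log, indent=2, default=float))
    return log
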