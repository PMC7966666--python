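"""Synthetic multi-country world with known youth-mortality truth.

Real youth-mortality databases mix vital registration of varying
completeness, retrospective sibling-survival histories with recall bias that
grows with the length of the recall period, and census household-death
reports with underreporting.  This module generates a world with all of
those error structures and a known latent truth, so every estimation stage
can be validated against ground truth without external data.

Everything here is a pure function of (parameters, seed): two calls with the
same arguments return identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .lifetable import OBSERVATION_COLUMNS, m_to_q, q_to_m

__all__ = [
    "TrendParams",
    "BiasParams",
    "TrueTrajectory",
    "CrisisEvent",
    "World",
    "generate_truth",
    "generate_population",
    "simulate_vr",
    "simulate_sibling_survey",
    "simulate_census",
    "simulate_q15_19",
    "apply_crisis",
    "make_world",
    "stable_population_inputs",
    "logquad_reference_pairs",
]

_LOGQ_MIN, _LOGQ_MAX = math.log(2e-4), math.log(0.45)


@dataclass(frozen=True)
class TrendParams:
    """Controls for the latent mortality trajectories.

    Levels and slopes are on the log ``10q15`` scale.  Defaults give a world
    whose median ``10q15`` sits near 15 per 1000 around 2000 and declines at
    roughly 1.5% per year, with smooth country-specific departures from
    log-linearity produced by an integrated random walk.
    """

    level_mean: float = math.log(0.014)
    region_level_sd: float = 0.45
    country_level_sd: float = 0.30
    slope_mean: float = -0.015
    slope_sd: float = 0.008
    irw_sd: float = 0.002  # innovation SD of the integrated random walk, per year
    # logit of the ratio 5q15 / 10q15
    ratio_logit_mean: float = -0.20  # r around 0.45
    ratio_logit_sd: float = 0.15
    ratio_slope_mean: float = -0.002
    ratio_slope_sd: float = 0.002
    ratio_bounds: tuple[float, float] = (0.2, 0.8)
    # log-linear link from log 10q15 to log 5q0, plus country noise, giving
    # the in-world reference relation used by the quality screen
    link_intercept: float = 0.90
    link_slope: float = 0.95
    link_quad: float = 0.0
    link_country_sd: float = 0.15
    link_year_sd: float = 0.02


@dataclass(frozen=True)
class BiasParams:
    """Error-structure controls for the simulated data sources.

    ``sibling_slope_mean`` is the mean per-year-of-recall multiplicative bias
    on the log scale: a value of -0.01 means a survey underestimates
    mortality 10 years back by about 10% on average, emulating progressive
    omission of deceased siblings.
    """

    sibling_level_bias_sd: float = 0.10
    sibling_slope_mean: float = -0.010
    sibling_slope_sd: float = 0.010
    census_underreport_factor: float = 0.95
    vr_completeness_range: tuple[float, float] = (0.60, 1.00)
    nonsampling_sd_by_source: dict = field(
        default_factory=lambda: {
            "vr_complete": 0.0,
            "vr_incomplete": 0.02,
            "srs": 0.025,
            "sibling": 0.05,
            "census": 0.05,
        }
    )
    design_effect: float = 1.5

    def __post_init__(self) -> None:
        if not 0 < self.census_underreport_factor <= 1:
            raise ValueError("census_underreport_factor must be in (0, 1]")
        lo, hi = self.vr_completeness_range
        if not (0 < lo <= hi <= 1):
            raise ValueError("vr_completeness_range must be within (0, 1]")


@dataclass
class TrueTrajectory:
    """Ground-truth mortality path for one synthetic country."""

    country: str
    region: str
    years: np.ndarray
    logq15_24: np.ndarray
    ratio_r: np.ndarray  # true 5q15 / 10q15 per year
    logq5_0: np.ndarray
    crisis_years: set = field(default_factory=set)

    @property
    def q15_24(self) -> np.ndarray:
        return np.exp(self.logq15_24)

    @property
    def q15_19(self) -> np.ndarray:
        return self.ratio_r * self.q15_24

    def q_at(self, t: float | np.ndarray) -> np.ndarray:
        """Linear interpolation of 10q15 at decimal time t."""
        return np.interp(t, self.years, self.q15_24)

    def q5_at(self, t: float | np.ndarray) -> np.ndarray:
        return np.interp(t, self.years, np.exp(self.logq5_0))


@dataclass(frozen=True)
class CrisisEvent:
    """Excess deaths in one country-year-band from conflict/disaster/epidemic."""

    country: str
    year: int
    age_start: int
    age_width: int
    excess_deaths: float

    def __post_init__(self) -> None:
        if self.excess_deaths < 0:
            raise ValueError("excess_deaths must be non-negative")


def generate_truth(
    n_countries: int = 20,
    n_regions: int = 4,
    years: tuple[int, int] = (1985, 2019),
    seed: int = 0,
    trend_params: TrendParams | None = None,
) -> list[TrueTrajectory]:
    """Draw latent mortality trajectories for a synthetic world.

    Each country's log ``10q15`` path is a regional intercept plus a country
    intercept, a country-specific linear slope, and an integrated random walk
    (a smooth, twice-summed Gaussian deviation).  ``log 5q0`` follows the
    configured log-quadratic link plus country noise so the quality screen's
    reference relation exists in-world.
    """
    if n_countries < 1 or n_regions < 1 or n_regions > n_countries:
        raise ValueError("need n_countries >= n_regions >= 1")
    y0, y1 = years
    if y1 <= y0:
        raise ValueError("years must be an increasing range")
    p = trend_params or TrendParams()
    rng = np.random.default_rng(seed)
    yr = np.arange(y0, y1 + 1)
    t = yr - yr.mean()
    region_levels = rng.normal(p.level_mean, p.region_level_sd, n_regions)

    lo_logit = math.log(p.ratio_bounds[0] / (1 - p.ratio_bounds[0]))
    hi_logit = math.log(p.ratio_bounds[1] / (1 - p.ratio_bounds[1]))

    out: list[TrueTrajectory] = []
    for i in range(n_countries):
        ridx = i % n_regions
        level = region_levels[ridx] + rng.normal(0.0, p.country_level_sd)
        slope = rng.normal(p.slope_mean, p.slope_sd)
        # smooth deviation from log-linearity: an integrated random walk with
        # zero initial level and velocity, so the path is locally linear with
        # second differences of SD irw_sd — the same process family the
        # estimation model's penalty encodes
        innov = rng.normal(0.0, p.irw_sd, len(yr))
        irw = np.cumsum(np.cumsum(innov))
        logq = np.clip(level + slope * t + irw, _LOGQ_MIN, _LOGQ_MAX)

        rlogit = (
            rng.normal(p.ratio_logit_mean, p.ratio_logit_sd)
            + rng.normal(p.ratio_slope_mean, p.ratio_slope_sd) * t
        )
        ratio = 1.0 / (1.0 + np.exp(-np.clip(rlogit, lo_logit, hi_logit)))

        cnoise = rng.normal(0.0, p.link_country_sd)
        logq5 = (
            p.link_intercept
            + p.link_slope * logq
            + p.link_quad * logq**2
            + cnoise
            + rng.normal(0.0, p.link_year_sd, len(yr))
        )
        logq5 = np.clip(logq5, _LOGQ_MIN, _LOGQ_MAX)

        out.append(
            TrueTrajectory(
                country=f"C{i + 1:03d}",
                region=f"R{ridx + 1}",
                years=yr,
                logq15_24=logq,
                ratio_r=ratio,
                logq5_0=logq5,
            )
        )
    return out


def generate_population(
    trajectories: list[TrueTrajectory],
    seed: int = 0,
    base_mean: float = 1.0e6,
    growth_mean: float = 0.010,
    growth_sd: float = 0.005,
) -> pd.DataFrame:
    """Smooth, positive person-years by country-year for bands 15-19 and 20-24.

    Base sizes are lognormal across countries; each country grows (or
    shrinks) exponentially at its own smooth rate, emulating cohort flow
    without explicit population reconstruction.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for traj in trajectories:
        base = base_mean * rng.lognormal(0.0, 0.7)
        g = rng.normal(growth_mean, growth_sd)
        frac_young = rng.uniform(0.48, 0.55)  # slight excess of 15-19 over 20-24
        for year in traj.years:
            tot = base * math.exp(g * (year - traj.years[0]))
            rows.append((traj.country, int(year), 15, 5, frac_young * tot))
            rows.append((traj.country, int(year), 20, 5, (1 - frac_young) * tot))
    return pd.DataFrame(
        rows, columns=["country", "year", "age_start", "age_width", "person_years"]
    )


def _empty_observations() -> pd.DataFrame:
    return pd.DataFrame(columns=OBSERVATION_COLUMNS)


def _band_person_years(pop: pd.DataFrame, country: str, year: int) -> float:
    sel = pop[(pop["country"] == country) & (pop["year"] == year)]
    return float(sel["person_years"].sum())


def simulate_vr(
    traj: TrueTrajectory,
    pop: pd.DataFrame,
    completeness: float | dict[int, float] = 1.0,
    seed: int = 0,
    years: np.ndarray | None = None,
) -> pd.DataFrame:
    """Simulate annual vital-registration observations of 10q15.

    True deaths are binomial given the hazard-implied annual death
    probability; registered deaths are a binomial thinning of true deaths at
    the registration completeness.  The observed q is computed from
    registered deaths *as if* registration were complete, so incomplete VR is
    biased low by roughly the completeness factor — exactly the defect the
    completeness-adjustment stage corrects.
    """
    rng = np.random.default_rng(seed)
    years = traj.years if years is None else np.asarray(years)
    rows = []
    for year in years:
        py = _band_person_years(pop, traj.country, int(year))
        if py <= 0:
            continue
        c = completeness[int(year)] if isinstance(completeness, dict) else completeness
        if not 0 < c <= 1:
            raise ValueError("completeness must be in (0, 1]")
        q = float(np.interp(year + 0.5, traj.years, traj.q15_24))  # mid-year, matches ref_time
        m = q_to_m(q, 10.0)
        p_annual = 1.0 - math.exp(-m)
        n = int(round(py))
        true_deaths = rng.binomial(n, p_annual)
        reg = rng.binomial(true_deaths, c) if c < 1 else true_deaths
        if reg == 0:
            continue
        q_obs = m_to_q(reg / py, 10.0)
        se = math.sqrt(1.0 / reg)  # Poisson approximation on the log scale
        source = "vr_complete" if c == 1.0 else "vr_incomplete"
        rows.append(
            (
                traj.country,
                f"{traj.country}-vr",
                source,
                year + 0.5,
                year + 0.5,
                15,
                10,
                q_obs,
                max(se, 0.005),
                False,
                "",
            )
        )
    return pd.DataFrame(rows, columns=OBSERVATION_COLUMNS) if rows else _empty_observations()


def simulate_sibling_survey(
    traj: TrueTrajectory,
    survey_year: float,
    bias: BiasParams | None = None,
    effective_exposure: float = 150_000.0,
    seed: int = 0,
    window_width: float = 5.0,
    recall_horizon: float = 15.0,
    with_under5: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one sibling-history survey series of 10q15 observations.

    One observation per retrospective window (default three 5-year windows
    covering the 15 years before the field date).  On the log scale each
    observation is the truth at the window midpoint plus a survey-level bias
    ``b0 + b1 * lag`` (lag = survey date minus window midpoint) plus sampling
    and non-sampling noise.  Returns the observations and a one-row table
    with the survey's paired under-5 summary (from its birth histories),
    which the quality screen consumes.
    """
    bias = bias or BiasParams()
    rng = np.random.default_rng(seed)
    if survey_year > traj.years[-1] + 1:
        raise ValueError("survey_year beyond the trajectory range")
    b0 = rng.normal(0.0, bias.sibling_level_bias_sd)
    b1 = rng.normal(bias.sibling_slope_mean, bias.sibling_slope_sd)
    series_id = f"{traj.country}-sib{int(survey_year)}"
    nonsamp = bias.nonsampling_sd_by_source.get("sibling", 0.0)

    rows = []
    n_windows = int(round(recall_horizon / window_width))
    truncated = False
    for k in range(n_windows):
        end = survey_year - k * window_width
        start = end - window_width
        if end <= traj.years[0]:
            truncated = True
            continue
        start = max(start, float(traj.years[0]))
        mid = 0.5 * (start + end)
        q_true = float(traj.q_at(mid))
        lag = survey_year - mid
        # sampling variance of log q from the death count implied by the
        # sibling exposure, inflated by the design effect
        m = q_to_m(q_true, 10.0)
        se_samp = math.sqrt(bias.design_effect / max(effective_exposure * m, 1.0))
        logq_obs = (
            math.log(q_true)
            + b0
            + b1 * lag
            + rng.normal(0.0, math.hypot(se_samp, nonsamp))
        )
        rows.append(
            (
                traj.country,
                series_id,
                "sibling",
                mid,
                float(survey_year),
                15,
                10,
                float(np.exp(np.clip(logq_obs, _LOGQ_MIN, _LOGQ_MAX))),
                se_samp,
                False,
                "",
            )
        )
    if truncated:
        import warnings

        warnings.warn(
            f"survey {series_id}: recall windows before trajectory start truncated",
            stacklevel=2,
        )
    obs = pd.DataFrame(rows, columns=OBSERVATION_COLUMNS) if rows else _empty_observations()

    pairs = pd.DataFrame(columns=["series_id", "q5_0", "b0_true", "b1_true"])
    if with_under5:
        q5 = float(traj.q5_at(survey_year - 2.5)) * math.exp(rng.normal(0.0, 0.03))
        # record the survey's generating bias so recovery can be scored
        pairs = pd.DataFrame(
            {"series_id": [series_id], "q5_0": [q5], "b0_true": [b0], "b1_true": [b1]}
        )
    return obs, pairs


def simulate_census(
    traj: TrueTrajectory,
    pop: pd.DataFrame,
    census_year: int,
    underreport_factor: float = 0.95,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a census household-deaths observation of 10q15.

    Household deaths in the 12 months before the census are a binomial draw
    from the true hazard, thinned by the underreporting factor; the reported
    q comes from the abridged life-table conversion of the observed rate.
    Also returns the paired under-5 summary for the quality screen.
    """
    if not 0 < underreport_factor <= 1:
        raise ValueError("underreport_factor must be in (0, 1]")
    rng = np.random.default_rng(seed)
    ref = census_year - 0.5
    py = _band_person_years(pop, traj.country, census_year - 1)
    if py <= 0:
        return _empty_observations(), pd.DataFrame(columns=["series_id", "q5_0"])
    q = float(traj.q_at(ref))
    m = q_to_m(q, 10.0)
    true_deaths = rng.binomial(int(round(py)), 1.0 - math.exp(-m))
    reported = rng.binomial(true_deaths, underreport_factor)
    series_id = f"{traj.country}-cen{census_year}"
    if reported == 0:
        return _empty_observations(), pd.DataFrame(columns=["series_id", "q5_0"])
    q_obs = m_to_q(reported / py, 10.0)
    se = math.sqrt(1.0 / reported)
    obs = pd.DataFrame(
        [
            (
                traj.country,
                series_id,
                "census",
                ref,
                float(census_year),
                15,
                10,
                q_obs,
                max(se, 0.01),
                False,
                "",
            )
        ],
        columns=OBSERVATION_COLUMNS,
    )
    q5 = float(traj.q5_at(ref)) * math.exp(rng.normal(0.0, 0.03))
    pairs = pd.DataFrame({"series_id": [series_id], "q5_0": [q5]})
    return obs, pairs


def apply_crisis(
    traj: TrueTrajectory, events: list[CrisisEvent], pop: pd.DataFrame
) -> TrueTrajectory:
    """Superimpose crisis-year excess mortality on a smooth trajectory.

    The excess death count is converted to an excess probability through the
    band person-years and the rate-to-q identity, then combined with the
    smooth q multiplicatively in survival space.  Reapplying a crisis to a
    year already marked raises (the operation is not idempotent).
    """
    logq = traj.logq15_24.copy()
    crisis_years = set(traj.crisis_years)
    for ev in events:
        if ev.country != traj.country:
            continue
        if ev.year not in traj.years:
            raise ValueError(f"crisis year {ev.year} outside trajectory range")
        if ev.year in crisis_years:
            raise ValueError(f"crisis already applied to {traj.country} {ev.year}")
        py = _band_person_years(pop, traj.country, ev.year)
        if ev.excess_deaths > 0.2 * py:
            raise ValueError("excess_deaths exceeds 20% of person-years bound")
        q_ex = m_to_q(ev.excess_deaths / py, float(ev.age_width))
        idx = int(np.where(traj.years == ev.year)[0][0])
        q_new = 1.0 - (1.0 - math.exp(logq[idx])) * (1.0 - q_ex)
        logq[idx] = math.log(q_new)
        crisis_years.add(ev.year)
    return replace(traj, logq15_24=logq, crisis_years=crisis_years)


def simulate_q15_19(
    traj: TrueTrajectory,
    pop: pd.DataFrame,
    seed: int = 0,
    years: np.ndarray | None = None,
    step: int = 3,
) -> pd.DataFrame:
    """Observations of the 15-19 band probability for the age-split database.

    Deaths in the 15-19 band are binomial draws from the hazard implied by
    the true 5q15; the observed q and its log-scale standard error follow
    from the registered count.  Only sampling noise is simulated here: the
    age-split stage consumes the ratio to the (bias-corrected) median 10q15
    estimate, so the aggregate bias signature lives in the 10q15 series.
    """
    rng = np.random.default_rng(seed)
    years = traj.years if years is None else np.asarray(years)
    rows = []
    for year in years[::step]:
        sel = pop[
            (pop["country"] == traj.country)
            & (pop["year"] == int(year))
            & (pop["age_start"] == 15)
        ]
        py = float(sel["person_years"].sum())
        if py <= 0:
            continue
        q = float(np.interp(year + 0.5, traj.years, traj.q15_19))  # mid-year, matches ref_time
        m = q_to_m(q, 5.0)
        deaths = rng.binomial(int(round(py)), 1.0 - math.exp(-m))
        if deaths == 0:
            continue
        q_obs = m_to_q(deaths / py, 5.0)
        rows.append(
            (
                traj.country,
                f"{traj.country}-a15",
                "vr_complete",
                year + 0.5,
                year + 0.5,
                15,
                5,
                q_obs,
                max(math.sqrt(1.0 / deaths), 0.005),
                False,
                "",
            )
        )
    return pd.DataFrame(rows, columns=OBSERVATION_COLUMNS) if rows else _empty_observations()


@dataclass
class World:
    """A fully simulated world: truth plus all observation tables."""

    trajectories: list[TrueTrajectory]
    population: pd.DataFrame
    observations: pd.DataFrame
    obs_5q15: pd.DataFrame  # 15-19 band observations for the age split
    survey_pairs: pd.DataFrame  # series_id -> paired under-5 summary
    region_map: pd.DataFrame  # country, region
    crisis_events: list[CrisisEvent] = field(default_factory=list)
    vr_completeness: dict = field(default_factory=dict)  # country -> true c

    def truth_frame(self) -> pd.DataFrame:
        rows = []
        for tr in self.trajectories:
            for j, year in enumerate(tr.years):
                rows.append(
                    (
                        tr.country,
                        int(year),
                        tr.q15_24[j],
                        tr.q15_19[j],
                        math.exp(tr.logq5_0[j]),
                    )
                )
        return pd.DataFrame(
            rows, columns=["country", "year", "q15_24_true", "q15_19_true", "q5_0_true"]
        )


def make_world(
    n_countries: int = 20,
    n_regions: int = 4,
    years: tuple[int, int] = (1985, 2019),
    seed: int = 0,
    trend_params: TrendParams | None = None,
    bias_params: BiasParams | None = None,
    frac_vr_complete: float = 0.35,
    frac_vr_incomplete: float = 0.25,
    frac_survey_only: float = 0.30,
    n_surveys_per_country: int = 3,
    survey_exposure: float = 150_000.0,
) -> World:
    """Assemble a complete synthetic world with a realistic source mix.

    Countries are assigned one of four data situations: complete VR,
    incomplete VR plus sibling surveys, survey/census only, or sparse (too
    few observations for the spline model, triggering the fallback
    estimator).  Fractions are rounded to whole countries in the listed
    order; the remainder is sparse.
    """
    bias = bias_params or BiasParams()
    trajs = generate_truth(n_countries, n_regions, years, seed, trend_params)
    pop = generate_population(trajs, seed=seed + 1)
    rng = np.random.default_rng(seed + 2)

    n_vrc = int(round(frac_vr_complete * n_countries))
    n_vri = int(round(frac_vr_incomplete * n_countries))
    n_survey = int(round(frac_survey_only * n_countries))

    obs_frames, pair_frames, a15_frames = [], [], []
    completeness_map: dict[str, float] = {}
    y0, y1 = years
    # quinquennial survey programme; with the default years this withholds
    # roughly a quarter of the data under a 2013 collection-date cutoff,
    # emulating the share omitted in the validation design
    survey_years = [y for y in range(y0 + 10, y1 + 1, 5)]

    for i, traj in enumerate(trajs):
        sub = int(rng.integers(0, 2**30 - 1))
        a15_frames.append(simulate_q15_19(traj, pop, seed=sub + 3))
        if i < n_vrc:
            completeness_map[traj.country] = 1.0
            obs_frames.append(simulate_vr(traj, pop, 1.0, seed=sub))
        elif i < n_vrc + n_vri:
            c = float(rng.uniform(*bias.vr_completeness_range))
            completeness_map[traj.country] = c
            obs_frames.append(simulate_vr(traj, pop, c, seed=sub))
            for k, sy in enumerate(survey_years[-n_surveys_per_country:]):
                o, p = simulate_sibling_survey(
                    traj, sy + 0.5, bias, survey_exposure, seed=sub + 11 * (k + 1)
                )
                obs_frames.append(o)
                pair_frames.append(p)
        elif i < n_vrc + n_vri + n_survey:
            for k, sy in enumerate(survey_years[-n_surveys_per_country:]):
                o, p = simulate_sibling_survey(
                    traj, sy + 0.5, bias, survey_exposure, seed=sub + 11 * (k + 1)
                )
                obs_frames.append(o)
                pair_frames.append(p)
            o, p = simulate_census(
                traj, pop, y1 - 4, bias.census_underreport_factor, seed=sub + 101
            )
            obs_frames.append(o)
            pair_frames.append(p)
        else:  # sparse: a single survey
            o, p = simulate_sibling_survey(
                traj,
                survey_years[-1] + 0.5,
                bias,
                survey_exposure,
                seed=sub + 7,
                window_width=5.0,
                recall_horizon=5.0,
            )
            obs_frames.append(o)
            pair_frames.append(p)

    observations = pd.concat(
        [f for f in obs_frames if len(f)], ignore_index=True
    )
    survey_pairs = (
        pd.concat([f for f in pair_frames if len(f)], ignore_index=True)
        if pair_frames
        else pd.DataFrame(columns=["series_id", "q5_0"])
    )
    region_map = pd.DataFrame(
        {"country": [t.country for t in trajs], "region": [t.region for t in trajs]}
    )
    obs_5q15 = pd.concat([f for f in a15_frames if len(f)], ignore_index=True)
    return World(
        trajectories=trajs,
        population=pop,
        observations=observations,
        obs_5q15=obs_5q15,
        survey_pairs=survey_pairs,
        region_map=region_map,
        vr_completeness=completeness_map,
    )


# ---------------------------------------------------------------------------
# Stable-population inputs for the growth-balance completeness method
# ---------------------------------------------------------------------------

def _gompertz_schedule(ages: np.ndarray) -> np.ndarray:
    """A plausible all-age hazard: background + Gompertz senescence + child hump."""
    return 0.0004 + 0.00018 * np.exp(0.075 * ages) + 0.03 * np.exp(-ages / 2.0)


def stable_population_inputs(
    true_completeness: float = 1.0,
    growth: float = 0.02,
    t1: float = 2000.0,
    t2: float = 2010.0,
    open_age: int = 85,
    noise_sd: float = 0.01,
    seed: int = 0,
    base_population: float = 1.0e6,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Two census age distributions and intercensal registered deaths.

    The population is stable with growth rate ``growth`` under a fixed
    Gompertz-like mortality schedule; registered deaths are the true deaths
    thinned by ``true_completeness``.  Multiplicative lognormal noise with SD
    ``noise_sd`` perturbs every reported count.  Returns (census1, census2,
    deaths) tables in the completeness module's CSV schema, with deaths as
    annual averages over the intercensal period.
    """
    if not 0 < true_completeness <= 1:
        raise ValueError("true_completeness must be in (0, 1]")
    rng = np.random.default_rng(seed)
    fine = np.arange(0.0, open_age + 25.0, 0.25)
    haz = _gompertz_schedule(fine)
    # survivorship and stable age density on the fine grid
    surv = np.exp(-np.cumsum(haz) * 0.25)
    dens = np.exp(-growth * fine) * surv
    death_dens = dens * haz

    starts = list(range(0, open_age, 5))
    T = t2 - t1

    def grouped(density: np.ndarray, scale: float) -> np.ndarray:
        out = []
        for s in starts:
            sel = (fine >= s) & (fine < s + 5)
            out.append(scale * np.sum(density[sel]) * 0.25)
        sel = fine >= open_age
        out.append(scale * np.sum(density[sel]) * 0.25)
        return np.asarray(out)

    scale1 = base_population
    scale2 = base_population * math.exp(growth * T)
    scale_mid = base_population * math.exp(growth * T / 2.0)

    n1 = grouped(dens, scale1) * rng.lognormal(0.0, noise_sd, len(starts) + 1)
    n2 = grouped(dens, scale2) * rng.lognormal(0.0, noise_sd, len(starts) + 1)
    d = (
        grouped(death_dens, scale_mid)
        * true_completeness
        * rng.lognormal(0.0, noise_sd, len(starts) + 1)
    )

    widths = [5] * len(starts) + [999]
    all_starts = starts + [open_age]

    def frame(counts: np.ndarray, time: float) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "country": "S",
                "time": time,
                "age_start": all_starts,
                "age_width": widths,
                "count": counts,
            }
        )

    return frame(n1, t1), frame(n2, t2), frame(d, 0.5 * (t1 + t2))


def logquad_reference_pairs(
    n_countries: int = 120, seed: int = 0, trend_params: TrendParams | None = None
) -> pd.DataFrame:
    """Reference (5q0, 10q15) pairs for fitting the quality-screen regression.

    Stands in for an external high-quality reference database: country-years
    sampled from the world's own generating link, so the screen's expected
    pattern matches the in-world relation between under-5 and youth
    mortality.
    """
    trajs = generate_truth(n_countries, max(4, n_countries // 25), seed=seed, trend_params=trend_params)
    rng = np.random.default_rng(seed + 1)
    rows = []
    for tr in trajs:
        years = rng.choice(len(tr.years), size=4, replace=False)
        for j in years:
            rows.append((math.exp(tr.logq5_0[j]), tr.q15_24[j]))
    return pd.DataFrame(rows, columns=["q5_0", "q10_15"])
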