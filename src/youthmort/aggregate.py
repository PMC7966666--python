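"""Death counts, regional aggregation, and headline tables.

Band probabilities are converted to central death rates, multiplied by
person-years to give deaths per draw (population counts carry no
uncertainty), summed over member countries per draw for regions and the
world, and summarised as medians with 90% uncertainty intervals.  Regional
band probabilities come back from the aggregated rates (total deaths over
total exposure), and the regional 10q15 composes the two band
probabilities, so the life-table identities hold at every level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .agesplit import SplitDraws
from .lifetable import annual_rate_of_reduction, report_round

__all__ = [
    "DeathsTable",
    "deaths_from_q",
    "aggregate",
    "share_of_global",
    "headline_tables",
]

_BANDS = ((15, 5, "q15_19"), (20, 5, "q20_24"))


@dataclass
class DeathsTable:
    """Draw-level deaths by unit (country/region/world), year and band."""

    unit: str
    years: np.ndarray
    deaths: dict = field(default_factory=dict)  # band name -> (n_draws, n_years)
    person_years: dict = field(default_factory=dict)  # band name -> (n_years,)

    def total(self) -> np.ndarray:
        return sum(self.deaths.values())

    def summary(self) -> pd.DataFrame:
        rows = []
        bands = list(self.deaths.keys()) + ["total"]
        for band in bands:
            d = self.total() if band == "total" else self.deaths[band]
            lo, med, hi = np.percentile(d, [5, 50, 95], axis=0)
            for j, y in enumerate(self.years):
                rows.append((self.unit, int(y), band, med[j], lo[j], hi[j]))
        return pd.DataFrame(
            rows, columns=["unit", "year", "band", "median", "ui_lower", "ui_upper"]
        )


def _pop_vector(
    population: pd.DataFrame, country: str, years: np.ndarray, age_start: int
) -> np.ndarray:
    sub = population[
        (population["country"] == country) & (population["age_start"] == age_start)
    ]
    py_map = dict(zip(sub["year"], sub["person_years"]))
    missing = [int(y) for y in years if int(y) not in py_map]
    if missing:
        raise ValueError(f"missing population for {country} years {missing}")
    return np.array([py_map[int(y)] for y in years], dtype=float)


def deaths_from_q(split: SplitDraws, population: pd.DataFrame) -> DeathsTable:
    """Per-draw deaths for one country: m(q) times person-years, per band.

    Person-years are mid-year population times one year; no population
    uncertainty is added.
    """
    deaths, pys = {}, {}
    for age_start, width, name in _BANDS:
        py = _pop_vector(population, split.country, split.years, age_start)
        q = getattr(split, name)
        m = q / (width - q * (width / 2.0))  # vectorised q_to_m, a = n/2
        deaths[name] = m * py[None, :]
        pys[name] = py
    return DeathsTable(
        unit=split.country, years=split.years, deaths=deaths, person_years=pys
    )


def aggregate(
    splits: dict[str, SplitDraws],
    population: pd.DataFrame,
    region_map: pd.DataFrame,
) -> tuple[dict[str, DeathsTable], dict[str, dict]]:
    """Aggregate country draws to regions and the world.

    Returns ``(deaths_tables, q_draws)``: deaths tables keyed by country,
    region and "World"; and, for each region and the world, per-draw band
    probabilities recovered from the aggregated rates plus the composed
    10q15.  Regional deaths are exact per-draw sums of member countries.
    """
    regions = dict(zip(region_map["country"], region_map["region"]))
    missing = [c for c in regions if c not in splits]
    if missing:
        raise ValueError(f"countries in region map without draws: {missing}")

    tables: dict[str, DeathsTable] = {}
    for country, split in splits.items():
        tables[country] = deaths_from_q(split, population)

    years = next(iter(splits.values())).years
    by_region: dict[str, list[str]] = {}
    for country, region in regions.items():
        by_region.setdefault(region, []).append(country)
    # the world is the sum of its regions, so conservation holds exactly in
    # floating point at both levels
    region_names = list(by_region)
    by_region["World"] = region_names

    q_draws: dict[str, dict] = {}
    for region, members in by_region.items():
        deaths, pys = {}, {}
        for _, width, name in _BANDS:
            deaths[name] = sum(tables[c].deaths[name] for c in members)
            pys[name] = sum(tables[c].person_years[name] for c in members)
        tables[region] = DeathsTable(
            unit=region, years=years, deaths=deaths, person_years=pys
        )
        qd = {}
        for _, width, name in _BANDS:
            m = deaths[name] / pys[name][None, :]
            qd[name] = width * m / (1.0 + (width / 2.0) * m)  # m_to_q, a = n/2
        qd["q15_24"] = 1.0 - (1.0 - qd["q15_19"]) * (1.0 - qd["q20_24"])
        q_draws[region] = qd
    return tables, q_draws


def share_of_global(
    tables: dict[str, DeathsTable], unit: str, year: int
) -> tuple[float, float, float]:
    """Unit share of world deaths in a year: median percent and 90% UI."""
    if "World" not in tables:
        raise ValueError("world deaths missing from tables")
    j = int(np.where(tables[unit].years == float(year))[0][0])
    ratio = 100.0 * tables[unit].total()[:, j] / tables["World"].total()[:, j]
    lo, med, hi = np.percentile(ratio, [5, 50, 95])
    return float(med), float(lo), float(hi)


def _q_summary(qd: np.ndarray, j: int) -> tuple[float, float, float]:
    lo, med, hi = np.percentile(1000.0 * qd[:, j], [5, 50, 95])
    return float(med), float(lo), float(hi)


def headline_tables(
    tables: dict[str, DeathsTable],
    q_draws: dict[str, dict],
    years: tuple[int, ...] = (1990, 2000, 2019),
    decimals: int = 1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Produce the probability table and the deaths table.

    The first table reports 5q15, 5q20 and 10q15 per 1000 (median and 90%
    UI) for the requested years plus the annual rate of reduction in 10q15
    between the first and last year, computed on medians.  The second
    reports deaths in thousands per band and year, the share of global
    deaths in the last year, and the relative change in total deaths.
    All printed values use half-away-from-zero rounding.
    """
    units = [u for u in q_draws]
    yr_grid = tables[units[0]].years
    jdx = {y: int(np.where(yr_grid == float(y))[0][0]) for y in years}
    y0, y1 = years[0], years[-1]

    rows1 = []
    for unit in units:
        qd = q_draws[unit]
        row: dict = {"unit": unit}
        for name in ("q15_19", "q20_24", "q15_24"):
            for y in years:
                med, lo, hi = _q_summary(qd[name], jdx[y])
                row[f"{name}_{y}"] = report_round(med, decimals)
                row[f"{name}_{y}_lo"] = report_round(lo, decimals)
                row[f"{name}_{y}_hi"] = report_round(hi, decimals)
        med0 = float(np.median(qd["q15_24"][:, jdx[y0]]))
        med1 = float(np.median(qd["q15_24"][:, jdx[y1]]))
        row["arr"] = report_round(annual_rate_of_reduction(med0, med1, y0, y1), decimals)
        arr_draws = (
            100.0
            * np.log(qd["q15_24"][:, jdx[y0]] / qd["q15_24"][:, jdx[y1]])
            / (y1 - y0)
        )
        lo, hi = np.percentile(arr_draws, [5, 95])
        row["arr_lo"], row["arr_hi"] = report_round(lo, decimals), report_round(hi, decimals)
        rows1.append(row)
    table1 = pd.DataFrame(rows1)

    rows2 = []
    for unit in units:
        tab = tables[unit]
        row = {"unit": unit}
        for band in ("q15_19", "q20_24"):
            label = "15_19" if band == "q15_19" else "20_24"
            for y in years:
                lo, med, hi = np.percentile(tab.deaths[band][:, jdx[y]] / 1e3, [5, 50, 95])
                row[f"deaths_{label}_{y}"] = report_round(med, 0)
                row[f"deaths_{label}_{y}_lo"] = report_round(lo, 0)
                row[f"deaths_{label}_{y}_hi"] = report_round(hi, 0)
        for y in years:
            lo, med, hi = np.percentile(tab.total()[:, jdx[y]] / 1e3, [5, 50, 95])
            row[f"deaths_total_{y}"] = report_round(med, 0)
            row[f"deaths_total_{y}_lo"] = report_round(lo, 0)
            row[f"deaths_total_{y}_hi"] = report_round(hi, 0)
        med, lo, hi = share_of_global(tables, unit, y1)
        row["share_2019"] = report_round(med, decimals)
        row["share_2019_lo"], row["share_2019_hi"] = (
            report_round(lo, decimals),
            report_round(hi, decimals),
        )
        change = 100.0 * (tab.total()[:, jdx[y1]] / tab.total()[:, jdx[y0]] - 1.0)
        lo, med, hi = np.percentile(change, [5, 50, 95])
        row["rel_change"] = report_round(med, decimals)
        row["rel_change_lo"], row["rel_change_hi"] = (
            report_round(lo, decimals),
            report_round(hi, decimals),
        )
        rows2.append(row)
    table2 = pd.DataFrame(rows2)
    return table1, table2
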