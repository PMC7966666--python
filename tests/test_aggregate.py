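"""Deaths, regional aggregation, shares, and headline tables."""

import numpy as np
import pandas as pd
import pytest

from youthmort.agesplit import SplitDraws
from youthmort.aggregate import (
    aggregate,
    deaths_from_q,
    headline_tables,
    share_of_global,
)
from youthmort.lifetable import m_to_q, q_to_m


def _population(countries, years, py=1.0e6):
    rows = []
    for c in countries:
        scale = py if np.isscalar(py) else py[c]
        for y in years:
            rows.append((c, int(y), 15, 5, scale))
            rows.append((c, int(y), 20, 5, scale))
    return pd.DataFrame(
        rows, columns=["country", "year", "age_start", "age_width", "person_years"]
    )


def _split(country, years, q1519, q2024, n_draws=50):
    q1 = np.full((n_draws, len(years)), q1519)
    q2 = np.full((n_draws, len(years)), q2024)
    q = 1 - (1 - q1) * (1 - q2)
    return SplitDraws(country, years, q1, q2, q)


class TestDeathsFromQ:
    years = np.arange(1990.0, 1993.0)

    def test_zero_probability_gives_zero_deaths(self):
        pop = _population(["A"], self.years)
        tab = deaths_from_q(_split("A", self.years, 0.0, 0.0), pop)
        assert np.all(tab.total() == 0.0)

    def test_closed_form_through_rate_conversion(self):
        pop = _population(["A"], self.years, py=1.0e6)
        tab = deaths_from_q(_split("A", self.years, 0.005, 0.0), pop)
        expected = q_to_m(0.005, 5) * 1.0e6  # 1002.506... deaths
        assert np.allclose(tab.deaths["q15_19"], expected)
        assert expected == pytest.approx(1002.506, abs=0.01)

    def test_deaths_scale_linearly_with_population(self):
        pop1 = _population(["A"], self.years, py=1.0e6)
        pop2 = _population(["A"], self.years, py=2.0e6)
        t1 = deaths_from_q(_split("A", self.years, 0.004, 0.006), pop1)
        t2 = deaths_from_q(_split("A", self.years, 0.004, 0.006), pop2)
        assert np.allclose(2 * t1.total(), t2.total())

    def test_missing_population_year_named(self):
        pop = _population(["A"], self.years[:-1])
        with pytest.raises(ValueError, match="1992"):
            deaths_from_q(_split("A", self.years, 0.004, 0.006), pop)


class TestAggregate:
    years = np.arange(1990.0, 1995.0)

    def test_single_country_region_equals_country(self):
        splits = {"A": _split("A", self.years, 0.004, 0.006)}
        pop = _population(["A"], self.years)
        region_map = pd.DataFrame({"country": ["A"], "region": ["R1"]})
        tables, q_draws = aggregate(splits, pop, region_map)
        assert np.allclose(tables["R1"].total(), tables["A"].total())
        assert np.allclose(q_draws["R1"]["q15_19"], 0.004, atol=1e-12)

    def test_equal_population_regional_rate_is_mean_of_rates(self):
        splits = {
            "A": _split("A", self.years, 0.004, 0.004),
            "B": _split("B", self.years, 0.008, 0.008),
        }
        pop = _population(["A", "B"], self.years)
        region_map = pd.DataFrame({"country": ["A", "B"], "region": ["R1", "R1"]})
        _, q_draws = aggregate(splits, pop, region_map)
        m_mean = 0.5 * (q_to_m(0.004, 5) + q_to_m(0.008, 5))
        assert np.allclose(q_draws["R1"]["q15_19"], m_to_q(m_mean, 5), atol=1e-12)

    def test_world_deaths_conserve_exactly_per_draw(self):
        rng = np.random.default_rng(0)
        splits, countries = {}, ["A", "B", "C", "D"]
        for c in countries:
            q1 = rng.uniform(0.002, 0.01, (40, len(self.years)))
            q2 = rng.uniform(0.002, 0.01, (40, len(self.years)))
            splits[c] = SplitDraws(c, self.years, q1, q2, 1 - (1 - q1) * (1 - q2))
        pop = _population(countries, self.years, py={"A": 1e6, "B": 2e6, "C": 5e5, "D": 3e6})
        region_map = pd.DataFrame(
            {"country": countries, "region": ["R1", "R1", "R2", "R2"]}
        )
        tables, q_draws = aggregate(splits, pop, region_map)
        for band in ("q15_19", "q20_24"):
            regional_sum = tables["R1"].deaths[band] + tables["R2"].deaths[band]
            assert np.array_equal(regional_sum, tables["World"].deaths[band])
            for r, members in (("R1", "AB"), ("R2", "CD")):
                member_sum = sum(tables[c].deaths[band] for c in members)
                assert np.array_equal(member_sum, tables[r].deaths[band])
        country_sum = sum(tables[c].total() for c in countries)
        assert np.allclose(country_sum, tables["World"].total(), rtol=1e-12)
        # regional composition identity
        for r in ("R1", "R2", "World"):
            qd = q_draws[r]
            lhs = 1 - (1 - qd["q15_19"]) * (1 - qd["q20_24"])
            assert np.allclose(lhs, qd["q15_24"], atol=1e-15)

    def test_missing_member_country_named(self):
        splits = {"A": _split("A", self.years, 0.004, 0.006)}
        pop = _population(["A", "B"], self.years)
        region_map = pd.DataFrame({"country": ["A", "B"], "region": ["R1", "R1"]})
        with pytest.raises(ValueError, match="B"):
            aggregate(splits, pop, region_map)


class TestShares:
    years = np.arange(1990.0, 1992.0)

    def _tables(self):
        splits = {
            "A": _split("A", self.years, 0.004, 0.004),
            "B": _split("B", self.years, 0.008, 0.008),
        }
        pop = _population(["A", "B"], self.years)
        region_map = pd.DataFrame({"country": ["A", "B"], "region": ["R1", "R2"]})
        return aggregate(splits, pop, region_map)

    def test_single_region_world_share_is_100(self):
        splits = {"A": _split("A", self.years, 0.004, 0.006)}
        pop = _population(["A"], self.years)
        region_map = pd.DataFrame({"country": ["A"], "region": ["R1"]})
        tables, _ = aggregate(splits, pop, region_map)
        med, lo, hi = share_of_global(tables, "R1", 1990)
        assert med == pytest.approx(100.0) and lo == pytest.approx(100.0)

    def test_shares_sum_to_100_per_draw(self):
        tables, _ = self._tables()
        total = (
            tables["R1"].total() / tables["World"].total()
            + tables["R2"].total() / tables["World"].total()
        )
        assert np.allclose(total, 1.0, atol=1e-15)

    def test_printed_table_share_arithmetic(self):
        # printed medians: south Asia 366 thousand of a 1351 thousand world total
        assert round(100 * 366 / 1351, 1) == 27.1


class TestHeadlineTables:
    def test_arr_and_composition_columns(self):
        years = np.arange(1990.0, 2020.0)
        q1519 = np.linspace(0.008, 0.0049, len(years))
        q2024 = np.linspace(0.0092, 0.0063, len(years))
        q1 = np.tile(q1519, (30, 1))
        q2 = np.tile(q2024, (30, 1))
        splits = {"A": SplitDraws("A", years, q1, q2, 1 - (1 - q1) * (1 - q2))}
        pop = _population(["A"], years)
        region_map = pd.DataFrame({"country": ["A"], "region": ["R1"]})
        tables, q_draws = aggregate(splits, pop, region_map)
        t1, t2 = headline_tables(tables, q_draws, years=(1990, 2000, 2019))
        row = t1[t1["unit"] == "R1"].iloc[0]
        # noiseless draws: ARR equals the closed form on the medians
        from youthmort.lifetable import annual_rate_of_reduction, report_round

        q90 = row["q15_24_1990"] / 1000
        q19 = row["q15_24_2019"] / 1000
        assert row["arr"] == report_round(
            annual_rate_of_reduction(q90, q19, 1990, 2019), 1
        )
        # composition of the printed band columns reproduces the total column
        composed = 1000 * (
            1 - (1 - row["q15_19_2019"] / 1000) * (1 - row["q20_24_2019"] / 1000)
        )
        assert abs(composed - row["q15_24_2019"]) <= 0.1  # printed rounding only
        drow = t2[t2["unit"] == "R1"].iloc[0]
        assert drow["share_2019"] == 100.0
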