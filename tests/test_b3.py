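"""The spline bias-reduction model: fit, extrapolation, crisis overlay, summaries."""

import numpy as np
import pandas as pd
import pytest

from youthmort.b3 import (
    B3Config,
    B3Posterior,
    BiasReductionSplineModel,
    crisis_adjust,
    extrapolate,
    fit_b3,
    summarize,
)
from youthmort.lifetable import m_to_q
from youthmort.synthetic import CrisisEvent

_FAST = dict(chains=2, warmup=150, samples=150, projection_year=2022.0)


class TestFit:
    def test_signal_dominated_limit_tracks_observations(self, vr_only_obs):
        model = BiasReductionSplineModel(B3Config(seed=5, **_FAST))
        model.fit(vr_only_obs)
        post = model.posteriors_["L"]
        for _, row in vr_only_obs.iterrows():
            d = post.draws_at(row["ref_time"])[:, 0]
            assert abs(np.median(d) - np.log(row["q"])) < 2 * d.std() + 0.01

    def test_same_seed_reproduces_draws_exactly(self, vr_only_obs):
        a = BiasReductionSplineModel(B3Config(seed=7, **_FAST)).fit(vr_only_obs)
        b = BiasReductionSplineModel(B3Config(seed=7, **_FAST)).fit(vr_only_obs)
        assert np.array_equal(a.posteriors_["L"].draws, b.posteriors_["L"].draws)

    def test_different_seed_changes_draws(self, vr_only_obs):
        a = BiasReductionSplineModel(B3Config(seed=7, **_FAST)).fit(vr_only_obs)
        b = BiasReductionSplineModel(B3Config(seed=8, **_FAST)).fit(vr_only_obs)
        assert not np.array_equal(a.posteriors_["L"].draws, b.posteriors_["L"].draws)

    def test_calendar_shift_equivariance(self, vr_only_obs):
        shifted = vr_only_obs.copy()
        shifted["ref_time"] += 7.0
        shifted["collection_time"] += 7.0
        a = BiasReductionSplineModel(B3Config(seed=9, **_FAST)).fit(vr_only_obs)
        b = BiasReductionSplineModel(B3Config(seed=9, **_FAST)).fit(shifted)
        sa = summarize(a.posteriors_["L"], np.arange(1995.0, 2012.0))
        sb = summarize(b.posteriors_["L"], np.arange(1995.0, 2012.0) + 7.0)
        assert np.allclose(sa["median"], sb["median"], rtol=0.02)

    def test_observation_error_is_multiplicative(self, vr_only_obs):
        # doubling one observation's q shifts its log-scale residual by ln 2:
        # the fitted latent path moves far less than the observation
        bumped = vr_only_obs.copy()
        bumped.loc[10, "q"] *= 2.0
        a = BiasReductionSplineModel(B3Config(seed=4, **_FAST)).fit(vr_only_obs)
        b = BiasReductionSplineModel(B3Config(seed=4, **_FAST)).fit(bumped)
        t = float(vr_only_obs.loc[10, "ref_time"])
        shift = np.median(b.posteriors_["L"].draws_at(t)) - np.median(
            a.posteriors_["L"].draws_at(t)
        )
        assert 0 < shift < np.log(2) / 2

    def test_sparse_countries_deferred(self, vr_only_obs):
        sparse = vr_only_obs.iloc[:3].copy()
        sparse["country"] = "S"
        sparse["series_id"] = "S-vr"
        model = BiasReductionSplineModel(B3Config(seed=5, **_FAST))
        model.fit(pd.concat([vr_only_obs, sparse], ignore_index=True))
        assert model.sparse_countries_ == ["S"]
        assert "S" not in model.posteriors_

    def test_empty_input_rejected(self, vr_only_obs):
        with pytest.raises(ValueError, match="no usable"):
            BiasReductionSplineModel(B3Config(**_FAST)).fit(
                vr_only_obs.assign(excluded=True)
            )

    def test_convergence_diagnostics_reported(self, small_model):
        for post in small_model.posteriors_.values():
            assert set(post.convergence) == {"rhat", "ess", "converged"}
            assert all(np.isfinite(v) for v in post.convergence["rhat"].values())


class TestBiasRecovery:
    def test_known_survey_bias_identified_against_vr(self, vr_only_obs):
        """A sibling survey deflated by b0=-0.25 overlapping complete VR:
        the survey-level bias posterior should locate the deflation."""
        hits = 0
        reps = 12
        for rep in range(reps):
            rng = np.random.default_rng(100 + rep)
            mids = np.array([2008.0, 2003.0, 1998.0])
            logq_true = -4.2 - 0.015 * (mids - 2000.0)
            survey = pd.DataFrame(
                {
                    "country": "L",
                    "series_id": "L-sib",
                    "source_type": "sibling",
                    "ref_time": mids,
                    "collection_time": 2010.5,
                    "age_start": 15,
                    "age_width": 10,
                    "q": np.exp(logq_true - 0.25 + rng.normal(0, 0.05, 3)),
                    "se_logq": 0.05,
                    "excluded": False,
                    "exclusion_reason": "",
                }
            )
            obs = pd.concat([vr_only_obs, survey], ignore_index=True)
            model = BiasReductionSplineModel(B3Config(seed=200 + rep, **_FAST))
            model.fit(obs)
            bd = model.posteriors_["L"].bias_draws["L-sib"][:, 0]
            lo, hi = np.percentile(bd, [5, 95])
            hits += lo <= -0.25 <= hi
        assert hits / reps >= 0.85


class TestExtrapolate:
    def test_projection_uncertainty_widens_beyond_data(self, vr_only_obs):
        model = BiasReductionSplineModel(B3Config(seed=5, **_FAST))
        model.fit(vr_only_obs)  # data end 2012.5
        s = summarize(model.posteriors_["L"])
        width = np.log(s["ui_upper"]) - np.log(s["ui_lower"])
        j_last = int(np.where(s["year"] == 2012.0)[0][0])
        j_2019 = int(np.where(s["year"] == 2019.0)[0][0])
        assert width[j_2019] > width[j_last]
        assert np.all(np.diff(width[j_last:]) > -1e-6)

    def test_dense_linear_data_project_linearly(self, vr_only_obs):
        precise = vr_only_obs.copy()
        precise["se_logq"] = 0.003
        precise["q"] = np.exp(-4.2 - 0.015 * (precise["ref_time"] - 2000.0))
        model = BiasReductionSplineModel(B3Config(seed=6, **_FAST))
        model.fit(precise)
        s = summarize(model.posteriors_["L"], np.array([2019.0]))
        expected = np.exp(-4.2 - 0.015 * 19.0)
        assert s["median"][0] == pytest.approx(expected, rel=0.03)

    def test_target_inside_range_truncates_without_changing_draws(self, small_model):
        post = next(iter(small_model.posteriors_.values()))
        cut = extrapolate(post, 2019.0)
        keep = post.years <= 2019.0
        assert np.array_equal(cut.draws, post.draws[:, keep])

    def test_target_beyond_basis_rejected(self, small_model):
        post = next(iter(small_model.posteriors_.values()))
        with pytest.raises(ValueError, match="beyond"):
            extrapolate(post, 2060.0)


class TestCrisisAdjust:
    @pytest.fixture()
    def post(self):
        years = np.arange(2000.0, 2011.0)
        rng = np.random.default_rng(3)
        draws = np.log(0.012) + 0.03 * rng.standard_normal((400, len(years)))
        return B3Posterior("A", years, draws, chains=1)

    @pytest.fixture()
    def pop(self):
        return pd.DataFrame(
            {
                "country": "A",
                "year": np.arange(2000, 2011),
                "age_start": 15,
                "age_width": 10,
                "person_years": 1.0e6,
            }
        )

    def test_zero_excess_is_identity(self, post, pop):
        out = crisis_adjust(post, [CrisisEvent("A", 2005, 15, 10, 0.0)], pop)
        assert np.array_equal(out.draws, post.draws)

    def test_excess_raises_median_by_converted_amount(self, post, pop):
        excess = 0.01 * 1.0e6
        out = crisis_adjust(post, [CrisisEvent("A", 2005, 15, 10, excess)], pop)
        q_ex = m_to_q(excess / 1.0e6, 10.0)
        j = 5
        expected = 1 - (1 - np.exp(post.draws[:, j])) * (1 - q_ex)
        assert np.allclose(np.exp(out.draws[:, j]), expected, atol=1e-10)
        assert out.crisis_years == {2005}

    def test_interval_width_is_log_survival_shift(self, post, pop):
        out = crisis_adjust(post, [CrisisEvent("A", 2005, 15, 10, 5000.0)], pop)
        j = 5
        w_before = np.subtract(*np.percentile(np.log1p(-np.exp(post.draws[:, j])), [95, 5]))
        w_after = np.subtract(*np.percentile(np.log1p(-np.exp(out.draws[:, j])), [95, 5]))
        assert w_after == pytest.approx(w_before, rel=1e-10)

    def test_event_outside_range_skipped_with_warning(self, post, pop):
        with pytest.warns(UserWarning, match="outside"):
            out = crisis_adjust(post, [CrisisEvent("A", 2030, 15, 10, 100.0)], pop)
        assert np.array_equal(out.draws, post.draws)


class TestSummarize:
    def test_constant_draws_have_zero_width(self):
        years = np.arange(2000.0, 2005.0)
        post = B3Posterior("A", years, np.full((100, 5), np.log(0.01)), chains=1)
        s = summarize(post)
        assert np.allclose(s["ui_lower"], s["ui_upper"])
        assert np.allclose(s["median"], 0.01)

    def test_percentile_ordering(self, small_model):
        for post in small_model.posteriors_.values():
            s = summarize(post)
            assert (s["ui_lower"] <= s["median"]).all()
            assert (s["median"] <= s["ui_upper"]).all()

    def test_matches_independent_quantile_computation(self):
        rng = np.random.default_rng(12)
        years = np.arange(2000.0, 2003.0)
        draws = rng.normal(-4.0, 0.3, (501, 3))
        post = B3Posterior("A", years, draws, chains=1)
        s = summarize(post)
        # second implementation: sort-based quantiles with linear interpolation
        for j in range(3):
            srt = np.sort(np.exp(draws[:, j]))
            for col, p in (("ui_lower", 0.05), ("median", 0.50), ("ui_upper", 0.95)):
                pos = p * (len(srt) - 1)
                k = int(np.floor(pos))
                frac = pos - k
                val = srt[k] * (1 - frac) + srt[min(k + 1, len(srt) - 1)] * frac
                assert s[col][j] == pytest.approx(val, rel=1e-12)


def test_functional_wrapper_returns_posteriors(vr_only_obs):
    posts = fit_b3(vr_only_obs, B3Config(seed=11, **_FAST))
    assert set(posts) == {"L"}
    assert isinstance(posts["L"], B3Posterior)
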