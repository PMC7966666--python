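"""Fallback estimator for data-sparse countries.

Countries with fewer than four usable observations, or whose observations
span less than ten years, cannot support the spline model (it uses no
covariates to fill gaps).  For them, log 10q15 is predicted from the
under-5 mortality rate through a linear mixed model with random intercepts
and random slopes by region, trained on the spline-model medians of the
data-rich countries.  Predictions are emitted in the same posterior-draw
format as the main model so downstream stages are source-agnostic.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .b3 import B3Posterior

__all__ = [
    "MixedFit",
    "MixedEffectsLogLog",
    "is_sparse",
    "fit_mixed",
    "predict_sparse",
    "training_pairs_from_posteriors",
]


def is_sparse(observations: pd.DataFrame) -> bool:
    """True iff a country's data fail the richness rule.

    The rule: fewer than 4 observations, or the period covered by the
    observations (max minus min reference time) is under 10 years.
    """
    obs = observations[~observations["excluded"].astype(bool)]
    if len(obs) < 4:
        return True
    t = obs["ref_time"]
    return bool(t.max() - t.min() < 10.0)


@dataclass
class MixedFit:
    """Fitted mixed-effects log-log regression of 10q15 on U5MR."""

    fixed_intercept: float
    fixed_slope: float
    region_effects: dict = field(default_factory=dict)  # region -> (d_int, d_slope)
    var_intercept: float = 0.0
    var_slope: float = 0.0
    cov_int_slope: float = 0.0
    var_resid: float = 1.0
    n_obs: int = 0
    ols_fallback: bool = False


class MixedEffectsLogLog(BaseEstimator):
    """Mixed-effects regression of log 10q15 on log U5MR by region.

    Fitted by restricted maximum likelihood through statsmodels' ``MixedLM``
    with a deterministic optimizer start; a singular random-effects fit
    falls back to fixed-effects OLS with a warning.

    Attributes (after fit)
    ----------------------
    fit_ : MixedFit
    """

    def __init__(self, min_regions: int = 2, min_pairs: int = 10):
        self.min_regions = min_regions
        self.min_pairs = min_pairs

    def fit(self, pairs: pd.DataFrame) -> "MixedEffectsLogLog":
        """Fit from a table with columns (logq, logu5, region)."""
        n = len(pairs)
        regions = pairs["region"].unique()
        if n < self.min_pairs:
            raise ValueError(f"need at least {self.min_pairs} training pairs, got {n}")
        y = pairs["logq"].to_numpy(dtype=float)
        x = pairs["logu5"].to_numpy(dtype=float)

        if len(regions) < self.min_regions:
            self.fit_ = self._ols(y, x, n, "single region")
            return self

        import statsmodels.api as sm
        from statsmodels.regression.mixed_linear_model import MixedLM

        exog = sm.add_constant(x)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                md = MixedLM(y, exog, groups=pairs["region"].to_numpy(), exog_re=exog)
                res = md.fit(reml=True, method="lbfgs", start_params=None, maxiter=200)
            cov_re = np.asarray(res.cov_re)
            if not np.all(np.isfinite(cov_re)) or np.linalg.det(cov_re) < 0:
                raise np.linalg.LinAlgError("singular random-effects covariance")
        except (np.linalg.LinAlgError, ValueError) as err:
            warnings.warn(f"mixed model failed ({err}); falling back to OLS", stacklevel=2)
            self.fit_ = self._ols(y, x, n, str(err))
            return self

        re = {g: tuple(np.asarray(v)) for g, v in res.random_effects.items()}
        self.fit_ = MixedFit(
            fixed_intercept=float(res.fe_params[0]),
            fixed_slope=float(res.fe_params[1]),
            region_effects=re,
            var_intercept=float(cov_re[0, 0]),
            var_slope=float(cov_re[1, 1]),
            cov_int_slope=float(cov_re[0, 1]),
            var_resid=float(res.scale),
            n_obs=n,
        )
        return self

    @staticmethod
    def _ols(y: np.ndarray, x: np.ndarray, n: int, reason: str) -> MixedFit:
        X = np.column_stack([np.ones(n), x])
        beta, res_ss, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        return MixedFit(
            fixed_intercept=float(beta[0]),
            fixed_slope=float(beta[1]),
            var_resid=float(resid @ resid / max(n - 2, 1)),
            n_obs=n,
            ols_fallback=True,
        )

    def predict(
        self,
        u5mr: np.ndarray,
        region: str | None = None,
        level: float = 0.90,
    ) -> pd.DataFrame:
        """Median and interval of 10q15 given a U5MR series.

        For a region seen in training the prediction conditions on that
        region's estimated effects and carries residual variance only; for
        an unseen region the fixed effects are used and the random-effect
        prediction variance widens the interval.
        """
        from scipy import stats

        f = self.fit_
        u5 = np.asarray(u5mr, dtype=float)
        if np.any(u5 <= 0):
            raise ValueError("U5MR values must be positive")
        x = np.log(u5)
        d_int, d_slope = f.region_effects.get(region, (0.0, 0.0)) if region else (0.0, 0.0)
        seen = region in f.region_effects
        mean = (f.fixed_intercept + d_int) + (f.fixed_slope + d_slope) * x
        var = np.full_like(x, f.var_resid)
        if not seen and not f.ols_fallback:
            var = var + f.var_intercept + 2 * f.cov_int_slope * x + f.var_slope * x**2
        z = stats.norm.ppf(0.5 + level / 2.0)
        sd = np.sqrt(var)
        return pd.DataFrame(
            {
                "median": np.exp(mean),
                "ui_lower": np.exp(mean - z * sd),
                "ui_upper": np.exp(mean + z * sd),
                "sd_log": sd,
                "mean_log": mean,
            }
        )


def training_pairs_from_posteriors(
    posteriors: dict[str, B3Posterior],
    u5mr: pd.DataFrame,
    region_map: pd.DataFrame,
    grid_step: int = 5,
) -> pd.DataFrame:
    """Build (logq, logu5, region) training pairs on a 5-year grid.

    Uses the spline-model posterior medians — not raw observations — of the
    data-rich countries, paired with the country-year U5MR series (columns
    country, year, u5mr).
    """
    reg = dict(zip(region_map["country"], region_map["region"]))
    rows = []
    for country, post in posteriors.items():
        med = np.median(post.draws, axis=0)
        sub = u5mr[u5mr["country"] == country]
        u5_map = dict(zip(sub["year"], sub["u5mr"]))
        for j, year in enumerate(post.years):
            if int(year) % grid_step or int(year) not in u5_map:
                continue
            rows.append((med[j], math.log(u5_map[int(year)]), reg.get(country, "?")))
    return pd.DataFrame(rows, columns=["logq", "logu5", "region"])


def fit_mixed(pairs: pd.DataFrame) -> MixedFit:
    """REML fit of the mixed-effects log-log regression."""
    est = MixedEffectsLogLog()
    est.fit(pairs)
    return est.fit_


def predict_sparse(
    u5mr: pd.DataFrame,
    region: str,
    fit: MixedFit,
    country: str = "",
    n_draws: int = 4000,
    seed: int = 0,
) -> B3Posterior:
    """Predict a sparse country's 10q15 path and emit posterior-style draws.

    ``u5mr`` has columns (year, u5mr).  Draws are independent normals on the
    log scale around the mixed-model prediction, so downstream stages
    (age split, aggregation) cannot distinguish this output from a spline
    fit; the ``source`` flag records the provenance.
    """
    est = MixedEffectsLogLog()
    est.fit_ = fit
    years = u5mr["year"].to_numpy(dtype=float)
    pred = est.predict(u5mr["u5mr"].to_numpy(), region=region)
    rng = np.random.default_rng(seed)
    draws = pred["mean_log"].to_numpy()[None, :] + pred["sd_log"].to_numpy()[
        None, :
    ] * rng.standard_normal((n_draws, len(years)))
    return B3Posterior(
        country=country,
        years=years,
        draws=draws,
        chains=1,
        convergence={"converged": True, "rhat": {}, "ess": {}},
        source="sparse",
    )
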