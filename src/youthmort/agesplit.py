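"""Split 10q15 into 5q15 and 5q20 via a penalised spline on the logit ratio.

The quantity smoothed is the logit of r = 5q15 / (median 10q15): ratio
observations from the 15-19 database are divided by the model's median
youth-mortality estimate at the observation time, logit-transformed, and
smoothed over time with a second-difference-penalised B-spline whose
penalty is chosen by generalized cross-validation.  The fitted ratio is
then applied to every posterior draw of 10q15, so that per draw

    5q15 = r(t) * q,     5q20 = 1 - (1 - q) / (1 - 5q15)

and the composition identity 1-q = (1-5q15)(1-5q20) holds exactly; split
uncertainty derives entirely from the 10q15 posterior.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .b3 import B3Posterior
from .basis import build_basis

__all__ = [
    "RatioFit",
    "SplitDraws",
    "RatioSplineSplitter",
    "ratio_observations",
    "fit_ratio_spline",
    "apply_split",
]

_CLIP = (0.01, 0.99)


@dataclass
class RatioFit:
    """Smoothed trajectory of the 5q15 / 10q15 ratio for one country."""

    country: str
    years: np.ndarray
    r_hat: np.ndarray
    smoothing_penalty: float
    n_obs_used: int

    def r_at(self, t: np.ndarray | float) -> np.ndarray:
        return np.interp(np.asarray(t, dtype=float), self.years, self.r_hat)


@dataclass
class SplitDraws:
    """Posterior draws of the two five-year band probabilities."""

    country: str
    years: np.ndarray
    q15_19: np.ndarray  # (n_draws, n_years)
    q20_24: np.ndarray
    q15_24: np.ndarray
    source: str = "b3"


def ratio_observations(
    obs_5q15: pd.DataFrame, posterior: B3Posterior
) -> pd.DataFrame:
    """Build (t, logit r, weight) rows from 15-19 observations.

    The denominator is the posterior median 10q15 linearly interpolated at
    each observation time.  Ratios outside (0.01, 0.99) are clipped and
    flagged.  Weights are inverse squared standard errors of log q.
    """
    t = obs_5q15["ref_time"].to_numpy(dtype=float)
    med = np.exp(np.median(posterior.draws_at(t), axis=0))
    if np.any(med <= 0):
        raise ValueError("posterior median 10q15 is zero at an observation time")
    r = obs_5q15["q"].to_numpy(dtype=float) / med
    clipped = (r <= _CLIP[0]) | (r >= _CLIP[1])
    r = np.clip(r, _CLIP[0], _CLIP[1])
    se = np.maximum(obs_5q15["se_logq"].to_numpy(dtype=float), 1e-6)
    return pd.DataFrame(
        {
            "t": t,
            "logit_r": np.log(r / (1.0 - r)),
            "weight": 1.0 / se**2,
            "clipped": clipped,
        }
    )


class RatioSplineSplitter(BaseEstimator):
    """Penalised weighted least squares for the logit ratio trend.

    Parameters
    ----------
    penalty : float or None
        Second-difference penalty weight; None selects it by generalized
        cross-validation over a log-spaced grid.
    knot_spacing : float
        Knot spacing of the underlying B-spline basis, in years.

    Attributes (after fit)
    ----------------------
    fit_ : RatioFit
    gcv_path_ : DataFrame with the GCV score per candidate penalty.
    """

    def __init__(self, penalty: float | None = None, knot_spacing: float = 2.5):
        self.penalty = penalty
        self.knot_spacing = knot_spacing

    def fit(
        self,
        ratio_obs: pd.DataFrame,
        years: np.ndarray,
        country: str = "",
    ) -> "RatioSplineSplitter":
        years = np.asarray(years, dtype=float)
        n = len(ratio_obs)
        if n <= 2:
            # too little data for a curve: constant at the weighted mean
            if n == 0:
                raise ValueError(
                    "no ratio observations; use the regional mean curve instead"
                )
            w = ratio_obs["weight"].to_numpy(dtype=float)
            z = ratio_obs["logit_r"].to_numpy(dtype=float)
            const = float(np.sum(w * z) / np.sum(w))
            r = 1.0 / (1.0 + math.exp(-const))
            self.fit_ = RatioFit(country, years, np.full(len(years), r), math.inf, n)
            self.gcv_path_ = pd.DataFrame(columns=["penalty", "gcv"])
            return self

        t = ratio_obs["t"].to_numpy(dtype=float)
        z = ratio_obs["logit_r"].to_numpy(dtype=float)
        w = ratio_obs["weight"].to_numpy(dtype=float)
        w = w / w.mean()  # scale-free weights so the penalty grid is comparable

        lo = min(years[0], t.min())
        hi = max(years[-1], t.max())
        basis = build_basis(math.floor(lo), math.ceil(hi), self.knot_spacing)
        X = basis.design(t)
        D = basis.penalty(2)
        P = D.T @ D
        XtW = X.T * w
        XtWX = XtW @ X
        XtWz = XtW @ z
        # small ridge on the penalty null space keeps lambda -> inf well posed
        ridge = 1e-8 * np.eye(basis.n_basis)

        def solve(lam: float) -> tuple[np.ndarray, float]:
            A = XtWX + lam * P + ridge
            beta = np.linalg.solve(A, XtWz)
            H_diag = np.einsum("ij,ji->i", X @ np.linalg.inv(A), XtW)
            return beta, float(np.sum(H_diag))

        if self.penalty is None:
            grid = np.logspace(-2, 6, 17)
            scores = []
            for lam in grid:
                beta, edf = solve(lam)
                resid = z - X @ beta
                rss = float(np.sum(w * resid**2))
                denom = max(n - edf, 1e-6)
                scores.append(n * rss / denom**2)
            best = int(np.argmin(scores))
            lam = float(grid[best])
            self.gcv_path_ = pd.DataFrame({"penalty": grid, "gcv": scores})
        else:
            lam = float(self.penalty)
            self.gcv_path_ = pd.DataFrame(columns=["penalty", "gcv"])

        beta, _ = solve(lam)
        zhat = basis.design(years) @ beta
        r_hat = 1.0 / (1.0 + np.exp(-np.clip(zhat, -6, 6)))
        self.fit_ = RatioFit(country, years, r_hat, lam, n)
        return self

    def transform(self, posterior: B3Posterior) -> SplitDraws:
        return apply_split(posterior, self.fit_)


def fit_ratio_spline(
    ratio_obs: pd.DataFrame,
    years: np.ndarray,
    penalty: float | None = None,
    country: str = "",
    knot_spacing: float = 2.5,
) -> RatioFit:
    """Fit the penalised logit-ratio spline; GCV picks the penalty if None."""
    est = RatioSplineSplitter(penalty=penalty, knot_spacing=knot_spacing)
    est.fit(ratio_obs, years, country)
    return est.fit_


def apply_split(posterior: B3Posterior, fit: RatioFit) -> SplitDraws:
    """Apply the smoothed ratio to every 10q15 posterior draw.

    Per draw and year, 5q15 = r * q and 5q20 follows from the survival
    identity, so composing the two bands reproduces the draw's 10q15
    exactly.
    """
    r = fit.r_at(posterior.years)
    if np.any((r <= 0) | (r >= 1)):
        raise ValueError("fitted ratio must lie strictly inside (0, 1)")
    q = posterior.q_draws
    q5_15 = r[None, :] * q
    q5_20 = 1.0 - (1.0 - q) / (1.0 - q5_15)
    return SplitDraws(
        country=posterior.country,
        years=posterior.years,
        q15_19=q5_15,
        q20_24=q5_20,
        q15_24=q,
        source=posterior.source,
    )
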