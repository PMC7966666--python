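"""Death-registration completeness by the generalized growth balance method.

In a population closed to migration, the entry rate into the open age
interval x+ minus its growth rate equals its death rate.  When only a
fraction *c* of deaths is registered, the observed partial death rates are
scaled by 1/c, so regressing (entry rate - growth rate) on the registered
partial death rate across open ages recovers 1/c as the slope; the
intercept absorbs relative census coverage change.  Orthogonal (total least
squares) regression is used for the line, the standard choice in
death-distribution methods since both axes carry error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .lifetable import m_to_q, q_to_m

__all__ = [
    "CompletenessEstimate",
    "GrowthBalanceCompleteness",
    "ggb_fit",
    "adjust_vr_series",
    "completeness_schedule",
]


@dataclass
class CompletenessEstimate:
    """Result of one growth-balance fit over an intercensal period."""

    country: str
    period: tuple[float, float]
    c: float
    intercept: float
    se_c: float
    fit_points: pd.DataFrame = field(repr=False)  # open age, x=d(x+), y=b(x+)-r(x+)
    ages_used: tuple[int, int] = (15, 65)


def _orthogonal_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Total-least-squares slope and intercept of y on x."""
    xm, ym = x.mean(), y.mean()
    sxx = np.sum((x - xm) ** 2)
    syy = np.sum((y - ym) ** 2)
    sxy = np.sum((x - xm) * (y - ym))
    if abs(sxy) < 1e-300:
        raise ValueError("degenerate growth-balance fit: no covariance")
    slope = (syy - sxx + math.hypot(syy - sxx, 2 * sxy)) / (2 * sxy)
    return slope, ym - slope * xm


class GrowthBalanceCompleteness(BaseEstimator):
    """Generalized growth balance estimator of registration completeness.

    Parameters
    ----------
    age_min, age_max : int
        Lowest and highest open-age boundaries used in the regression.
        Defaults 15 through 65 target the youth band while retaining eleven
        fit points.

    Attributes (after fit)
    ----------------------
    completeness_ : float
        Estimated completeness, clipped to (0, 1.5].
    intercept_ : float
        Residual coverage-change/migration term.
    se_c_ : float
        Delete-one jackknife standard error of the completeness estimate.
    fit_points_ : DataFrame
        Open age, partial death rate, and entry-minus-growth rate per point.
    """

    def __init__(self, age_min: int = 15, age_max: int = 65):
        self.age_min = age_min
        self.age_max = age_max

    @staticmethod
    def _validate(frame: pd.DataFrame, name: str) -> pd.DataFrame:
        frame = frame.sort_values("age_start").reset_index(drop=True)
        starts = frame["age_start"].to_numpy()
        if len(starts) < 5 or np.any(np.diff(starts) <= 0):
            raise ValueError(f"{name}: age groups must be strictly increasing")
        if np.any(frame["count"].to_numpy() < 0):
            raise ValueError(f"{name}: negative counts")
        return frame

    def fit(
        self,
        census1: pd.DataFrame,
        census2: pd.DataFrame,
        deaths: pd.DataFrame,
    ) -> "GrowthBalanceCompleteness":
        """Fit from two census age distributions and annual registered deaths.

        All three tables use columns (country, time, age_start, age_width,
        count); deaths are annual averages over the intercensal period.
        """
        c1 = self._validate(census1, "census1")
        c2 = self._validate(census2, "census2")
        d = self._validate(deaths, "deaths")
        t1 = float(c1["time"].iloc[0])
        t2 = float(c2["time"].iloc[0])
        if t2 <= t1:
            raise ValueError("second census must postdate the first")
        T = t2 - t1
        starts = c1["age_start"].to_numpy()
        if not np.array_equal(starts, c2["age_start"].to_numpy()) or not np.array_equal(
            starts, d["age_start"].to_numpy()
        ):
            raise ValueError("age groups must agree across the three tables")
        n1 = c1["count"].to_numpy(dtype=float)
        n2 = c2["count"].to_numpy(dtype=float)
        dd = d["count"].to_numpy(dtype=float)
        if dd.sum() <= 0:
            raise ValueError("registered deaths are all zero")

        open_ages = [
            int(a) for a in starts if self.age_min <= a <= self.age_max and a > starts[0]
        ]
        if len(open_ages) < 4:
            raise ValueError("growth-balance fit needs at least 4 open-age points")

        rows = []
        for x in open_ages:
            sel = starts >= x
            gm_plus = math.sqrt(n1[sel].sum() * n2[sel].sum())  # mean pop aged x+
            if gm_plus <= 0:
                raise ValueError(f"zero population above age {x}")
            around = (starts >= x - 5) & (starts < x + 5)
            gm_around = math.sqrt(n1[around].sum() * n2[around].sum())
            if gm_around <= 0:
                raise ValueError(f"zero population around age {x}")
            entry = (gm_around / 10.0) / gm_plus
            growth = math.log(n2[sel].sum() / n1[sel].sum()) / T
            death_rate = dd[sel].sum() / gm_plus
            rows.append((x, death_rate, entry - growth))
        pts = pd.DataFrame(rows, columns=["open_age", "partial_death_rate", "entry_minus_growth"])

        x = pts["partial_death_rate"].to_numpy()
        y = pts["entry_minus_growth"].to_numpy()
        slope, intercept = _orthogonal_line(x, y)
        if slope <= 0:
            raise ValueError("growth-balance slope non-positive; inputs inconsistent")
        c_hat = min(1.0 / slope, 1.5)

        # delete-one jackknife for the sampling error of c
        if len(x) > 4:
            reps = []
            for i in range(len(x)):
                keep = np.arange(len(x)) != i
                s_i, _ = _orthogonal_line(x[keep], y[keep])
                if s_i > 0:
                    reps.append(min(1.0 / s_i, 1.5))
            reps = np.asarray(reps)
            n = len(reps)
            se = math.sqrt((n - 1) / n * np.sum((reps - reps.mean()) ** 2)) if n > 1 else 0.0
        else:
            se = 0.0

        self.completeness_ = c_hat
        self.intercept_ = intercept
        self.se_c_ = se
        self.fit_points_ = pts
        self.period_ = (t1, t2)
        self.country_ = str(c1["country"].iloc[0])
        return self

    def estimate_(self) -> CompletenessEstimate:
        return CompletenessEstimate(
            country=self.country_,
            period=self.period_,
            c=self.completeness_,
            intercept=self.intercept_,
            se_c=self.se_c_,
            fit_points=self.fit_points_,
            ages_used=(self.age_min, self.age_max),
        )


def ggb_fit(
    census1: pd.DataFrame,
    census2: pd.DataFrame,
    deaths: pd.DataFrame,
    age_range: tuple[int, int] = (15, 65),
) -> CompletenessEstimate:
    """Estimate registration completeness by generalized growth balance."""
    est = GrowthBalanceCompleteness(age_min=age_range[0], age_max=age_range[1])
    est.fit(census1, census2, deaths)
    return est.estimate_()


def adjust_vr_series(
    observations: pd.DataFrame,
    estimate: CompletenessEstimate,
    inclusion_threshold: float = 0.5,
    reclassify_threshold: float = 0.95,
) -> pd.DataFrame:
    """Scale incompletely registered VR observations up to full coverage.

    Death rates are divided by min(c, 1) before the q conversion; the
    standard error on the log scale is inflated by the delta-method
    completeness uncertainty.  Series with c below ``inclusion_threshold``
    are flagged excluded rather than adjusted, mirroring the rule that only
    country-years with usable registration enter the likelihood.
    """
    if not 0 < estimate.c <= 1.5:
        raise ValueError("completeness estimate out of range")
    out = observations.copy()
    is_vr = out["source_type"].isin(["vr_complete", "vr_incomplete"])
    if estimate.c < inclusion_threshold:
        out.loc[is_vr, "excluded"] = True
        out.loc[is_vr, "exclusion_reason"] = "completeness_below_threshold"
        return out
    c_eff = min(estimate.c, 1.0)
    if c_eff < 1.0:
        widths = out.loc[is_vr, "age_width"].to_numpy(dtype=float)
        qs = out.loc[is_vr, "q"].to_numpy(dtype=float)
        adj = np.array(
            [m_to_q(q_to_m(q, w) / c_eff, w) for q, w in zip(qs, widths)]
        )
        out.loc[is_vr, "q"] = adj
        extra = estimate.se_c / c_eff
        out.loc[is_vr, "se_logq"] = np.hypot(
            out.loc[is_vr, "se_logq"].to_numpy(dtype=float), extra
        )
    if estimate.c < reclassify_threshold:
        out.loc[is_vr, "source_type"] = "vr_incomplete"
    return out


def completeness_schedule(
    estimates: list[CompletenessEstimate], years: np.ndarray
) -> dict[int, float]:
    """Linear interpolation of completeness between intercensal midpoints.

    Outside the span of estimates the nearest value is carried forward or
    backward.
    """
    if not estimates:
        raise ValueError("no completeness estimates supplied")
    mids = np.array([0.5 * (e.period[0] + e.period[1]) for e in estimates])
    cs = np.array([e.c for e in estimates])
    order = np.argsort(mids)
    interp = np.interp(np.asarray(years, dtype=float), mids[order], cs[order])
    return {int(y): float(c) for y, c in zip(years, interp)}
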