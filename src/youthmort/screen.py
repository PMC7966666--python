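"""Plausibility screen for survey series: log-quadratic expected pattern.

Retrospective surveys that omit deceased siblings produce implausibly low
youth mortality relative to the under-5 mortality measured by the same
survey's birth histories.  The screen fits a log-quadratic regression of
log 10q15 on log 5q0 (and its square) over a reference database, and
excludes any survey series whose pooled 10q15 falls below the lower bound
of the one-sided 95% prediction interval at the survey's under-5 level.
Exclusion is one-sided: overstated mortality never triggers it.  Vital
registration is never screened.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

__all__ = ["LogQuadFit", "LogQuadraticScreen", "fit_logquad", "prediction_bounds", "screen_surveys"]


@dataclass
class LogQuadFit:
    """Frozen coefficients and prediction machinery of the reference fit."""

    beta: np.ndarray  # (beta0, beta1, beta2) on (1, x, x^2), x = log 5q0
    sigma2: float
    n_ref: int
    xtx_inverse: np.ndarray = field(repr=False)

    @property
    def dof(self) -> int:
        return self.n_ref - 3


class LogQuadraticScreen(BaseEstimator):
    """OLS of log 10q15 on a quadratic in log 5q0, with prediction intervals.

    Attributes (after fit)
    ----------------------
    fit_ : LogQuadFit
        Coefficients, residual variance (n-3 denominator), and the stored
        design cross-product inverse used for prediction leverage.
    """

    def __init__(self, level: float = 0.95):
        self.level = level

    def fit(self, q5_0: np.ndarray, q10_15: np.ndarray) -> "LogQuadraticScreen":
        q5 = np.asarray(q5_0, dtype=float)
        q15 = np.asarray(q10_15, dtype=float)
        if np.any((q5 <= 0) | (q5 >= 1)) or np.any((q15 <= 0) | (q15 >= 1)):
            raise ValueError("reference probabilities must lie in (0, 1)")
        n = len(q5)
        if n <= 10:
            raise ValueError("reference database too small (need n > 10)")
        x = np.log(q5)
        X = np.column_stack([np.ones(n), x, x**2])
        y = np.log(q15)
        xtx = X.T @ X
        cond = np.linalg.cond(xtx)
        if not np.isfinite(cond) or cond > 1e12:
            raise ValueError("degenerate design: log 5q0 values nearly collinear")
        beta = np.linalg.solve(xtx, X.T @ y)
        resid = y - X @ beta
        sigma2 = float(resid @ resid) / (n - 3)
        self.fit_ = LogQuadFit(
            beta=beta, sigma2=sigma2, n_ref=n, xtx_inverse=np.linalg.inv(xtx)
        )
        return self

    def predict(self, q5_0: np.ndarray | float) -> np.ndarray:
        """Expected 10q15 at the given under-5 level(s)."""
        x = np.log(np.atleast_1d(np.asarray(q5_0, dtype=float)))
        X = np.column_stack([np.ones_like(x), x, x**2])
        return np.exp(X @ self.fit_.beta)

    def prediction_bounds(
        self, q5_0: float, level: float | None = None
    ) -> tuple[float, float]:
        """Two-sided prediction interval for a new 10q15 at q5_0, on the q scale."""
        f = self.fit_
        level = self.level if level is None else level
        x = float(np.log(q5_0))
        v = np.array([1.0, x, x**2])
        leverage = float(v @ f.xtx_inverse @ v)
        half = stats.t.ppf(0.5 + level / 2.0, f.dof) * np.sqrt(f.sigma2 * (1.0 + leverage))
        mean = float(v @ f.beta)
        return float(np.exp(mean - half)), float(np.exp(mean + half))


def fit_logquad(reference_pairs: pd.DataFrame, level: float = 0.95) -> LogQuadraticScreen:
    """Fit the screen from a reference table with columns (q5_0, q10_15)."""
    scr = LogQuadraticScreen(level=level)
    scr.fit(reference_pairs["q5_0"].to_numpy(), reference_pairs["q10_15"].to_numpy())
    return scr


def prediction_bounds(
    screen: LogQuadraticScreen, q5_0: float, level: float = 0.95
) -> tuple[float, float]:
    return screen.prediction_bounds(q5_0, level)


def _pool_series(group: pd.DataFrame) -> float:
    """Inverse-variance weighted mean of log q across a series' observations."""
    logq = np.log(group["q"].to_numpy(dtype=float))
    se = group["se_logq"].to_numpy(dtype=float)
    w = 1.0 / np.maximum(se, 1e-6) ** 2
    return float(np.sum(w * logq) / np.sum(w))


def screen_surveys(
    observations: pd.DataFrame,
    screen: LogQuadraticScreen,
    survey_pairs: pd.DataFrame,
    level: float = 0.95,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flag survey/census series implausibly low against the expected pattern.

    The decision is at series level: the series' inverse-variance pooled
    10q15 is compared with the lower bound of the 95% prediction interval at
    the series' paired under-5 level.  Series without a paired under-5
    summary pass with a warning.  Returns the flagged observation table and
    a per-series screen report.
    """
    out = observations.copy()
    pair_map = dict(zip(survey_pairs["series_id"], survey_pairs["q5_0"]))
    screenable = out["source_type"].isin(["sibling", "census"])
    report_rows = []
    for series_id, group in out[screenable].groupby("series_id"):
        pooled_q = float(np.exp(_pool_series(group)))
        q5 = pair_map.get(series_id)
        if q5 is None or not np.isfinite(q5):
            import warnings

            warnings.warn(
                f"series {series_id} has no paired under-5 summary; passes unscreened",
                stacklevel=2,
            )
            report_rows.append((series_id, pooled_q, np.nan, np.nan, "kept_unpaired"))
            continue
        lower, _ = screen.prediction_bounds(float(q5), level)
        if pooled_q < lower:
            out.loc[out["series_id"] == series_id, "excluded"] = True
            out.loc[out["series_id"] == series_id, "exclusion_reason"] = (
                "below_logquad_lower"
            )
            decision = "excluded"
        else:
            decision = "kept"
        report_rows.append((series_id, pooled_q, float(q5), lower, decision))
    report = pd.DataFrame(
        report_rows,
        columns=["series_id", "pooled_q15_24", "pooled_q5_0", "lower_bound", "decision"],
    )
    return out, report
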