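"""Out-of-sample validation of the estimation pipeline.

The design mirrors standard practice for mortality estimation models: refit
on all data *collected* before a cutoff year (the split is by survey or
census field date, not by the reference period, so a recent survey's whole
retrospective series is withheld together), then compare the refit's
predictions with the withheld observations.  Errors are reported per 1000
(observed minus predicted); coverage is measured against the predictive
interval for a *new observation* — the latent-q interval widened by the
observation's sampling error, the source's non-sampling error, and, for
retrospective sources, the survey-bias distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .b3 import B3Posterior, BiasReductionSplineModel

__all__ = ["ValidationReport", "make_training_set", "evaluate", "evaluate_predictions"]

_DELTA_SOURCES = ("sibling", "census")


@dataclass
class ValidationReport:
    """Summary of prediction errors on withheld observations."""

    cutoff_year: float
    n_leftout: int
    median_error: float  # per 1000, observed minus predicted
    median_abs_error: float  # per 1000
    coverage90: float
    records: pd.DataFrame = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "cutoff_year": self.cutoff_year,
            "n_leftout": self.n_leftout,
            "median_error": self.median_error,
            "median_abs_error": self.median_abs_error,
            "coverage90": self.coverage90,
        }


def make_training_set(
    observations: pd.DataFrame, cutoff_year: float = 2013.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split observations by collection date: training strictly before cutoff."""
    coll = observations["collection_time"].to_numpy(dtype=float)
    training = observations[coll < cutoff_year].copy()
    leftout = observations[coll >= cutoff_year].copy()
    if training.empty:
        raise ValueError("training set is empty: every observation is at or after the cutoff")
    if leftout.empty:
        raise ValueError("no observations at or after the cutoff to validate against")
    return training, leftout


def _predictive_draws(
    post: B3Posterior,
    row: pd.Series,
    hyper: pd.DataFrame,
    rng: np.random.Generator,
    vr_level_sd: float = 0.0,
) -> np.ndarray:
    """Draws of a new observation's q at the row's time, band and source."""
    n = len(post.draws)
    logq = post.draws_at(float(row["ref_time"]))[:, 0]
    h = hyper.iloc[np.arange(n) % len(hyper)]
    source = row["source_type"]
    se = float(row["se_logq"])
    omega_col = f"omega_{source}"
    omega = h[omega_col].to_numpy() if omega_col in h else np.zeros(n)
    total_sd = np.sqrt(se**2 + omega**2)
    mean = logq
    series_id = row["series_id"]
    if series_id in post.bias_draws:
        # the series continues from the training period: reuse its posterior
        # error-term draws (aligned and correlated with the latent draws)
        bd = post.bias_draws[series_id]
        lag = float(row["collection_time"]) - float(row["ref_time"])
        mean = mean + bd[:, 0] + bd[:, 1] * lag
    elif source == "vr_incomplete":
        # new adjusted-VR series: fresh residual completeness level error
        total_sd = np.sqrt(total_sd**2 + vr_level_sd**2)
    elif source in _DELTA_SOURCES:
        # new retrospective series: fresh survey-level bias from the hierarchy
        lag = float(row["collection_time"]) - float(row["ref_time"])
        b0 = h["mu0"].to_numpy() + h["tau0"].to_numpy() * rng.standard_normal(n)
        b1 = h["mu1"].to_numpy() + h["tau1"].to_numpy() * rng.standard_normal(n)
        mean = mean + b0 + b1 * lag
    return np.exp(mean + total_sd * rng.standard_normal(n))


def evaluate(
    model: BiasReductionSplineModel,
    leftout: pd.DataFrame,
    seed: int = 0,
    level: float = 0.90,
) -> ValidationReport:
    """Score a refit model against withheld observations.

    Per observation: error = 1000 * (q_obs - median predictive q); coverage
    is the fraction of withheld observations inside the central 90%
    predictive interval.  Observations for countries absent from the refit
    are skipped (they had no training data).
    """
    rng = np.random.default_rng(seed)
    hyper = model.hyper_draws_
    rows = []
    for _, row in leftout.iterrows():
        country = row["country"]
        if country not in model.posteriors_:
            continue
        if int(row["age_width"]) != 10:
            raise ValueError("validation expects 10-year band observations")
        pred = _predictive_draws(
            model.posteriors_[country],
            row,
            hyper,
            rng,
            vr_level_sd=model.config.vr_level_error_sd,
        )
        lo, med, hi = np.percentile(pred, [50 - 50 * level, 50, 50 + 50 * level])
        q_obs = float(row["q"])
        rows.append(
            (
                country,
                row["series_id"],
                row["source_type"],
                float(row["ref_time"]),
                q_obs,
                med,
                lo,
                hi,
                1000.0 * (q_obs - med),
                lo <= q_obs <= hi,
            )
        )
    records = pd.DataFrame(
        rows,
        columns=[
            "country",
            "series_id",
            "source_type",
            "ref_time",
            "q_obs",
            "q_pred",
            "pred_lower",
            "pred_upper",
            "error_per_1000",
            "covered",
        ],
    )
    return _report_from_records(records, cutoff_year=np.nan)


def evaluate_predictions(
    predictions: pd.DataFrame, cutoff_year: float = np.nan
) -> ValidationReport:
    """Score externally supplied point/interval predictions.

    ``predictions`` carries one row per withheld observation with columns
    (q_obs, q_pred, pred_lower, pred_upper); useful for testing the error
    conventions with constructed predictions.
    """
    rec = predictions.copy()
    rec["error_per_1000"] = 1000.0 * (rec["q_obs"] - rec["q_pred"])
    rec["covered"] = (rec["pred_lower"] <= rec["q_obs"]) & (
        rec["q_obs"] <= rec["pred_upper"]
    )
    return _report_from_records(rec, cutoff_year)


def _report_from_records(records: pd.DataFrame, cutoff_year: float) -> ValidationReport:
    if records.empty:
        raise ValueError("no withheld observations could be scored")
    err = records["error_per_1000"].to_numpy(dtype=float)
    return ValidationReport(
        cutoff_year=cutoff_year,
        n_leftout=len(records),
        median_error=float(np.median(err)),
        median_abs_error=float(np.median(np.abs(err))),
        coverage90=float(records["covered"].mean()),
        records=records,
    )
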