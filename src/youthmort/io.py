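"""Readers and writers for the pipeline's plain-text tables.

All interchange is CSV (observations, populations, region maps, censuses,
summaries), YAML for run configuration, and JSON for run summaries.  The
observation schema is validated row by row; malformed rows are rejected
with their line numbers, and the probability scale must be declared (per 1)
— per-1000 inputs are refused rather than guessed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .lifetable import OBSERVATION_COLUMNS, SOURCE_TYPES

__all__ = [
    "read_observations",
    "write_observations",
    "read_population",
    "read_region_map",
    "write_summaries",
    "write_posterior_store",
    "read_posterior_store",
]


class SchemaError(ValueError):
    """A table violated the declared schema."""


def read_observations(path: str | Path) -> pd.DataFrame:
    """Read and validate an observation CSV.

    Raises :class:`SchemaError` naming the offending line numbers for
    unknown source types, invalid q values (including values > 1 that look
    like undeclared per-1000 reporting), negative standard errors, and
    negative retrospective lags.
    """
    df = pd.read_csv(path)
    missing = [c for c in OBSERVATION_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    df = df[OBSERVATION_COLUMNS]
    problems = []
    lines = df.index + 2  # header is line 1
    bad_source = ~df["source_type"].isin(SOURCE_TYPES)
    for ln in lines[bad_source]:
        problems.append(f"line {ln}: unknown source_type")
    q = df["q"].to_numpy(dtype=float)
    bad_q = (q <= 0) | (q >= 1)
    for ln in lines[bad_q]:
        problems.append(
            f"line {ln}: q outside (0, 1) — per-1000 values must be rescaled "
            "to per 1 before loading"
        )
    bad_se = df["se_logq"].to_numpy(dtype=float) < 0
    for ln in lines[bad_se]:
        problems.append(f"line {ln}: negative se_logq")
    lag = df["collection_time"].to_numpy(dtype=float) - df["ref_time"].to_numpy(dtype=float)
    for ln in lines[lag < 0]:
        problems.append(f"line {ln}: collection_time before ref_time")
    bad_band = (df["age_start"].to_numpy(dtype=float) < 0) | (
        df["age_width"].to_numpy(dtype=float) <= 0
    )
    for ln in lines[bad_band]:
        problems.append(f"line {ln}: invalid age band")
    if problems:
        raise SchemaError(f"{path}: " + "; ".join(problems))
    df["excluded"] = df["excluded"].astype(bool)
    df["exclusion_reason"] = df["exclusion_reason"].fillna("").astype(str)
    return df


def write_observations(df: pd.DataFrame, path: str | Path) -> None:
    df[OBSERVATION_COLUMNS].to_csv(path, index=False)


def read_population(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    need = ["country", "year", "age_start", "age_width", "person_years"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    if (df["person_years"] <= 0).any():
        raise SchemaError(f"{path}: non-positive person_years")
    return df[need]


def read_region_map(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ("country", "region") if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    return df


def write_summaries(summaries: pd.DataFrame, path: str | Path) -> None:
    summaries.to_csv(path, index=False)


def write_posterior_store(posteriors: dict, path: str | Path) -> None:
    """Write draws as a long columnar CSV (country, year, draw, logq, source)."""
    frames = []
    for country, post in posteriors.items():
        n_draws, n_years = post.draws.shape
        frames.append(
            pd.DataFrame(
                {
                    "country": country,
                    "year": np.repeat(post.years, n_draws),
                    "draw": np.tile(np.arange(n_draws), n_years),
                    "logq": post.draws.T.ravel(),
                    "source": post.source,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_posterior_store(path: str | Path) -> dict:
    from .b3 import B3Posterior

    df = pd.read_csv(path)
    out = {}
    for country, sub in df.groupby("country"):
        years = np.sort(sub["year"].unique().astype(float))
        piv = sub.pivot(index="draw", columns="year", values="logq")
        out[country] = B3Posterior(
            country=country,
            years=years,
            draws=piv.to_numpy(),
            chains=1,
            source=str(sub["source"].iloc[0]),
        )
    return out


def write_run_summary(summary: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(summary, indent=2, default=float))
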