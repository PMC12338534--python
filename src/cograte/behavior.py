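"""Composite cognitive rank from trial-level Barnes-maze records.

Eight behavioral measures are computed per mouse and ranked within the
cohort (higher rank = better cognition); the per-mouse median of the eight
ranks is the composite cognitive rank.

Measures
--------
training period (days 1-6, three trials per day, day is the predictor):
    latency_intercept, latency_slope : Tobit regression of -log(latency)
        with limits -log(240) (left) and -log(1)=0 (right)
    score_intercept, score_slope     : OLS of the cognitive score
test trials:
    probe_latency, probe_score       : day-7 probe trial, used as recorded
    retention_latency                : min of the day-11 and day-12 latencies
    retention_score                  : day-11 cognitive score

Ranking uses average ranks for ties.  A missing value gets rank 1 exactly;
when any value is missing, the observed values are ranked among themselves
and shifted up by one (ranks 2..), so missing never averages into an
observed tie block.  probe_latency and retention_latency are lower-is-better;
all other measures (the Tobit coefficients live on the -log scale) are
higher-is-better.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .tobit import TobitModel, TobitResults

__all__ = [
    "TRAINING_SCORES",
    "PROBE_SCORES",
    "MEASURES",
    "LOWER_IS_BETTER",
    "CognitiveRankResult",
    "load_trials",
    "fit_tobit_log_latency",
    "fit_linear_cognitive_score",
    "extract_eight_measures",
    "rank_measures",
    "composite_cognitive_rank",
    "cognitive_rank_pipeline",
]

#: legal strategy-score values (direct=1 ... random=0; probe has its own set)
TRAINING_SCORES = (0.0, 0.25, 0.5, 0.75, 1.0)
PROBE_SCORES = (0.0, 0.167, 0.5, 1.0)

MEASURES = (
    "latency_intercept",
    "latency_slope",
    "score_intercept",
    "score_slope",
    "probe_latency",
    "probe_score",
    "retention_latency",
    "retention_score",
)
LOWER_IS_BETTER = frozenset({"probe_latency", "retention_latency"})

TRIAL_COLUMNS = [
    "mouse_id", "phase", "day", "trial_index", "latency", "censored", "cognitive_score",
]


def load_trials(path: str | Path) -> pd.DataFrame:
    """Read a trials CSV and validate the record invariants."""
    df = pd.read_csv(path)
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trials file lacks column(s): {sorted(missing)}")
    df = df[TRIAL_COLUMNS].copy()
    df["censored"] = df["censored"].astype(bool)
    if (df["latency"] <= 0).any():
        raise ValueError("non-positive latency encountered")
    cens = df.loc[df["censored"], "latency"]
    if len(cens) and cens.nunique() > 1:
        raise ValueError("censored trials must all sit at the latency limit")
    return df


def fit_tobit_log_latency(
    trials: pd.DataFrame, censor_limit: float = 240.0
) -> TobitResults:
    """Tobit fit of -log(latency) on training day for one mouse.

    Censored trials (latency at the cap) enter as left-censored at
    -log(censor_limit); latencies at the 1 s floor are right-censored at 0.
    """
    if (trials["latency"] <= 0).any():
        raise ValueError("non-positive latency")
    days = trials["day"].to_numpy(dtype=float)
    if len(np.unique(days)) < 2:
        raise ValueError("need trials on >= 2 distinct days")
    y = -np.log(trials["latency"].to_numpy(dtype=float))
    lower = -np.log(censor_limit)
    upper = 0.0
    X = np.column_stack([np.ones_like(days), days])
    model = TobitModel(
        y, X,
        lower=lower, upper=upper,
        left_censored=trials["censored"].to_numpy(dtype=bool),
        exog_names=("intercept", "day"),
    )
    return model.fit()


def fit_linear_cognitive_score(trials: pd.DataFrame) -> tuple[float, float]:
    """OLS of the cognitive score on training day -> (intercept, slope)."""
    days = trials["day"].to_numpy(dtype=float)
    if len(np.unique(days)) < 2:
        raise ValueError("need trials on >= 2 distinct days")
    scores = trials["cognitive_score"].to_numpy(dtype=float)
    slope, intercept = np.polyfit(days, scores, 1)
    return float(intercept), float(slope)


def extract_eight_measures(trials: pd.DataFrame,
                           censor_limit: float = 240.0) -> pd.DataFrame:
    """Per-mouse table of the eight behavioral measures (NaN = missing)."""
    rows = {}
    for mouse, sub in trials.groupby("mouse_id", sort=True):
        m = dict.fromkeys(MEASURES, np.nan)
        training = sub[sub["phase"] == "training"]
        if training["day"].nunique() >= 2:
            fit = fit_tobit_log_latency(training, censor_limit)
            if fit.converged:
                m["latency_intercept"] = fit.intercept
                m["latency_slope"] = fit.slope
            intercept, slope = fit_linear_cognitive_score(training)
            m["score_intercept"] = intercept
            m["score_slope"] = slope
        probe = sub[sub["phase"] == "probe"]
        if len(probe):
            m["probe_latency"] = float(probe["latency"].iloc[0])
            m["probe_score"] = float(probe["cognitive_score"].iloc[0])
        r11 = sub[sub["phase"] == "retention11"]
        r12 = sub[sub["phase"] == "retention12"]
        lat = [float(r["latency"].iloc[0]) for r in (r11, r12) if len(r)]
        if lat:
            m["retention_latency"] = min(lat)
        if len(r11):
            m["retention_score"] = float(r11["cognitive_score"].iloc[0])
        rows[mouse] = m
    return pd.DataFrame.from_dict(rows, orient="index")[list(MEASURES)]


def _rank_column(values: pd.Series, lower_is_better: bool) -> pd.Series:
    """Rank one measure 1..n, higher = better; missing -> rank 1 exactly."""
    x = values.to_numpy(dtype=float)
    if lower_is_better:
        x = -x
    out = np.ones(len(x))
    observed = ~np.isnan(x)
    if observed.any():
        ranks = stats.rankdata(x[observed], method="average")
        offset = 1.0 if (~observed).any() else 0.0
        out[observed] = ranks + offset
    return pd.Series(out, index=values.index)


def rank_measures(measures: pd.DataFrame) -> pd.DataFrame:
    """Within-cohort ranks for all eight measures."""
    if len(measures) < 2:
        raise ValueError("cohort must contain at least two mice")
    return pd.DataFrame(
        {c: _rank_column(measures[c], c in LOWER_IS_BETTER) for c in measures.columns},
        index=measures.index,
    )


@dataclass
class CognitiveRankResult:
    ranks: pd.DataFrame       # mice x eight measures
    composite: pd.Series      # per-mouse median of the eight ranks
    n_cohort: int


def composite_cognitive_rank(ranks: pd.DataFrame) -> CognitiveRankResult:
    """Median of the eight per-measure ranks for each mouse."""
    composite = ranks.median(axis=1)
    return CognitiveRankResult(ranks=ranks, composite=composite, n_cohort=len(ranks))


def cognitive_rank_pipeline(
    trials: pd.DataFrame, censor_limit: float = 240.0
) -> CognitiveRankResult:
    """trials -> measures -> ranks -> composite, in one call."""
    measures = extract_eight_measures(trials, censor_limit)
    return composite_cognitive_rank(rank_measures(measures))
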