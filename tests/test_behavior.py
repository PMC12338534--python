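import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cograte.behavior import (
    composite_cognitive_rank,
    cognitive_rank_pipeline,
    extract_eight_measures,
    fit_linear_cognitive_score,
    fit_tobit_log_latency,
    rank_measures,
)
from cograte.simulate import SimCohortConfig, simulate_barnes_maze
from cograte.tobit import TobitModel


# -- Tobit regression -------------------------------------------------------


def test_tobit_recovers_exact_line_without_censoring():
    days = np.repeat(np.arange(1, 7), 3).astype(float)
    y = 1.0 + 0.5 * days
    X = np.column_stack([np.ones_like(days), days])
    fit = TobitModel(y, X).fit()
    assert fit.converged
    assert fit.intercept == pytest.approx(1.0, abs=1e-5)
    assert fit.slope == pytest.approx(0.5, abs=1e-5)


def test_left_censored_point_contributes_lower_tail():
    # single censored observation at -log(240): loglik must equal log Phi((L-mu)/sigma)
    L = -np.log(240.0)
    days = np.array([1.0, 2.0, 3.0])
    y = np.array([L, -3.0, -2.0])
    X = np.column_stack([np.ones_like(days), days])
    model = TobitModel(y, X, lower=L, upper=0.0,
                       left_censored=np.array([True, False, False]))
    params = np.array([-4.0, 0.5, np.log(0.8)])
    mu = X @ params[:2]
    expected = (
        stats.norm.logcdf((L - mu[0]) / 0.8)
        + stats.norm.logpdf((y[1] - mu[1]) / 0.8) - np.log(0.8)
        + stats.norm.logpdf((y[2] - mu[2]) / 0.8) - np.log(0.8)
    )
    assert model.loglike(params) == pytest.approx(expected, abs=1e-12)
    assert L == pytest.approx(-5.4806, abs=1e-4)


def test_tobit_equals_ols_when_uncensored(training_trials):
    fit = fit_tobit_log_latency(training_trials)
    days = training_trials["day"].to_numpy(float)
    slope, intercept = np.polyfit(days, -np.log(training_trials["latency"]), 1)
    assert fit.converged
    assert fit.intercept == pytest.approx(intercept, abs=1e-6)
    assert fit.slope == pytest.approx(slope, abs=1e-6)


def test_all_censored_flagged_not_converged():
    trials = pd.DataFrame(
        {
            "day": np.repeat(np.arange(1, 7), 3).astype(float),
            "latency": 240.0,
            "censored": True,
        }
    )
    fit = fit_tobit_log_latency(trials)
    assert not fit.converged


def test_nonpositive_latency_is_input_error():
    trials = pd.DataFrame({"day": [1.0, 2.0], "latency": [0.0, 5.0], "censored": False})
    with pytest.raises(ValueError, match="latency"):
        fit_tobit_log_latency(trials)


# -- linear cognitive-score fit --------------------------------------------


@pytest.mark.parametrize(
    "days,scores,intercept,slope",
    [
        ([1, 2, 3, 4], [0.5, 0.5, 0.5, 0.5], 0.5, 0.0),
        ([1, 2, 3, 4, 5, 6], [0.1, 0.2, 0.3, 0.4, 0.5, 0.6], 0.0, 0.1),
        ([1, 1, 2, 2], [0.0, 0.25, 0.5, 0.75], -0.375, 0.5),
    ],
)
def test_linear_score_fit_known_lines(days, scores, intercept, slope):
    trials = pd.DataFrame({"day": days, "cognitive_score": scores})
    b0, b1 = fit_linear_cognitive_score(trials)
    assert b0 == pytest.approx(intercept, abs=1e-10)
    assert b1 == pytest.approx(slope, abs=1e-10)


def test_single_day_raises():
    trials = pd.DataFrame({"day": [1, 1], "cognitive_score": [0.5, 0.75]})
    with pytest.raises(ValueError, match="distinct days"):
        fit_linear_cognitive_score(trials)


# -- eight measures ---------------------------------------------------------


def _trial(mouse, phase, day, latency, score, censored=False, trial_index=1):
    return {
        "mouse_id": mouse, "phase": phase, "day": day, "trial_index": trial_index,
        "latency": latency, "censored": censored, "cognitive_score": score,
    }


def test_retention_uses_best_of_both_days_and_day11_score(training_trials):
    extra = pd.DataFrame(
        [
            _trial("m1", "probe", 7, 30.0, 0.5),
            _trial("m1", "retention11", 11, 120.0, 0.75),
            _trial("m1", "retention12", 12, 80.0, 0.25),
        ]
    )
    trials = pd.concat([training_trials, extra], ignore_index=True)
    measures = extract_eight_measures(trials)
    assert measures.loc["m1", "retention_latency"] == 80.0
    assert measures.loc["m1", "retention_score"] == 0.75
    assert measures.loc["m1"].notna().all()  # exactly 8 non-missing


def test_absent_probe_yields_missing_probe_measures(training_trials):
    measures = extract_eight_measures(training_trials)
    assert np.isnan(measures.loc["m1", "probe_latency"])
    assert np.isnan(measures.loc["m1", "probe_score"])


# -- ranking and composite --------------------------------------------------


def _measures_frame(**columns):
    base = {c: [np.nan] * len(next(iter(columns.values()))) for c in (
        "latency_intercept", "latency_slope", "score_intercept", "score_slope",
        "probe_latency", "probe_score", "retention_latency", "retention_score")}
    base.update(columns)
    return pd.DataFrame(base, index=[f"m{i}" for i in range(len(next(iter(columns.values()))))])


def test_tied_scores_get_average_rank():
    ranks = rank_measures(_measures_frame(probe_score=[0.2, 0.2, 0.9]))
    assert list(ranks["probe_score"]) == [1.5, 1.5, 3.0]


def test_latency_measures_are_lower_is_better():
    ranks = rank_measures(_measures_frame(probe_latency=[240.0, 10.0, 100.0]))
    assert list(ranks["probe_latency"]) == [1.0, 3.0, 2.0]


def test_missing_gets_minimum_rank_exactly():
    ranks = rank_measures(_measures_frame(score_slope=[np.nan, 5.0, 7.0]))
    assert list(ranks["score_slope"]) == [1.0, 2.0, 3.0]


def test_two_missing_share_rank_one():
    ranks = rank_measures(_measures_frame(score_slope=[np.nan, np.nan, 5.0, 7.0]))
    assert list(ranks["score_slope"]) == [1.0, 1.0, 2.0, 3.0]


def test_composite_is_median_of_eight():
    ranks = pd.DataFrame(
        [np.full(8, 42.0), np.arange(1.0, 9.0)],
        index=["a", "b"],
        columns=list(_measures_frame(probe_score=[0]).columns),
    )
    result = composite_cognitive_rank(ranks)
    assert result.composite["a"] == 42.0
    assert result.composite["b"] == 4.5


def test_composite_invariant_under_monotone_transforms():
    cfg = SimCohortConfig(seed=5)
    trials, _ = simulate_barnes_maze(cfg)
    measures = extract_eight_measures(trials)
    baseline = composite_cognitive_rank(rank_measures(measures)).composite
    rng = np.random.default_rng(0)
    for col in measures.columns:
        transformed = measures.copy()
        x = transformed[col]
        uniq = np.sort(x.dropna().unique())
        # random strictly-increasing map over the unique observed values
        mapping = dict(zip(uniq, np.cumsum(rng.uniform(0.1, 2.0, size=len(uniq)))))
        transformed[col] = x.map(mapping)
        composite = composite_cognitive_rank(rank_measures(transformed)).composite
        pd.testing.assert_series_equal(composite, baseline)


def test_rank_recovers_latent_ability():
    cfg = SimCohortConfig(seed=1)
    trials, truth = simulate_barnes_maze(cfg)
    result = cognitive_rank_pipeline(trials)
    ability = truth.set_index("mouse_id").loc[result.composite.index, "ability"]
    rho = stats.spearmanr(result.composite, ability).statistic
    assert rho >= 0.8


def test_cohort_of_one_rejected():
    with pytest.raises(ValueError, match="two mice"):
        rank_measures(_measures_frame(probe_score=[0.5]))
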