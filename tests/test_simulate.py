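import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cograte.metmodel import read_model, write_model_sbml
from cograte.simulate import (
    SimCohortConfig,
    SimOmicsConfig,
    simulate_barnes_maze,
    simulate_cpg_table,
    simulate_metabolic_models,
    simulate_omics_layers,
    simulate_taxon_abundance,
)
from cograte.preprocess import aggregate_promoter_methylation


# -- Barnes-maze cohort -----------------------------------------------------


def test_latency_clamped_and_censoring_flag_consistent():
    trials, _ = simulate_barnes_maze(SimCohortConfig(seed=1))
    assert trials["latency"].between(1.0, 240.0).all()
    assert (trials["censored"] == (trials["latency"] == 240.0)).all()


def test_scores_drawn_from_legal_sets():
    trials, _ = simulate_barnes_maze(SimCohortConfig(seed=4))
    training = trials[trials["phase"] != "probe"]
    assert set(training["cognitive_score"]) <= {0.0, 0.25, 0.5, 0.75, 1.0}
    probe = trials[trials["phase"] == "probe"]
    assert set(probe["cognitive_score"]) <= {0.0, 0.167, 0.5, 1.0}


def test_noise_free_positive_slopes_give_monotone_latencies():
    cfg = SimCohortConfig(seed=2, noise_sd=1e-9, intercept_sd=0.0, slope_sd=0.0)
    trials, _ = simulate_barnes_maze(cfg)
    training = trials[trials["phase"] == "training"]
    for _, sub in training.groupby("mouse_id"):
        daily = sub.groupby("day")["latency"].first()
        assert (np.diff(daily.to_numpy()) <= 1e-9).all()


def test_censoring_rate_matches_analytic_normal_tail():
    cfg = SimCohortConfig(seed=1)
    trials, truth = simulate_barnes_maze(cfg)
    training = trials[trials["phase"] == "training"]
    L = -np.log(cfg.censor_limit)
    # closed-form probability under the realized per-mouse latent parameters
    probs = []
    for row in truth.itertuples(index=False):
        for day in range(1, 7):
            mu = row.intercept + row.slope * day
            probs.extend([stats.norm.cdf((L - mu) / cfg.noise_sd)] * 3)
    probs = np.asarray(probs)
    expected = probs.sum()
    sd = np.sqrt((probs * (1 - probs)).sum())
    observed = training["censored"].sum()
    assert abs(observed - expected) <= 3 * sd


def test_group_size_mismatch_is_config_error():
    with pytest.raises(ValueError, match="n_mice"):
        SimCohortConfig(n_mice=80)


def test_cohort_generator_deterministic():
    t1, u1 = simulate_barnes_maze(SimCohortConfig(seed=9))
    t2, u2 = simulate_barnes_maze(SimCohortConfig(seed=9))
    pd.testing.assert_frame_equal(t1, t2)
    pd.testing.assert_frame_equal(u1, u2)


# -- omics layers -----------------------------------------------------------


def _rank(n=80):
    return pd.Series(np.arange(n, dtype=float), index=[f"s{i}" for i in range(n)])


def test_effect_size_one_gives_perfect_monotone_association():
    cfg = SimOmicsConfig(
        n_features_per_layer={"la": 20}, n_planted=3, effect_size=1.0,
        missing_sample_fraction=0.0, seed=0,
    )
    layers, registry = simulate_omics_layers(cfg, _rank())
    for fid in registry["feature_id"]:
        rho = stats.spearmanr(layers["la"].loc[fid], _rank()).statistic
        assert abs(rho) == pytest.approx(1.0, abs=1e-12)


def _max_abs_spearman(features: np.ndarray, target: np.ndarray) -> float:
    """max_j |spearman(features[j], target)| via rank-Pearson (no ties)."""
    r_t = stats.rankdata(target)
    r_t = (r_t - r_t.mean()) / r_t.std()
    r_f = np.apply_along_axis(stats.rankdata, 1, features)
    r_f = (r_f - r_f.mean(axis=1, keepdims=True)) / r_f.std(axis=1, keepdims=True)
    return float(np.abs(r_f @ r_t / len(target)).max())


def test_no_planting_matches_monte_carlo_null():
    n = 80
    cfg = SimOmicsConfig(
        n_features_per_layer={"la": 200}, n_planted=0, effect_size=0.6,
        missing_sample_fraction=0.0, seed=1,
    )
    layers, registry = simulate_omics_layers(cfg, _rank(n))
    assert registry.empty
    observed = _max_abs_spearman(layers["la"].to_numpy(), _rank(n).to_numpy())
    # Monte-Carlo null: distribution of max |rho| over 200 independent features
    rng = np.random.default_rng(0)
    null = [
        _max_abs_spearman(rng.normal(size=(200, n)), np.arange(n, dtype=float))
        for _ in range(100)
    ]
    assert observed <= np.quantile(null, 0.99) + 0.05


def test_methylation_layers_bounded_expression_nonnegative():
    cfg = SimOmicsConfig(
        n_features_per_layer={"la_meth": 30, "lb_expr": 30}, n_planted=4,
        effect_size=0.5, missing_sample_fraction=0.0, seed=2,
    )
    layers, _ = simulate_omics_layers(cfg, _rank())
    meth = layers["la_meth"].to_numpy()
    assert ((meth >= 0) & (meth <= 1)).all()
    assert (layers["lb_expr"].to_numpy() > 0).all()


def test_planted_effect_size_converges_at_large_n():
    n = 500
    rank = pd.Series(np.arange(n, dtype=float), index=[f"s{i}" for i in range(n)])
    cfg = SimOmicsConfig(
        n_features_per_layer={"la": 40}, n_planted=10, effect_size=0.6,
        missing_sample_fraction=0.0, seed=3,
    )
    layers, registry = simulate_omics_layers(cfg, rank)
    rhos = [
        abs(stats.spearmanr(layers["la"].loc[f], rank).statistic)
        for f in registry["feature_id"]
    ]
    assert abs(np.mean(rhos) - 0.6) <= 0.05


def test_effect_size_validation():
    with pytest.raises(ValueError, match="effect_size"):
        SimOmicsConfig(effect_size=1.2)


# -- metabolic model fixtures ----------------------------------------------


def test_generated_truth_ranges_are_ordered():
    models, truth = simulate_metabolic_models(8, seed=0)
    assert len(models) == 8
    for model in models:
        tr = truth[model.model_id]
        assert (tr["min"] <= tr["max"] + 1e-12).all()
        assert len(model.reactions) <= 30


def test_branch_motif_hand_lp():
    # taxon02 is the branch motif; capacities a+b give the growth optimum and
    # both branches stay non-degenerate at the 99% threshold
    models, truth = simulate_metabolic_models(2, seed=0)
    branch = models[1]
    cap_a = branch.reaction("branch1").upper_bound
    cap_b = branch.reaction("branch2").upper_bound
    tr = truth[branch.model_id]
    assert tr.attrs["max_growth"] == pytest.approx(cap_a + cap_b, abs=1e-9)
    for rid in ("branch1", "branch2"):
        lo, hi = tr.loc[rid, "min"], tr.loc[rid, "max"]
        assert hi - lo > 1e-6
    assert tr.loc["branch1", "max"] == pytest.approx(cap_a, abs=1e-8)
    assert tr.loc["branch2", "max"] == pytest.approx(cap_b, abs=1e-8)


def test_sbml_roundtrip_of_generated_models(tmp_path):
    models, _ = simulate_metabolic_models(4, seed=5)
    for model in models:
        path = tmp_path / f"{model.model_id}.xml"
        write_model_sbml(model, path)
        back = read_model(path)
        assert len(back.reactions) == len(model.reactions)
        for rid in model.reaction_ids:
            assert back.reaction(rid).stoichiometry == model.reaction(rid).stoichiometry
            assert back.reaction(rid).lower_bound == model.reaction(rid).lower_bound


def test_taxon_abundance_columns_sum_to_one():
    ab = simulate_taxon_abundance(["a", "b", "c"], ["s1", "s2"], seed=0)
    assert np.allclose(ab.sum(axis=0), 1.0)
    assert (ab.values >= 0).all()


# -- CpG table --------------------------------------------------------------


def test_cpg_table_deterministic_and_bounded(tmp_path):
    c1, t1 = simulate_cpg_table(5, seed=3)
    c2, t2 = simulate_cpg_table(5, seed=3)
    pd.testing.assert_frame_equal(c1, c2)
    pd.testing.assert_frame_equal(t1, t2)
    values = c1.drop(columns=["chrom", "pos", "strand"]).to_numpy()
    assert ((values >= 0) & (values <= 1) | np.isnan(values)).all()


def test_cpg_fixture_feeds_promoter_aggregation():
    cpg, tss = simulate_cpg_table(6, seed=1)
    out = aggregate_promoter_methylation(cpg, tss)
    assert not out.empty
    assert out.to_numpy().min() >= 0 and out.to_numpy().max() <= 1
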