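import numpy as np
import pandas as pd
import pytest

from cograte.preprocess import (
    NZVParams,
    aggregate_promoter_methylation,
    intersect_complete_samples,
    near_zero_var_filter,
    read_tss_bed,
)
from cograte.simulate import SimCohortConfig, SimOmicsConfig, simulate_barnes_maze, simulate_omics_layers
from cograte.behavior import cognitive_rank_pipeline


def _matrix(rows: dict) -> pd.DataFrame:
    return pd.DataFrame.from_dict(rows, orient="index")


def test_nzv_hand_classified_cases():
    n = 100
    rows = {
        "constant": np.ones(n),
        # 95 zeros, 4 ones, 1 two: ratio 23.75 > 19 and 3% unique < 10%
        "dominated": np.r_[np.zeros(95), np.ones(4), [2.0]],
        "increasing": np.arange(n, dtype=float),
        # ratio 90/10 = 9 < 19: retained despite low uniqueness
        "two_valued": np.r_[np.zeros(90), np.ones(10)],
    }
    kept, report = near_zero_var_filter(_matrix(rows))
    assert set(kept.index) == {"increasing", "two_valued"}
    assert report.loc["dominated", "freq_ratio"] == pytest.approx(23.75)
    assert report.loc["dominated", "percent_unique"] == pytest.approx(3.0)
    assert np.isinf(report.loc["constant", "freq_ratio"])


def test_nzv_idempotent():
    rng = np.random.default_rng(0)
    m = pd.DataFrame(rng.integers(0, 3, size=(50, 40)).astype(float))
    once, _ = near_zero_var_filter(m)
    twice, _ = near_zero_var_filter(once)
    pd.testing.assert_frame_equal(once, twice)


def test_nzv_params_validation():
    with pytest.raises(ValueError):
        NZVParams(freq_cut=0.5)
    with pytest.raises(ValueError):
        NZVParams(unique_cut=0)


# -- promoter aggregation ---------------------------------------------------


def _cpg(rows, samples):
    df = pd.DataFrame(rows, columns=["chrom", "pos"] + list(samples))
    return df


def test_singleton_cpg_mean(tmp_path):
    cpg = _cpg([["chr1", 1010, 0.8]], ["s1"])
    tss = pd.DataFrame(
        [["chr1", 1000, 1001, "g1", "+"]],
        columns=["chrom", "start", "end", "name", "strand"],
    )
    out = aggregate_promoter_methylation(cpg, tss)
    assert out.loc["g1", "s1"] == pytest.approx(0.8)


def test_two_cpg_hand_mean_and_window_membership():
    # CpGs at TSS+500 and TSS-500 average to 0.4; TSS+1000 is outside [T-1000, T+1000)
    cpg = _cpg(
        [["chr1", 10500, 0.2], ["chr1", 9500, 0.6], ["chr1", 11000, 1.0]], ["s1"]
    )
    tss = pd.DataFrame(
        [["chr1", 10000, 10001, "g1", "+"]],
        columns=["chrom", "start", "end", "name", "strand"],
    )
    out = aggregate_promoter_methylation(cpg, tss)
    assert out.loc["g1", "s1"] == pytest.approx(0.4)


def test_all_cpgs_outside_windows_gives_empty_matrix():
    cpg = _cpg([["chr1", 50000, 0.5]], ["s1"])
    tss = pd.DataFrame(
        [["chr1", 10000, 10001, "g1", "+"]],
        columns=["chrom", "start", "end", "name", "strand"],
    )
    out = aggregate_promoter_methylation(cpg, tss)
    assert out.empty


def test_gene_uncovered_in_one_sample_dropped_cohort_wide():
    cpg = _cpg(
        [["chr1", 10010, 0.5, np.nan], ["chr1", 20010, 0.3, 0.7]], ["s1", "s2"]
    )
    tss = pd.DataFrame(
        [
            ["chr1", 10000, 10001, "g1", "+"],
            ["chr1", 20000, 20001, "g2", "+"],
        ],
        columns=["chrom", "start", "end", "name", "strand"],
    )
    out = aggregate_promoter_methylation(cpg, tss)
    assert list(out.index) == ["g2"]


def test_aggregation_invariant_to_row_order_and_strand():
    samples = ["s1", "s2"]
    rows = [["chr1", 9990, 0.1, 0.9], ["chr1", 10800, 0.5, 0.3]]
    tss_fwd = pd.DataFrame(
        [["chr1", 10000, 10001, "g1", "+"]],
        columns=["chrom", "start", "end", "name", "strand"],
    )
    tss_rev = tss_fwd.assign(strand="-")
    a = aggregate_promoter_methylation(_cpg(rows, samples), tss_fwd)
    b = aggregate_promoter_methylation(_cpg(rows[::-1], samples), tss_rev)
    pd.testing.assert_frame_equal(a, b)


def test_read_tss_bed_rejects_malformed(tmp_path):
    path = tmp_path / "bad.bed"
    path.write_text("chr1\t100\n")
    with pytest.raises(ValueError, match="bad.bed:1"):
        read_tss_bed(path)


# -- complete-case intersection --------------------------------------------


def test_intersection_keeps_common_samples_only():
    layers = {
        "a": pd.DataFrame(np.ones((2, 3)), columns=["A", "B", "C"]),
        "b": pd.DataFrame(np.ones((2, 3)), columns=["B", "C", "D"]),
    }
    rank = pd.Series([1.0, 2.0, 3.0, 4.0], index=["A", "B", "C", "D"])
    aligned, aligned_rank = intersect_complete_samples(layers, rank)
    for layer in aligned.values():
        assert list(layer.columns) == ["B", "C"]
    assert list(aligned_rank.index) == ["B", "C"]


def test_empty_intersection_raises():
    layers = {
        "a": pd.DataFrame(np.ones((1, 2)), columns=["A", "B"]),
        "b": pd.DataFrame(np.ones((1, 2)), columns=["C", "D"]),
    }
    rank = pd.Series([1.0, 2.0], index=["A", "C"])
    with pytest.raises(ValueError, match="no sample"):
        intersect_complete_samples(layers, rank)


def test_cohort_83_minus_9_withheld_retains_74():
    cfg = SimCohortConfig(seed=2)
    trials, _ = simulate_barnes_maze(cfg)
    rank = cognitive_rank_pipeline(trials).composite
    omics = SimOmicsConfig(seed=3)  # default withholds round(9/83*83)=9 samples
    layers, _ = simulate_omics_layers(omics, rank)
    aligned, aligned_rank = intersect_complete_samples(layers, rank)
    assert len(aligned_rank) == 74
    for layer in aligned.values():
        assert layer.shape[1] == 74
        assert not layer.isna().any().any()
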