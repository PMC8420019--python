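"""Coverage filtering, level binning, BH correction and the differential
methylation tests at site, window and island resolution."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from oracle_utils import fisher_two_sided_oracle, step_up_bh_oracle

import devhypoxia as dh
from devhypoxia.genome import partition_features
from devhypoxia.methylation import (
    bh_fdr,
    bin_methylation_levels,
    diff_cpg_test,
    filter_coverage,
    grouped_binomial_lrt,
    island_methylation_and_test,
    methylation_bin_percentages,
    sliding_window_dmr,
)


# ---------------------------------------------------------------------------
# Coverage filter
# ---------------------------------------------------------------------------

def test_filter_requires_two_covered_replicates_per_group(toy_matrix):
    matrix, groups = toy_matrix
    filt = filter_coverage(matrix, groups, min_cov=10, min_samples=2)
    # site 0: group a totals (12,9,11) ok, group b (15,10,0) ok -> retained
    # site 1: group a totals (9,9,12) only one >= 10 -> dropped
    assert filt.sites["pos"].tolist() == [10, 120, 300]


def test_filter_zero_mincov_is_identity(toy_matrix):
    matrix, groups = toy_matrix
    assert filter_coverage(matrix, groups, min_cov=0).n_sites == matrix.n_sites


def test_filter_monotone_in_min_cov(toy_matrix):
    matrix, groups = toy_matrix
    sizes = [
        filter_coverage(matrix, groups, min_cov=c).n_sites for c in (0, 5, 10, 20, 40)
    ]
    assert sizes == sorted(sizes, reverse=True)


def test_filter_rejects_undersized_group(toy_matrix):
    matrix, _ = toy_matrix
    groups = {s: ("a" if s == "a1" else "b") for s in matrix.samples}
    with pytest.raises(ValueError, match="fewer than min_samples"):
        filter_coverage(matrix, groups, min_samples=2)


# ---------------------------------------------------------------------------
# Level binning
# ---------------------------------------------------------------------------

def test_bin_percentage_formula_on_count_table():
    counts = pd.DataFrame(
        {
            "0-25%": [589_261, 13_500],
            "25-50%": [1_149_789, 5_950],
            "50-75%": [3_112_308, 12_777],
            "75-100%": [7_988_953, 35_941],
        },
        index=["intergenic", "promoter"],
    )
    pct = methylation_bin_percentages(counts).round(1)
    # 1,149,789/12,840,311 = 8.954% -> 9.0 at one decimal
    assert pct.loc["intergenic"].tolist() == [4.6, 9.0, 24.2, 62.2]
    assert pct.loc["promoter"].tolist() == [19.8, 8.7, 18.7, 52.7]


def test_boundary_levels_fall_in_upper_bin(small_dataset):
    """A site at exactly 75% methylation lands in the 75-100 bin, and a
    fully unmethylated matrix is 100% in the first bin."""
    sites = pd.DataFrame({"chrom": ["chr1"] * 2, "pos": [10, 20]})
    matrix = dh.CpGSiteMatrix(
        sites, np.array([[3], [0]]), np.array([[4], [8]]), ["s1"]
    )
    part = partition_features(small_dataset["annotation"])
    table = bin_methylation_levels(matrix, part)
    assert table.loc["intergenic", "75-100%"] == 1
    assert table.loc["intergenic", "0-25%"] == 1


def test_binned_rows_sum_to_feature_totals(small_dataset):
    part = partition_features(small_dataset["annotation"])
    table = bin_methylation_levels(small_dataset["matrix"], part)
    bins = ["0-25%", "25-50%", "50-75%", "75-100%"]
    assert (table[bins].sum(axis=1) == table["total"]).all()
    sub = ["first_exon", "remaining_exons", "intron"]
    assert table.loc[sub, "total"].sum() == table.loc["gene_body", "total"]
    # gene bodies are heavily methylated by construction
    assert table.loc["gene_body", "75-100%"] / table.loc["gene_body", "total"] > 0.5


# ---------------------------------------------------------------------------
# BH
# ---------------------------------------------------------------------------

def test_bh_step_up_hand_example():
    np.testing.assert_allclose(
        bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
    )
    np.testing.assert_allclose(bh_fdr([0.3]), [0.3])


def test_bh_matches_step_up_oracle_on_random_vectors():
    rng = np.random.default_rng(0)
    for n in (1, 2, 10, 101):
        p = rng.random(n)
        np.testing.assert_allclose(bh_fdr(p), step_up_bh_oracle(p), atol=1e-12)


def test_bh_dominates_p_and_rejects_bad_input():
    rng = np.random.default_rng(1)
    p = rng.random(50)
    q = bh_fdr(p)
    assert (q >= p - 1e-12).all()
    order = np.argsort(p)
    assert (np.diff(q[order]) >= -1e-12).all()
    with pytest.raises(ValueError):
        bh_fdr([0.5, 1.5])


# ---------------------------------------------------------------------------
# Per-CpG test
# ---------------------------------------------------------------------------

def test_identical_counts_give_null_result(toy_matrix):
    matrix, groups = toy_matrix
    calls = diff_cpg_test(matrix, groups)
    row = calls[calls["pos"] == 300].iloc[0]
    assert row["stat"] == 0.0
    assert row["p"] == 1.0
    assert row["delta"] == 0.0
    assert not row["significant"]


def test_extreme_site_beats_fisher_oracle(toy_matrix):
    """Pooled 30/30 methylated vs 0/30: the Fisher oracle on 10/10 vs 0/10
    gives p = 2/184756; the LRT p must clear the 0.01 threshold too."""
    assert fisher_two_sided_oracle(10, 0, 0, 10) == pytest.approx(
        2 / 184_756, rel=1e-9
    )
    matrix, groups = toy_matrix
    calls = diff_cpg_test(matrix, groups)
    row = calls[calls["pos"] == 120].iloc[0]
    assert row["delta"] == 100.0
    assert row["p"] < 0.01


def test_group_label_swap_preserves_p_flips_direction(toy_matrix):
    matrix, groups = toy_matrix
    swapped = {s: ("b" if g == "a" else "a") for s, g in groups.items()}
    a = diff_cpg_test(matrix, groups)
    b = diff_cpg_test(matrix, swapped)
    np.testing.assert_allclose(a["p"], b["p"])
    flip = {"hyper": "hypo", "hypo": "hyper", "none": "none"}
    assert [flip[d] for d in a["direction"]] == list(b["direction"])


def test_null_simulation_fdr_controlled():
    """With no planted differences, very few sites reach q < 0.01."""
    cfg = dh.SimulationConfig(
        seed=21, chrom_length=300_000, n_genes=20, n_planted_islands=0,
        planted_dm_fraction=0.0,
    )
    genome, ann, _ = dh.simulate_genome_and_annotation(cfg)
    matrix, groups, truth = dh.simulate_methylome(cfg, genome, ann)
    assert truth.empty
    filt = filter_coverage(matrix, groups)
    calls = diff_cpg_test(filt, groups)
    assert (calls["q"] < 0.01).mean() <= 0.02


def test_lrt_matches_proportion_test_on_large_counts():
    """On big balanced tables the grouped-binomial LRT agrees with the
    classic two-proportion chi-square to a few percent."""
    m1, t1, m2, t2 = 400, 1000, 500, 1000
    stat, p, _, _ = grouped_binomial_lrt(m1, t1, m2, t2)
    chi2_stat = stats.chi2_contingency(
        [[m1, t1 - m1], [m2, t2 - m2]], correction=False
    )[0]
    assert stat == pytest.approx(chi2_stat, rel=0.02)


# ---------------------------------------------------------------------------
# Sliding windows
# ---------------------------------------------------------------------------

def test_windows_tile_on_step_grid(small_dataset):
    calls = sliding_window_dmr(small_dataset["matrix"], small_dataset["groups"])
    assert (calls["start"] % 50 == 0).all()
    assert ((calls["end"] - calls["start"]) == 200).all()
    assert (calls["n_sites"] > 0).all()


def test_empty_windows_absent():
    sites = pd.DataFrame({"chrom": ["chr1"] * 2, "pos": [100, 5000]})
    matrix = dh.CpGSiteMatrix(
        sites, np.array([[5, 5], [5, 5]]), np.array([[10, 10], [10, 10]]), ["a1", "b1"]
    )
    groups = {"a1": "a", "b1": "b"}
    calls = sliding_window_dmr(matrix, groups)
    # site at 100 covered by windows starting 0..100, site at 5000 by 4850..5000
    assert calls["start"].min() == 0
    assert set(calls["start"]) == {0, 50, 100, 4850, 4900, 4950, 5000}


def test_each_site_contributes_to_four_windows():
    sites = pd.DataFrame({"chrom": ["chr1"], "pos": [1000]})
    matrix = dh.CpGSiteMatrix(
        sites, np.array([[5, 5]]), np.array([[10, 10]]), ["a1", "b1"]
    )
    calls = sliding_window_dmr(matrix, {"a1": "a", "b1": "b"})
    assert len(calls) == 4  # 200-bp windows at 50-bp steps covering pos 1000


# ---------------------------------------------------------------------------
# Island test
# ---------------------------------------------------------------------------

def _island_df(start, end):
    return pd.DataFrame({"chrom": ["chr1"], "start": [start], "end": [end]})


def test_island_level_is_read_pooled_fraction():
    sites = pd.DataFrame({"chrom": ["chr1"] * 2, "pos": [10, 20]})
    meth = np.array([[5, 5], [10, 10]])
    total = np.array([[10, 10], [10, 10]])
    matrix = dh.CpGSiteMatrix(sites, meth, total, ["a1", "b1"])
    out = island_methylation_and_test(matrix, _island_df(0, 100), {"a1": "a", "b1": "b"})
    assert out["level_a"].iloc[0] == pytest.approx(0.75)  # (5+10)/(10+10)
    assert out["level_b"].iloc[0] == pytest.approx(0.75)
    assert out["p"].iloc[0] == 1.0


def test_island_fisher_matches_enumeration():
    sites = pd.DataFrame({"chrom": ["chr1"], "pos": [10]})
    matrix = dh.CpGSiteMatrix(
        sites, np.array([[5, 0]]), np.array([[5, 5]]), ["a1", "b1"]
    )
    out = island_methylation_and_test(matrix, _island_df(0, 100), {"a1": "a", "b1": "b"})
    assert out["p"].iloc[0] == pytest.approx(2 / 252, rel=1e-9)
    assert out["p"].iloc[0] == pytest.approx(
        fisher_two_sided_oracle(5, 0, 0, 5), rel=1e-9
    )


def test_island_without_coverage_excluded():
    sites = pd.DataFrame({"chrom": ["chr1"] * 2, "pos": [10, 500]})
    meth = np.array([[3, 4], [0, 0]])
    total = np.array([[10, 10], [0, 0]])
    matrix = dh.CpGSiteMatrix(sites, meth, total, ["a1", "b1"])
    islands = pd.DataFrame(
        {"chrom": ["chr1", "chr1"], "start": [0, 400], "end": [100, 600]}
    )
    with pytest.warns(UserWarning, match="excluded"):
        out = island_methylation_and_test(matrix, islands, {"a1": "a", "b1": "b"})
    assert len(out) == 1


def test_island_level_equals_weighted_site_mean(small_dataset):
    """Pooling consistency: the island level equals the coverage-weighted
    mean of its site levels."""
    matrix = small_dataset["matrix"]
    groups = small_dataset["groups"]
    islands = small_dataset["islands"]
    out = island_methylation_and_test(matrix, islands, groups)
    gidx = matrix.group_indices(groups)
    for _, r in out.head(5).iterrows():
        sel = (
            (matrix.sites["chrom"] == r["chrom"])
            & (matrix.sites["pos"] >= r["start"])
            & (matrix.sites["pos"] < r["end"])
        ).to_numpy()
        ix = gidx["N21"]
        m = matrix.meth[sel][:, ix].sum()
        t = matrix.total[sel][:, ix].sum()
        assert r["level_N21"] == pytest.approx(m / t)


# ---------------------------------------------------------------------------
# Model front end
# ---------------------------------------------------------------------------

def test_model_results_summary_counts(toy_matrix):
    matrix, groups = toy_matrix
    res = dh.DifferentialMethylation(matrix, groups).fit(unit="cpg")
    assert res.n_tested == 4
    assert res.n_significant == res.n_hyper + res.n_hypo
    assert "units tested:     4" in res.summary()
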