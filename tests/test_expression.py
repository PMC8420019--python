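"""FPKM, expression binning, the concordance DE procedure and the
control-gene-PC1 ANCOVA."""

import numpy as np
import pandas as pd
import pytest

import devhypoxia as dh
from devhypoxia.expression import (
    DifferentialExpression,
    ancova_control_pc,
    expression_bins,
    fpkm,
    size_factors,
)


def _factorial_design(n_cell=2, heart=False):
    rows = []
    for ox in ("N21", "H10"):
        for age in ("7mo", "9mo"):
            for i in range(n_cell):
                rows.append({"oxygen": ox, "age": age})
    design = pd.DataFrame(rows)
    design.index = [f"s{i}" for i in range(len(design))]
    if heart:
        design["heart"] = "normal"
        h10 = design.index[design["oxygen"] == "H10"]
        design.loc[h10[: len(h10) // 2], "heart"] = "enlarged"
    return design


# ---------------------------------------------------------------------------
# FPKM
# ---------------------------------------------------------------------------

def test_fpkm_unit_example():
    counts = pd.DataFrame({"s1": [10]}, index=["g1"])
    lengths = pd.Series({"g1": 1000})
    out = fpkm(counts, lengths, library_sizes=pd.Series({"s1": 1_000_000}))
    assert out.loc["g1", "s1"] == pytest.approx(10.0)


def test_fpkm_scaling_and_zeros():
    counts = pd.DataFrame({"s1": [10, 0], "s2": [10, 0]}, index=["g1", "g2"])
    lengths = pd.Series({"g1": 500, "g2": 800})
    libs = pd.Series({"s1": 1e6, "s2": 2e6})
    out = fpkm(counts, lengths, libs)
    assert out.loc["g1", "s1"] == pytest.approx(2 * out.loc["g1", "s2"])
    assert out.loc["g2", "s1"] == 0.0
    with pytest.raises(ValueError):
        fpkm(counts, lengths, pd.Series({"s1": 0.0, "s2": 1e6}))
    with pytest.raises(ValueError):
        fpkm(counts, pd.Series({"g1": 0, "g2": 800}))


# ---------------------------------------------------------------------------
# Bins
# ---------------------------------------------------------------------------

def test_deciles_balanced():
    vals = pd.Series(np.arange(100, dtype=float), index=[f"g{i}" for i in range(100)])
    bins = expression_bins(vals, 10)
    assert bins.value_counts().eq(10).all()


def test_quintiles_rank_arithmetic():
    vals = pd.Series(np.arange(1, 26, dtype=float), index=[f"g{i:02d}" for i in range(25)])
    bins = expression_bins(vals, 5)
    for i in range(25):
        assert bins.iloc[i] == i // 5 + 1


def test_tied_values_fill_in_stable_order():
    vals = pd.Series(np.ones(10), index=[f"g{i}" for i in range(10)])
    bins = expression_bins(vals, 5)
    assert bins.tolist() == [1, 1, 2, 2, 3, 3, 4, 4, 5, 5]
    with pytest.raises(ValueError):
        expression_bins(vals, 11)


def test_bins_invariant_under_monotone_transform():
    rng = np.random.default_rng(0)
    vals = pd.Series(rng.random(40), index=[f"g{i}" for i in range(40)])
    a = expression_bins(vals, 5)
    b = expression_bins(np.log1p(vals * 100), 5)
    assert a.equals(b)


# ---------------------------------------------------------------------------
# DE procedure
# ---------------------------------------------------------------------------

def test_size_factors_median_of_ratios():
    counts = pd.DataFrame(
        {"s1": [10, 100, 20], "s2": [20, 200, 40]}, index=["g1", "g2", "g3"]
    )
    sf = size_factors(counts)
    assert sf["s2"] / sf["s1"] == pytest.approx(2.0)


def test_null_genes_not_called():
    rng = np.random.default_rng(2)
    design = _factorial_design(n_cell=4)
    mu = 200.0
    counts = pd.DataFrame(
        rng.poisson(mu, size=(30, len(design))),
        index=[f"g{i}" for i in range(30)],
        columns=design.index,
    )
    lengths = pd.Series(1000, index=counts.index)
    res = DifferentialExpression(counts, design, lengths).fit()
    assert len(res.significant_genes()) <= 1


def test_planted_effect_recovered_and_concordant():
    rng = np.random.default_rng(3)
    design = _factorial_design(n_cell=4)
    base = 300.0
    mu = np.where(design["oxygen"] == "H10", base * 4.0, base)
    rows = {"hit": rng.poisson(mu)}
    # null genes dominate so median-of-ratios size factors stay near 1
    for i in range(20):
        rows[f"null{i}"] = rng.poisson(base, len(design))
    counts = pd.DataFrame(rows).T
    counts.columns = design.index
    lengths = pd.Series(1000, index=counts.index)
    res = DifferentialExpression(counts, design, lengths).fit()
    row = res.table[(res.table["gene"] == "hit") & (res.table["effect"] == "oxygen")].iloc[0]
    assert row["significant"]
    assert row["log2_ratio"] == pytest.approx(2.0, abs=0.4)


def test_discordant_gene_excluded():
    """A gene significant in the primary leg but not in ANOVA fails the
    concordance rule (constructed via an external p-value table)."""
    rng = np.random.default_rng(4)
    design = _factorial_design(n_cell=4)
    counts = pd.DataFrame(
        rng.poisson(200, size=(3, len(design))),
        index=["g1", "g2", "g3"],
        columns=design.index,
    )
    lengths = pd.Series(1000, index=counts.index)
    external = pd.DataFrame(
        {"oxygen": [1e-6, 0.5, 0.5], "age": 0.5, "interaction": 0.5},
        index=counts.index,
    )
    res = DifferentialExpression(counts, design, lengths).fit(external_primary=external)
    row = res.table[(res.table["gene"] == "g1") & (res.table["effect"] == "oxygen")].iloc[0]
    assert row["p_nb"] < 0.01
    assert not row["concordant"] and not row["significant"]


def test_outlier_driven_effect_flagged():
    """An 'effect' produced by one extreme sample is caught by the
    leave-one-out screen."""
    design = _factorial_design(n_cell=4)
    y = np.full(len(design), 100.0)
    y[design.index.get_loc(design.index[design["oxygen"] == "H10"][0])] = 5000.0
    counts = pd.DataFrame([y.astype(int)], index=["g1"], columns=design.index)
    lengths = pd.Series(1000, index=counts.index)
    res = DifferentialExpression(counts, design, lengths).fit()
    sub = res.table[(res.table["gene"] == "g1") & (res.table["effect"] == "oxygen")]
    row = sub.iloc[0]
    if row["concordant"]:
        assert row["outlier_flag"] and not row["significant"]
    else:
        assert not row["significant"]


def test_heart_contrast_uses_fdr(small_dataset):
    res = DifferentialExpression(
        small_dataset["counts"], small_dataset["design"], small_dataset["gene_lengths"]
    ).fit()
    ht = res.heart_table
    assert ht is not None and "q" in ht.columns
    assert (ht.loc[ht["significant"], "q"] < 0.1).all()


def test_design_validation():
    design = _factorial_design(n_cell=2).iloc[:6]  # breaks the factorial
    counts = pd.DataFrame(
        np.ones((2, 6), dtype=int), index=["g1", "g2"], columns=design.index
    )
    with pytest.raises(ValueError, match="factorial"):
        DifferentialExpression(counts, design, pd.Series(1000, index=counts.index))


# ---------------------------------------------------------------------------
# ANCOVA with control-gene PC1
# ---------------------------------------------------------------------------

def test_collinear_controls_pc1_explains_everything():
    design = _factorial_design(n_cell=2)
    rng = np.random.default_rng(5)
    base = rng.normal(size=len(design))
    controls = pd.DataFrame(
        [base * 2 + 1, base * -3 + 5, base * 0.5], index=["c1", "c2", "c3"],
        columns=design.index,
    )
    targets = pd.DataFrame(
        rng.normal(size=(2, len(design))), index=["t1", "t2"], columns=design.index
    )
    _, _, explained = ancova_control_pc(controls, targets, design)
    assert explained == pytest.approx(1.0)


def test_orthogonal_covariate_leaves_anova_unchanged():
    """When PC1 is orthogonal to the design and the target, the ANCOVA
    term p-values match a plain two-way ANOVA."""
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    design = _factorial_design(n_cell=4)
    n = len(design)
    rng = np.random.default_rng(6)
    target = rng.normal(size=n)

    # covariate orthogonal to the design columns and the target
    X = pd.get_dummies(design[["oxygen", "age"]], drop_first=False).astype(float)
    X["inter"] = (design["oxygen"] == "H10").astype(float) * (design["age"] == "9mo")
    basis = np.column_stack([np.ones(n), X.to_numpy(), target])
    q, _ = np.linalg.qr(basis)
    raw = rng.normal(size=n)
    cov = raw - q @ (q.T @ raw)

    controls = pd.DataFrame(
        [cov, cov * 2, cov * -1], index=["c1", "c2", "c3"], columns=design.index
    )
    targets = pd.DataFrame([target], index=["t"], columns=design.index)
    table, pc1, _ = ancova_control_pc(controls, targets, design)

    df = design.copy()
    df["y"] = target
    plain = sm.stats.anova_lm(
        smf.ols("y ~ C(oxygen, Sum) * C(age, Sum)", data=df).fit(), typ=2
    )
    # an orthogonal covariate absorbs no sum of squares, so p's agree up
    # to the one residual degree of freedom it costs
    assert table.loc["t", "p_oxygen"] == pytest.approx(
        plain.loc["C(oxygen, Sum)", "PR(>F)"], abs=0.05
    )
    assert table.loc["t", "p_age"] == pytest.approx(
        plain.loc["C(age, Sum)", "PR(>F)"], abs=0.05
    )
    assert table.loc["t", "p_covariate"] > 0.5


def test_target_equal_to_covariate():
    design = _factorial_design(n_cell=4)
    rng = np.random.default_rng(7)
    cov = rng.normal(size=len(design))
    controls = pd.DataFrame(
        [cov, cov * 3, cov * -2], index=["c1", "c2", "c3"], columns=design.index
    )
    pc1 = ancova_control_pc(controls, pd.DataFrame([cov], index=["t"], columns=design.index), design)
    table = pc1[0]
    assert table.loc["t", "p_covariate"] < 1e-8
    assert table.loc["t", "p_oxygen"] > 0.05


def test_ancova_requires_three_controls():
    design = _factorial_design(n_cell=2)
    controls = pd.DataFrame(
        np.ones((2, len(design))), index=["c1", "c2"], columns=design.index
    )
    with pytest.raises(ValueError, match="control genes"):
        ancova_control_pc(controls, controls, design)
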