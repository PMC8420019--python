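"""Gene expression: FPKM, expression bins, and the dual-model differential
expression decision procedure.

The differential-expression call requires agreement between two models
fitted per gene to a 2x2 oxygen-by-age factorial:

* a negative-binomial Wald test on raw counts (median-of-ratios size
  factors as offset; method-of-moments per-gene dispersion floored at
  1e-8) at genewise p < 0.01, and
* a two-way ANOVA on log2(FPKM + 1) at p < 0.05,

with the oxygen main effect additionally required to agree in direction.
A leave-one-sample-out stability screen then drops genes whose call
hinges on the single most extreme sample.  Heart-size (normal vs
enlarged) is contrasted separately at BH FDR < 0.1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .methylation import bh_fdr

EFFECTS = ("oxygen", "age", "interaction")
_TERMS = {
    "oxygen": "C(oxygen, Sum)",
    "age": "C(age, Sum)",
    "interaction": "C(oxygen, Sum):C(age, Sum)",
}


# ---------------------------------------------------------------------------
# FPKM and bins
# ---------------------------------------------------------------------------

def fpkm(
    counts: pd.DataFrame,
    gene_lengths: pd.Series,
    library_sizes: pd.Series | None = None,
) -> pd.DataFrame:
    """Fragments per kilobase of exon-union length per million fragments."""
    gene_lengths = gene_lengths.reindex(counts.index)
    if (gene_lengths <= 0).any() or gene_lengths.isna().any():
        raise ValueError("gene lengths must be positive for all genes")
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    if (library_sizes <= 0).any():
        raise ValueError("library sizes must be positive")
    return counts.div(gene_lengths / 1e3, axis=0).div(library_sizes / 1e6, axis=1)


def expression_bins(values: pd.Series, k: int) -> pd.Series:
    """Assign genes to k near-equal expression bins, 1 = lowest.

    Genes are ranked ascending; ties break by stable input order; bin
    sizes differ by at most one (larger bins first).
    """
    n = len(values)
    if n < k:
        raise ValueError(f"cannot split {n} genes into {k} bins")
    order = np.argsort(values.to_numpy(), kind="stable")
    sizes = [n // k + (1 if i < n % k else 0) for i in range(k)]
    labels = np.empty(n, dtype=int)
    start = 0
    for b, size in enumerate(sizes, start=1):
        labels[order[start:start + size]] = b
        start += size
    return pd.Series(labels, index=values.index, name="bin")


# ---------------------------------------------------------------------------
# Negative-binomial leg
# ---------------------------------------------------------------------------

def size_factors(counts: pd.DataFrame) -> pd.Series:
    """DESeq-style median-of-ratios size factors."""
    log_counts = np.log(counts.where(counts > 0))
    log_geomeans = log_counts.mean(axis=1)
    usable = log_geomeans.notna() & np.isfinite(log_geomeans)
    if not usable.any():
        raise ValueError("no gene has nonzero counts in every sample")
    ratios = log_counts.loc[usable].sub(log_geomeans[usable], axis=0)
    return np.exp(ratios.median(axis=0)).rename("size_factor")


def _mom_dispersion(norm_counts: np.ndarray, cells: np.ndarray, floor: float = 1e-8) -> float:
    """Method-of-moments NB dispersion pooled over design cells."""
    num, den = 0.0, 0.0
    for c in np.unique(cells):
        y = norm_counts[cells == c]
        if len(y) < 2:
            continue
        m = y.mean()
        v = y.var(ddof=1)
        if m > 0:
            num += (v - m)
            den += m ** 2
    alpha = num / den if den > 0 else floor
    return max(alpha, floor)


def _nb_wald_gene(y, exog, term_cols, offset, alpha):
    """Wald z-tests per model term for one gene's NB GLM."""
    fam = sm.families.NegativeBinomial(alpha=alpha)
    try:
        res = sm.GLM(y, exog, family=fam, offset=offset).fit(maxiter=100)
    except Exception:
        return None
    out = {}
    for term, col in term_cols.items():
        coef = res.params[col]
        se = res.bse[col]
        z = coef / se if se > 0 else 0.0
        out[term] = (coef, 2 * stats.norm.sf(abs(z)))
    return out


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

class DifferentialExpression:
    """Dual-model differential expression over a counts matrix.

    Parameters
    ----------
    counts : genes x samples integer DataFrame.
    design : samples x factors DataFrame with columns ``oxygen``, ``age``
        and optionally ``heart`` ({"normal", "enlarged"}).
    gene_lengths : exon-union lengths in bp (for the FPKM/ANOVA leg).
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        design: pd.DataFrame,
        gene_lengths: pd.Series,
    ):
        if list(counts.columns) != list(design.index):
            raise ValueError("design index must match counts columns")
        for col in ("oxygen", "age"):
            if col not in design.columns:
                raise ValueError(f"design lacks required factor {col!r}")
            if design[col].nunique() != 2:
                raise ValueError(f"factor {col!r} must have exactly 2 levels")
        cells = design.groupby(["oxygen", "age"]).size()
        if len(cells) != 4:
            raise ValueError("design is not a full oxygen x age factorial (empty cell)")
        self.counts = counts
        self.design = design
        self.gene_lengths = gene_lengths.reindex(counts.index)
        self.fpkm = fpkm(counts, self.gene_lengths)
        self.size_factors = size_factors(counts)

    @classmethod
    def from_files(cls, counts_tsv, samples_tsv, lengths_tsv) -> "DifferentialExpression":
        counts = pd.read_csv(counts_tsv, sep="\t", index_col=0)
        design = pd.read_csv(samples_tsv, sep="\t", index_col=0)
        lengths = pd.read_csv(lengths_tsv, sep="\t", index_col=0).iloc[:, 0]
        return cls(counts.round().astype(int), design.loc[counts.columns], lengths)

    # -- single-gene fits -------------------------------------------------
    def _anova_gene(self, gene, sample_mask=None):
        df = self.design.copy()
        df["y"] = np.log2(self.fpkm.loc[gene] + 1.0).to_numpy()
        if sample_mask is not None:
            df = df.loc[sample_mask]
        ols = smf.ols("y ~ C(oxygen, Sum) * C(age, Sum)", data=df).fit()
        anova = sm.stats.anova_lm(ols, typ=2)
        pvals = {
            "oxygen": anova.loc["C(oxygen, Sum)", "PR(>F)"],
            "age": anova.loc["C(age, Sum)", "PR(>F)"],
            "interaction": anova.loc["C(oxygen, Sum):C(age, Sum)", "PR(>F)"],
        }
        ox_coef = ols.params.get("C(oxygen, Sum)[S.%s]" % sorted(df["oxygen"].unique())[0], np.nan)
        return pvals, ox_coef, ols

    def _nb_gene(self, gene, exog, term_cols, sample_mask=None):
        y = self.counts.loc[gene].to_numpy(dtype=float)
        offset = np.log(self.size_factors.to_numpy())
        cells = self.design.groupby(["oxygen", "age"], sort=True).ngroup().to_numpy()
        X = exog
        if sample_mask is not None:
            keep = np.asarray(sample_mask)
            y, offset, cells, X = y[keep], offset[keep], cells[keep], exog[keep]
        norm = y / np.exp(offset)
        alpha = _mom_dispersion(norm, cells)
        return _nb_wald_gene(y, X, term_cols, offset, alpha)

    def fit(
        self,
        alpha_primary: float = 0.01,
        alpha_anova: float = 0.05,
        heart_fdr: float = 0.1,
        outlier_screen: bool = True,
        external_primary: pd.DataFrame | None = None,
    ) -> "DifferentialExpressionResults":
        """Run both legs per gene and apply concordance + outlier rules.

        ``external_primary`` may supply a genes x {oxygen, age,
        interaction} p-value table to slot in as the primary leg (e.g.
        from an external count-model run); the NB leg is then skipped.
        """
        design = self.design
        exog = pd.get_dummies(
            pd.DataFrame(
                {
                    "ox": (design["oxygen"] == sorted(design["oxygen"].unique())[0]).astype(float) * 2 - 1,
                    "age": (design["age"] == sorted(design["age"].unique())[0]).astype(float) * 2 - 1,
                }
            )
        )
        exog["inter"] = exog["ox"] * exog["age"]
        exog.insert(0, "const", 1.0)
        exog = exog[["const", "ox", "age", "inter"]].to_numpy()
        term_cols = {"oxygen": 1, "age": 2, "interaction": 3}

        rows = []
        for gene in self.counts.index:
            if self.counts.loc[gene].sum() == 0:
                rows.append({"gene": gene, "skipped": "all-zero counts"})
                continue
            anova_p, anova_ox_coef, ols = self._anova_gene(gene)
            if external_primary is not None:
                nb = {
                    eff: (np.nan, external_primary.loc[gene, eff]) for eff in EFFECTS
                }
                nb_ox_coef = anova_ox_coef  # direction taken from the ANOVA leg
            else:
                nb = self._nb_gene(gene, exog, term_cols)
                if nb is None:
                    rows.append({"gene": gene, "skipped": "NB fit failed"})
                    continue
                nb_ox_coef = nb["oxygen"][0]

            # log2 ratio of normalized group means, treatment vs reference
            # (N21 is the reference when present)
            norm = self.counts.loc[gene] / self.size_factors
            lv = sorted(design["oxygen"].unique())
            if "N21" in lv:
                lv = ["N21"] + [x for x in lv if x != "N21"]
            mean_a = norm[design["oxygen"] == lv[0]].mean()
            mean_b = norm[design["oxygen"] == lv[1]].mean()
            log2_ratio = float(np.log2((mean_b + 0.5) / (mean_a + 0.5)))

            for eff in EFFECTS:
                p_nb = nb[eff][1]
                p_an = anova_p[eff]
                concordant = bool(p_nb < alpha_primary and p_an < alpha_anova)
                if eff == "oxygen" and concordant and external_primary is None:
                    concordant = bool(np.sign(nb_ox_coef) == np.sign(anova_ox_coef)) \
                        or nb_ox_coef == anova_ox_coef == 0
                outlier = False
                if concordant and outlier_screen:
                    outlier = self._outlier_unstable(
                        gene, eff, exog, term_cols, ols,
                        alpha_primary, alpha_anova, external_primary,
                    )
                rows.append(
                    {
                        "gene": gene,
                        "effect": eff,
                        "log2_ratio": log2_ratio if eff == "oxygen" else np.nan,
                        "p_nb": p_nb,
                        "p_anova": p_an,
                        "concordant": concordant,
                        "outlier_flag": outlier,
                        "significant": concordant and not outlier,
                    }
                )
        table = pd.DataFrame(rows)
        heart = self._heart_contrast(heart_fdr) if "heart" in design.columns else None
        return DifferentialExpressionResults(
            self, table, heart, alpha_primary, alpha_anova, heart_fdr
        )

    def _outlier_unstable(
        self, gene, effect, exog, term_cols, ols, alpha_primary, alpha_anova, external_primary
    ) -> bool:
        """Leave-one-out stability: drop the sample with the largest
        |studentized residual|; unstable iff either leg loses significance."""
        resid = ols.get_influence().resid_studentized_internal
        drop = int(np.nanargmax(np.abs(resid)))
        mask = np.ones(len(self.design), dtype=bool)
        mask[drop] = False
        # the reduced design must still be estimable
        if self.design.loc[mask].groupby(["oxygen", "age"]).size().shape[0] < 4:
            return False
        anova_p, _, _ = self._anova_gene(gene, sample_mask=mask)
        if anova_p[effect] >= alpha_anova or not np.isfinite(anova_p[effect]):
            return True
        if external_primary is None:
            nb = self._nb_gene(gene, exog, term_cols, sample_mask=mask)
            if nb is None or nb[effect][1] >= alpha_primary:
                return True
        return False

    def _heart_contrast(self, heart_fdr: float) -> pd.DataFrame:
        """Normal vs enlarged hearts: per-gene NB Wald, BH FDR."""
        design = self.design
        levels = sorted(design["heart"].unique())
        if len(levels) != 2:
            raise ValueError("heart factor must have exactly 2 levels")
        x = (design["heart"] == levels[1]).astype(float).to_numpy()
        exog = np.column_stack([np.ones_like(x), x])
        offset = np.log(self.size_factors.to_numpy())
        cells = design.groupby("heart").ngroup().to_numpy()
        rows = []
        for gene in self.counts.index:
            y = self.counts.loc[gene].to_numpy(dtype=float)
            if y.sum() == 0:
                continue
            alpha = _mom_dispersion(y / np.exp(offset), cells)
            res = _nb_wald_gene(y, exog, {"heart": 1}, offset, alpha)
            if res is None:
                continue
            coef, p = res["heart"]
            rows.append({"gene": gene, "log2_ratio": coef / np.log(2), "p": p})
        out = pd.DataFrame(rows)
        if len(out):
            out["q"] = bh_fdr(out["p"].to_numpy())
            out["significant"] = out["q"] < heart_fdr
        return out


@dataclass
class DifferentialExpressionResults:
    model: DifferentialExpression
    table: pd.DataFrame = field(repr=False)
    heart_table: pd.DataFrame | None = field(repr=False, default=None)
    alpha_primary: float = 0.01
    alpha_anova: float = 0.05
    heart_fdr: float = 0.1

    def significant_genes(self, effect: str | None = None) -> set[str]:
        t = self.table.dropna(subset=["effect"]) if "effect" in self.table else self.table
        sig = t[t["significant"].fillna(False)]
        if effect is not None:
            sig = sig[sig["effect"] == effect]
        return set(sig["gene"])

    @property
    def de_genes(self) -> set[str]:
        """Final DE set: oxygen main effect, oxygen x age interaction, or
        heart-size contrast (age-only genes are not followed up)."""
        out = self.significant_genes("oxygen") | self.significant_genes("interaction")
        if self.heart_table is not None and len(self.heart_table):
            out |= set(self.heart_table.loc[self.heart_table["significant"], "gene"])
        return out

    def summary(self) -> str:
        lines = [
            "Differential expression results",
            "=" * 40,
            f"genes tested:               {self.model.counts.shape[0]}",
            f"NB leg threshold:           p < {self.alpha_primary}",
            f"ANOVA leg threshold:        p < {self.alpha_anova}",
            f"oxygen effect (concordant): {len(self.significant_genes('oxygen'))}",
            f"oxygen x age interaction:   {len(self.significant_genes('interaction'))}",
            f"age only (not followed up): {len(self.significant_genes('age'))}",
        ]
        if self.heart_table is not None and len(self.heart_table):
            n = int(self.heart_table["significant"].sum())
            lines.append(f"heart-size contrast (FDR<{self.heart_fdr}): {n}")
        lines.append(f"final DE gene set:          {len(self.de_genes)}")
        return "\n".join(lines)


def de_test_concordant(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    gene_lengths: pd.Series,
    **fit_kwargs,
) -> DifferentialExpressionResults:
    """Functional wrapper over :class:`DifferentialExpression`."""
    return DifferentialExpression(counts, design, gene_lengths).fit(**fit_kwargs)


# ---------------------------------------------------------------------------
# qPCR-style ANCOVA with a control-gene PC1 covariate
# ---------------------------------------------------------------------------

def ancova_control_pc(
    control_expression: pd.DataFrame,
    target_expression: pd.DataFrame,
    design: pd.DataFrame,
) -> tuple[pd.DataFrame, np.ndarray, float]:
    """Two-way ANCOVA per target gene with control-gene PC1 as covariate.

    ``control_expression`` (>= 3 control genes x samples) is standardized
    per gene; PC1 sample scores enter as a covariate alongside oxygen,
    age and their interaction.  Returns (per-gene per-term p-values, PC1
    scores, fraction of control variance explained by PC1).
    """
    if control_expression.shape[0] < 3:
        raise ValueError("need at least 3 control genes")
    if control_expression.isna().any().any() or target_expression.isna().any().any():
        raise ValueError("missing sample values are not allowed")
    X = control_expression.to_numpy(dtype=float)
    X = (X - X.mean(axis=1, keepdims=True))
    sd = X.std(axis=1, ddof=1, keepdims=True)
    X = np.divide(X, sd, out=np.zeros_like(X), where=sd > 0)
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    pc1 = vt[0] * s[0]
    explained = float(s[0] ** 2 / (s ** 2).sum())

    base = design.copy()
    base["pc1"] = pc1
    formula = "y ~ C(oxygen, Sum) * C(age, Sum) + pc1"
    # estimability check: name the first aliased term
    from patsy import dmatrix

    mat = np.asarray(dmatrix("C(oxygen, Sum) * C(age, Sum) + pc1", base))
    rank = 0
    for j in range(mat.shape[1]):
        new_rank = np.linalg.matrix_rank(mat[:, : j + 1])
        if new_rank == rank:
            info = dmatrix("C(oxygen, Sum) * C(age, Sum) + pc1", base).design_info
            raise ValueError(f"rank-deficient design: term {info.column_names[j]!r} is aliased")
        rank = new_rank

    rows = []
    for gene in target_expression.index:
        df = base.copy()
        df["y"] = target_expression.loc[gene].to_numpy(dtype=float)
        fit = smf.ols(formula, data=df).fit()
        anova = sm.stats.anova_lm(fit, typ=2)
        rows.append(
            {
                "gene": gene,
                "p_oxygen": anova.loc["C(oxygen, Sum)", "PR(>F)"],
                "p_age": anova.loc["C(age, Sum)", "PR(>F)"],
                "p_interaction": anova.loc["C(oxygen, Sum):C(age, Sum)", "PR(>F)"],
                "p_covariate": anova.loc["pc1", "PR(>F)"],
            }
        )
    return pd.DataFrame(rows).set_index("gene"), pc1, explained
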