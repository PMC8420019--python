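"""Per-CpG methylation matrices and differential methylation calling.

The per-CpG test is a two-group binomial logistic likelihood-ratio test on
(methylated, total) read counts — the default test of replicate-aware
methylation callers.  Because every replicate within a group shares one
group proportion, the grouped-binomial MLEs are the read-pooled group
proportions and the LRT has a closed form, evaluated against chi-square
with 1 df.  Sites are significant when |pooled level difference| > 25
percentage points and BH q < 0.01; 200-bp/50-bp-step windows use the same
test at q < 0.001; CpG-island comparisons use a two-sided Fisher exact
test on the pooled 2x2 table at q < 0.05.  BH correction is applied within
each unit family (sites, windows, islands) separately.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .genome import CpGIsland, FeaturePartition, GenomeAnnotation

METH_BINS = ("0-25%", "25-50%", "50-75%", "75-100%")


def bh_fdr(p) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, order-preserving with input."""
    p = np.asarray(p, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Site matrix
# ---------------------------------------------------------------------------

@dataclass
class CpGSiteMatrix:
    """Methylated/total read counts at CpG sites across samples.

    ``sites`` has columns chrom, pos (0-based forward-strand C of the CpG
    dyad), sorted; ``meth`` and ``total`` are (n_sites, n_samples) count
    arrays aligned with ``samples``.
    """

    sites: pd.DataFrame
    meth: np.ndarray
    total: np.ndarray
    samples: list[str]

    def __post_init__(self):
        self.meth = np.asarray(self.meth)
        self.total = np.asarray(self.total)
        if self.meth.shape != self.total.shape:
            raise ValueError("meth and total shapes differ")
        if self.meth.shape != (len(self.sites), len(self.samples)):
            raise ValueError("count arrays do not match sites x samples")
        if (self.meth > self.total).any() or (self.meth < 0).any():
            raise ValueError("need 0 <= meth <= total")
        order = self.sites.sort_values(["chrom", "pos"], kind="stable").index.to_numpy()
        if not np.array_equal(order, np.arange(len(order))):
            self.sites = self.sites.iloc[order].reset_index(drop=True)
            self.meth = self.meth[order]
            self.total = self.total[order]
        else:
            self.sites = self.sites.reset_index(drop=True)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def pooled_levels(self, sample_idx=None) -> np.ndarray:
        """Per-site level = pooled M / pooled T over the given samples."""
        idx = slice(None) if sample_idx is None else sample_idx
        m = self.meth[:, idx].sum(axis=1)
        t = self.total[:, idx].sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(t > 0, m / np.maximum(t, 1), np.nan)

    def subset(self, mask) -> "CpGSiteMatrix":
        mask = np.asarray(mask)
        return CpGSiteMatrix(
            self.sites.loc[mask].reset_index(drop=True),
            self.meth[mask],
            self.total[mask],
            list(self.samples),
        )

    def group_indices(self, groups: dict[str, str]) -> dict[str, np.ndarray]:
        out: dict[str, list[int]] = {}
        for i, s in enumerate(self.samples):
            out.setdefault(groups[s], []).append(i)
        return {g: np.array(ix) for g, ix in out.items()}

    # ---- cytosine-report I/O -------------------------------------------
    @classmethod
    def from_cytosine_reports(
        cls, files: dict[str, str], merge_symmetric: bool = True
    ) -> "CpGSiteMatrix":
        """Load Bismark-dialect cytosine reports (one TSV per sample).

        Columns: chrom, 1-based position, strand, methylated count,
        unmethylated count, context[, trinucleotide].  Only CpG-context
        rows are used; minus-strand cytosines are merged into the
        forward-strand C of the same dyad (position - 1).
        """
        per_sample = {}
        keys: set[tuple[str, int]] = set()
        for sample, path in files.items():
            df = pd.read_csv(
                path,
                sep="\t",
                header=None,
                usecols=range(6),
                names=["chrom", "pos", "strand", "meth", "unmeth", "context"],
                dtype={"chrom": str},
            )
            df = df[df["context"].str.upper().isin(["CPG", "CG"])].copy()
            pos0 = df["pos"].to_numpy() - 1
            if merge_symmetric:
                pos0 = np.where(df["strand"].to_numpy() == "-", pos0 - 1, pos0)
            df["pos0"] = pos0
            agg = df.groupby(["chrom", "pos0"])[["meth", "unmeth"]].sum()
            per_sample[sample] = agg
            keys.update(agg.index)
        sites = pd.DataFrame(sorted(keys), columns=["chrom", "pos"])
        index = pd.MultiIndex.from_frame(sites)
        samples = list(files)
        meth = np.zeros((len(sites), len(samples)), dtype=np.int64)
        total = np.zeros_like(meth)
        for j, sample in enumerate(samples):
            agg = per_sample[sample].reindex(index, fill_value=0)
            meth[:, j] = agg["meth"].to_numpy()
            total[:, j] = (agg["meth"] + agg["unmeth"]).to_numpy()
        return cls(sites, meth, total, samples)

    def to_cytosine_reports(self, outdir, suffix: str = ".CpG_report.txt") -> None:
        import os

        for j, sample in enumerate(self.samples):
            path = os.path.join(outdir, f"{sample}{suffix}")
            with open(path, "w") as fh:
                for chrom, pos, m, t in zip(
                    self.sites["chrom"], self.sites["pos"], self.meth[:, j], self.total[:, j]
                ):
                    fh.write(f"{chrom}\t{pos + 1}\t+\t{m}\t{t - m}\tCpG\tCGN\n")


# ---------------------------------------------------------------------------
# Coverage filter and level binning
# ---------------------------------------------------------------------------

def _ordered_groups(gidx: dict) -> list:
    """Reference group first: N21 (normoxic control) when present, else
    lexicographic, so hyper/hypo reads as direction in the second group."""
    names = sorted(gidx)
    if "N21" in names:
        names = ["N21"] + [g for g in names if g != "N21"]
    return [(g, gidx[g]) for g in names]


def filter_coverage(
    matrix: CpGSiteMatrix,
    groups: dict[str, str],
    min_cov: int = 10,
    min_samples: int = 2,
) -> CpGSiteMatrix:
    """Keep sites covered >= ``min_cov`` reads in >= ``min_samples``
    replicates within every group."""
    gidx = matrix.group_indices(groups)
    for g, ix in gidx.items():
        if len(ix) < min_samples:
            raise ValueError(
                f"group {g!r} has {len(ix)} samples, fewer than min_samples={min_samples}"
            )
    keep = np.ones(matrix.n_sites, dtype=bool)
    for ix in gidx.values():
        keep &= (matrix.total[:, ix] >= min_cov).sum(axis=1) >= min_samples
    return matrix.subset(keep)


def methylation_bin_percentages(counts: pd.DataFrame) -> pd.DataFrame:
    """Row percentages of a feature x methylation-bin count table."""
    pct = counts.div(counts.sum(axis=1), axis=0) * 100.0
    return pct


def bin_methylation_levels(
    matrix: CpGSiteMatrix,
    partition: FeaturePartition,
    level: str = "sub",
) -> pd.DataFrame:
    """Feature x methylation-bin table of pooled per-site levels.

    Bins are [0,25), [25,50), [50,75), [75,100] percent so fully
    methylated sites land in the top bin.  Gene bodies appear both as an
    aggregate row and split into first exon / remaining exons / intron.
    Sites with zero pooled coverage are excluded (count logged).
    """
    levels = matrix.pooled_levels() * 100.0
    covered = ~np.isnan(levels)
    if (~covered).sum():
        warnings.warn(f"{(~covered).sum()} sites with zero coverage excluded", stacklevel=2)
    labels = np.empty(matrix.n_sites, dtype=object)
    for chrom, sub in matrix.sites.groupby("chrom", sort=False):
        labels[sub.index] = partition.label_positions(
            chrom, sub["pos"].to_numpy(), level=level
        )
    bins = np.digitize(levels[covered], [25.0, 50.0, 75.0])
    rows = {}
    lab_cov = labels[covered]
    order = ["intergenic", "gene_body", "promoter", "first_exon", "remaining_exons", "intron"]
    for feat in order:
        if feat == "gene_body" and level == "sub":
            in_feat = np.isin(lab_cov, ["first_exon", "remaining_exons", "intron"])
        else:
            in_feat = lab_cov == feat
        rows[feat] = [int(((bins == b) & in_feat).sum()) for b in range(4)]
    counts = pd.DataFrame.from_dict(rows, orient="index", columns=list(METH_BINS))
    counts["total"] = counts.sum(axis=1)
    pct = methylation_bin_percentages(counts[list(METH_BINS)])
    for b in METH_BINS:
        counts[f"{b} pct"] = pct[b]
    return counts


# ---------------------------------------------------------------------------
# Two-group grouped-binomial LRT (closed form)
# ---------------------------------------------------------------------------

def _binom_ll(m, t, p):
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return special.xlogy(m, p) + special.xlogy(t - m, 1 - p)


def grouped_binomial_lrt(m1, t1, m2, t2):
    """LRT of equal methylation proportion between two groups.

    Counts are read-pooled within group (the grouped-binomial MLE); the
    statistic is referred to chi-square with 1 df.  Returns (stat, p,
    level1, level2) as arrays.
    """
    m1, t1, m2, t2 = (np.asarray(x, dtype=float) for x in (m1, t1, m2, t2))
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = np.where(t1 > 0, m1 / np.maximum(t1, 1), np.nan)
        p2 = np.where(t2 > 0, m2 / np.maximum(t2, 1), np.nan)
        p0 = (m1 + m2) / np.maximum(t1 + t2, 1)
    ll_full = _binom_ll(m1, t1, np.nan_to_num(p1)) + _binom_ll(m2, t2, np.nan_to_num(p2))
    ll_null = _binom_ll(m1, t1, p0) + _binom_ll(m2, t2, p0)
    stat = np.maximum(2.0 * (ll_full - ll_null), 0.0)
    p = stats.chi2.sf(stat, df=1)
    return stat, p, p1, p2


def _dispersion_factor(meth, total, gidx):
    """Per-site replicate-level Pearson dispersion (floored at 1)."""
    chi = np.zeros(meth.shape[0])
    df = np.zeros(meth.shape[0])
    for ix in gidx.values():
        m = meth[:, ix].astype(float)
        t = total[:, ix].astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            phat = m.sum(axis=1) / np.maximum(t.sum(axis=1), 1)
            e = t * phat[:, None]
            v = e * (1 - phat[:, None])
            contrib = np.where(v > 0, (m - e) ** 2 / np.maximum(v, 1e-12), 0.0)
        chi += contrib.sum(axis=1)
        df += (t > 0).sum(axis=1) - 1
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.maximum(np.where(df > 0, chi / np.maximum(df, 1), 1.0), 1.0)


def diff_cpg_test(
    matrix: CpGSiteMatrix,
    groups: dict[str, str],
    min_delta: float = 25.0,
    q_max: float = 0.01,
    overdispersion: str = "none",
) -> pd.DataFrame:
    """Per-CpG differential methylation calls between two groups.

    ``overdispersion='scale'`` divides the LRT statistic by a per-site
    replicate-level Pearson dispersion factor (floored at 1); the default
    applies no correction.
    """
    gidx = matrix.group_indices(groups)
    if len(gidx) != 2:
        raise ValueError(f"expected exactly 2 groups, got {sorted(gidx)}")
    (g1, ix1), (g2, ix2) = _ordered_groups(gidx)
    m1 = matrix.meth[:, ix1].sum(axis=1)
    t1 = matrix.total[:, ix1].sum(axis=1)
    m2 = matrix.meth[:, ix2].sum(axis=1)
    t2 = matrix.total[:, ix2].sum(axis=1)
    testable = (t1 + t2) > 0
    stat, p, lv1, lv2 = grouped_binomial_lrt(m1, t1, m2, t2)
    if overdispersion == "scale":
        factor = _dispersion_factor(matrix.meth, matrix.total, gidx)
        stat = stat / factor
        p = stats.chi2.sf(stat, df=1)
    elif overdispersion != "none":
        raise ValueError("overdispersion must be 'none' or 'scale'")
    out = matrix.sites.copy()
    out[f"level_{g1}"] = lv1
    out[f"level_{g2}"] = lv2
    out["delta"] = np.abs(lv1 - lv2) * 100.0
    out["stat"] = stat
    out["p"] = np.where(testable, p, np.nan)
    out = out[testable].reset_index(drop=True)
    out["q"] = bh_fdr(out["p"].to_numpy())
    out["significant"] = (out["delta"] > min_delta) & (out["q"] < q_max)
    lo = out[f"level_{g1}"].to_numpy()
    hi = out[f"level_{g2}"].to_numpy()
    out["direction"] = np.where(hi > lo, "hyper", np.where(hi < lo, "hypo", "none"))
    return out


def sliding_window_dmr(
    matrix: CpGSiteMatrix,
    groups: dict[str, str],
    window: int = 200,
    step: int = 50,
    q_max: float = 0.001,
    annotation: GenomeAnnotation | None = None,
    promoter_length: int = 1000,
) -> pd.DataFrame:
    """Differentially methylated regions in tiled sliding windows.

    Windows start at 0, step, 2*step, ... and span exactly ``window`` bp;
    counts are summed over contained sites and tested with the grouped-
    binomial LRT; BH across windows; DMR iff q < ``q_max``.  When an
    annotation is given, a ``genes`` column lists genes whose promoter or
    gene body the window overlaps (a gene is differentially methylated iff
    at least one DMR overlaps it).
    """
    if step > window:
        warnings.warn("step > window leaves untiled gaps", stacklevel=2)
    gidx = matrix.group_indices(groups)
    if len(gidx) != 2:
        raise ValueError(f"expected exactly 2 groups, got {sorted(gidx)}")
    (g1, ix1), (g2, ix2) = _ordered_groups(gidx)

    records = []
    n_phases = max(1, -(-window // step))  # windows covering a given site
    for chrom, sub in matrix.sites.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        rows = sub.index.to_numpy()
        win_ids: dict[int, list[int]] = {}
        for k in range(n_phases):
            w = pos // step - k
            ok = (w >= 0) & (pos < (w * step + window)) & (pos >= w * step)
            for wi, ri in zip(w[ok], rows[ok]):
                win_ids.setdefault(int(wi), []).append(ri)
        for wi, ridx in sorted(win_ids.items()):
            ridx = np.array(ridx)
            records.append(
                (
                    chrom,
                    wi * step,
                    wi * step + window,
                    len(ridx),
                    matrix.meth[ridx][:, ix1].sum(),
                    matrix.total[ridx][:, ix1].sum(),
                    matrix.meth[ridx][:, ix2].sum(),
                    matrix.total[ridx][:, ix2].sum(),
                )
            )
    out = pd.DataFrame(
        records,
        columns=["chrom", "start", "end", "n_sites", "m1", "t1", "m2", "t2"],
    )
    if out.empty:
        return out
    stat, p, lv1, lv2 = grouped_binomial_lrt(
        out["m1"], out["t1"], out["m2"], out["t2"]
    )
    out[f"level_{g1}"] = lv1
    out[f"level_{g2}"] = lv2
    out["delta"] = np.abs(lv1 - lv2) * 100.0
    out["p"] = p
    out["q"] = bh_fdr(p)
    out["significant"] = out["q"] < q_max
    out["direction"] = np.where(lv2 > lv1, "hyper", np.where(lv2 < lv1, "hypo", "none"))
    if annotation is not None:
        out["genes"] = [
            ",".join(
                _overlapping_genes(annotation, chrom, s, e, promoter_length)
            )
            for chrom, s, e in zip(out["chrom"], out["start"], out["end"])
        ]
    return out


def _overlapping_genes(annotation, chrom, start, end, promoter_length):
    hits = []
    for g in annotation.genes_on(chrom):
        body = (g.start, g.end)
        if g.strand == "+":
            prom = (max(0, g.tss - promoter_length), g.tss)
        else:
            prom = (g.tss, g.tss + promoter_length)
        for s, e in (body, prom):
            if start < e and s < end:
                hits.append(g.gene_id)
                break
    return sorted(set(hits))


def dm_genes_from_windows(window_calls: pd.DataFrame) -> set[str]:
    """Genes with >= 1 significant DMR overlapping promoter or body."""
    if "genes" not in window_calls.columns:
        raise ValueError("window calls carry no gene overlaps; pass an annotation to sliding_window_dmr")
    sig = window_calls[window_calls["significant"]]
    out: set[str] = set()
    for genes in sig["genes"]:
        if genes:
            out.update(genes.split(","))
    return out


def island_methylation_and_test(
    matrix: CpGSiteMatrix,
    islands: list[CpGIsland] | pd.DataFrame,
    groups: dict[str, str],
    q_max: float = 0.05,
    level_method: str = "pooled",
) -> pd.DataFrame:
    """Per-island pooled methylation and two-sided Fisher exact group test.

    The island level is the read-pooled fraction sum(M)/sum(T) over
    contained sites and group samples (``level_method='site_mean'``
    averages per-site levels instead).  Islands without covered sites are
    excluded from testing.
    """
    if isinstance(islands, pd.DataFrame):
        isl = islands[["chrom", "start", "end"]].copy()
    else:
        isl = pd.DataFrame(
            [(i.chrom, i.start, i.end) for i in islands],
            columns=["chrom", "start", "end"],
        )
    gidx = matrix.group_indices(groups)
    if len(gidx) != 2:
        raise ValueError(f"expected exactly 2 groups, got {sorted(gidx)}")
    (g1, ix1), (g2, ix2) = _ordered_groups(gidx)

    records = []
    for chrom, isub in isl.groupby("chrom", sort=False):
        ssub = matrix.sites[matrix.sites["chrom"] == chrom]
        pos = ssub["pos"].to_numpy()
        rows = ssub.index.to_numpy()
        lo = np.searchsorted(pos, isub["start"].to_numpy(), side="left")
        hi = np.searchsorted(pos, isub["end"].to_numpy(), side="left")
        for (idx, row), a, b in zip(isub.iterrows(), lo, hi):
            ridx = rows[a:b]
            covered = ridx[matrix.total[ridx].sum(axis=1) > 0]
            m1 = int(matrix.meth[covered][:, ix1].sum())
            t1 = int(matrix.total[covered][:, ix1].sum())
            m2 = int(matrix.meth[covered][:, ix2].sum())
            t2 = int(matrix.total[covered][:, ix2].sum())
            if level_method == "pooled":
                lv1 = m1 / t1 if t1 else np.nan
                lv2 = m2 / t2 if t2 else np.nan
            else:
                with np.errstate(invalid="ignore", divide="ignore"):
                    s1 = matrix.meth[covered][:, ix1].sum(axis=1) / np.maximum(
                        matrix.total[covered][:, ix1].sum(axis=1), 1
                    )
                    s2 = matrix.meth[covered][:, ix2].sum(axis=1) / np.maximum(
                        matrix.total[covered][:, ix2].sum(axis=1), 1
                    )
                lv1 = float(np.mean(s1)) if len(covered) else np.nan
                lv2 = float(np.mean(s2)) if len(covered) else np.nan
            records.append(
                (row["chrom"], row["start"], row["end"], len(covered), m1, t1, m2, t2, lv1, lv2)
            )
    out = pd.DataFrame(
        records,
        columns=["chrom", "start", "end", "n_sites", "m1", "t1", "m2", "t2",
                 f"level_{g1}", f"level_{g2}"],
    )
    testable = (out["t1"] > 0) & (out["t2"] > 0)
    n_dropped = int((~testable).sum())
    if n_dropped:
        warnings.warn(f"{n_dropped} islands without covered sites excluded", stacklevel=2)
    out = out[testable].reset_index(drop=True)
    pvals = np.ones(len(out))
    for i, r in out.iterrows():
        _, pvals[i] = stats.fisher_exact(
            [[r["m1"], r["t1"] - r["m1"]], [r["m2"], r["t2"] - r["m2"]]],
            alternative="two-sided",
        )
    out["p"] = pvals
    out["q"] = bh_fdr(pvals)
    out["significant"] = out["q"] < q_max
    lv1 = out[f"level_{g1}"].to_numpy()
    lv2 = out[f"level_{g2}"].to_numpy()
    out["direction"] = np.where(lv2 > lv1, "hyper", np.where(lv2 < lv1, "hypo", "none"))
    return out


# ---------------------------------------------------------------------------
# Model/Results front end
# ---------------------------------------------------------------------------

class DifferentialMethylation:
    """Two-group differential methylation model over a CpG site matrix.

    ``fit(unit=...)`` dispatches to the per-CpG LRT, the sliding-window
    DMR scan, or the per-island Fisher test, and returns a
    :class:`DifferentialMethylationResults`.
    """

    def __init__(self, matrix: CpGSiteMatrix, groups: dict[str, str]):
        self.matrix = matrix
        self.groups = dict(groups)
        if len(set(self.groups.values())) != 2:
            raise ValueError("exactly two groups required")

    def fit(self, unit: str = "cpg", **kwargs) -> "DifferentialMethylationResults":
        if unit == "cpg":
            table = diff_cpg_test(self.matrix, self.groups, **kwargs)
        elif unit == "window":
            table = sliding_window_dmr(self.matrix, self.groups, **kwargs)
        elif unit == "island":
            table = island_methylation_and_test(
                self.matrix, kwargs.pop("islands"), self.groups, **kwargs
            )
        else:
            raise ValueError("unit must be 'cpg', 'window' or 'island'")
        return DifferentialMethylationResults(self, unit, table)


@dataclass
class DifferentialMethylationResults:
    model: DifferentialMethylation
    unit: str
    table: pd.DataFrame = field(repr=False)

    @property
    def n_tested(self) -> int:
        return len(self.table)

    @property
    def n_significant(self) -> int:
        return int(self.table["significant"].sum())

    @property
    def n_hyper(self) -> int:
        sig = self.table[self.table["significant"]]
        return int((sig["direction"] == "hyper").sum())

    @property
    def n_hypo(self) -> int:
        sig = self.table[self.table["significant"]]
        return int((sig["direction"] == "hypo").sum())

    def summary(self) -> str:
        names = sorted(set(self.model.groups.values()))
        if "N21" in names:
            names = ["N21"] + [g for g in names if g != "N21"]
        g1, g2 = names
        lines = [
            "Differential methylation results",
            "=" * 40,
            f"unit:             {self.unit}",
            f"groups:           {g1} vs {g2}",
            f"units tested:     {self.n_tested}",
            f"significant:      {self.n_significant}",
            f"  hypermethylated ({g2}): {self.n_hyper}",
            f"  hypomethylated  ({g2}): {self.n_hypo}",
        ]
        return "\n".join(lines)
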