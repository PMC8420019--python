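"""Methylation–expression integration: feature-wise Spearman correlations,
TSS-centred methylation meta-profiles with LOESS smoothing, and Fisher
odds-ratio enrichment for 2x2 comparisons (differentially methylated units
vs genomic features, DM genes vs DE genes, and the like)."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from .genome import GenomeAnnotation


# ---------------------------------------------------------------------------
# Spearman by feature
# ---------------------------------------------------------------------------

def spearman_by_feature(
    site_table: pd.DataFrame,
    min_sites: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spearman rho between per-CpG methylation level and host-gene
    expression bin, per genomic feature.

    ``site_table`` needs columns ``feature``, ``level`` (fraction) and
    ``bin`` (integer expression bin of the host gene).  Each CpG is one
    observation (site-wise, not gene-wise).  Returns (per-feature rho/p
    table, per-feature-per-bin median/IQR summaries for violin-style
    display).  Features with fewer than ``min_sites`` sites are skipped.
    """
    rows, summaries = [], []
    for feat, sub in site_table.groupby("feature", sort=False):
        sub = sub.dropna(subset=["level", "bin"])
        if len(sub) < min_sites:
            warnings.warn(f"feature {feat!r} has < {min_sites} sites; skipped", stacklevel=2)
            continue
        rho, p = stats.spearmanr(sub["level"], sub["bin"])
        rows.append({"feature": feat, "n_sites": len(sub), "rho": rho, "p": p})
        for b, bsub in sub.groupby("bin"):
            q1, med, q3 = np.percentile(bsub["level"], [25, 50, 75])
            summaries.append(
                {"feature": feat, "bin": int(b), "n": len(bsub),
                 "median": med, "q1": q1, "q3": q3}
            )
    return pd.DataFrame(rows), pd.DataFrame(summaries)


# ---------------------------------------------------------------------------
# TSS meta-profiles
# ---------------------------------------------------------------------------

def tss_distances(
    sites: pd.DataFrame, annotation: GenomeAnnotation, radius: int = 3000
) -> pd.DataFrame:
    """Signed strand-aware distance of each CpG to the nearest TSS.

    Upstream is negative on both strands.  Sites farther than ``radius``
    from every TSS are dropped; ties go to the lower-coordinate gene.
    """
    out = []
    for chrom, sub in sites.groupby("chrom", sort=False):
        genes = sorted(annotation.genes_on(chrom), key=lambda g: (g.tss, g.start, g.gene_id))
        if not genes:
            continue
        tss = np.array([g.tss for g in genes])
        strands = np.array([1 if g.strand == "+" else -1 for g in genes])
        gene_ids = np.array([g.gene_id for g in genes])
        pos = sub["pos"].to_numpy()
        right = np.searchsorted(tss, pos)
        left = np.clip(right - 1, 0, len(tss) - 1)
        right = np.clip(right, 0, len(tss) - 1)
        d_left = np.abs(pos - tss[left])
        d_right = np.abs(pos - tss[right])
        # tie -> lower coordinate, i.e. the left gene
        pick = np.where(d_right < d_left, right, left)
        dist = (pos - tss[pick]) * strands[pick]
        ok = np.abs(dist) <= radius
        out.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": pos[ok],
                    "gene": gene_ids[pick[ok]],
                    "distance": dist[ok],
                    "site_index": sub.index.to_numpy()[ok],
                }
            )
        )
    if not out:
        return pd.DataFrame(columns=["chrom", "pos", "gene", "distance", "site_index"])
    return pd.concat(out, ignore_index=True)


@dataclass
class TssProfile:
    """Smoothed methylation-vs-TSS-distance curves per expression bin."""

    grid: np.ndarray
    curves: dict[int, np.ndarray]
    raw: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for b, y in sorted(self.curves.items()):
            for d, v in zip(self.grid, y):
                rows.append({"bin": b, "distance": int(d), "level": v})
        return pd.DataFrame(rows)


def tss_profile(
    site_levels: pd.DataFrame,
    annotation: GenomeAnnotation,
    gene_bins: pd.Series,
    radius: int = 3000,
    loess_span: float = 0.3,
    grid_step: int = 50,
    min_sites: int = 50,
) -> TssProfile:
    """LOESS methylation profile around TSSs per gene-expression bin.

    ``site_levels`` needs columns chrom, pos, level.  Each CpG within
    ``radius`` of its nearest TSS contributes one point, binned by the
    host gene's expression bin; a local-linear tricube LOESS with span
    ``loess_span`` is evaluated on a ``grid_step``-bp grid.  Bins with
    fewer than ``min_sites`` sites are suppressed with a warning.
    """
    dist = tss_distances(site_levels[["chrom", "pos"]], annotation, radius=radius)
    dist["level"] = site_levels["level"].to_numpy()[dist["site_index"].to_numpy()]
    dist["bin"] = gene_bins.reindex(dist["gene"]).to_numpy()
    dist = dist.dropna(subset=["bin"])
    grid = np.arange(-radius, radius + 1, grid_step)
    curves: dict[int, np.ndarray] = {}
    for b, sub in dist.groupby("bin"):
        if len(sub) < min_sites:
            warnings.warn(f"bin {int(b)}: only {len(sub)} sites in window; curve suppressed",
                          stacklevel=2)
            continue
        # sort for deterministic, order-invariant output
        sub = sub.sort_values(["distance", "chrom", "pos"])
        fitted = lowess(
            sub["level"].to_numpy(),
            sub["distance"].to_numpy(dtype=float),
            frac=loess_span,
            it=0,
            delta=float(grid_step),  # anchor spacing; keeps genome-scale fits O(n)
            return_sorted=True,
        )
        x, y = fitted[:, 0], fitted[:, 1]
        x, keep = np.unique(x, return_index=True)
        curves[int(b)] = np.interp(grid, x, y[keep])
    return TssProfile(grid=grid, curves=curves, raw=dist.reset_index(drop=True))


def site_expression_table(
    sites: pd.DataFrame,
    levels: np.ndarray,
    features: np.ndarray,
    annotation: GenomeAnnotation,
    gene_bins: pd.Series,
) -> pd.DataFrame:
    """Join per-CpG levels and feature labels with host-gene expression bins.

    Each CpG is assigned the expression bin of the gene with the nearest
    TSS (site-wise assignment, one observation per CpG), giving the input
    :func:`spearman_by_feature` expects.
    """
    dist = tss_distances(sites[["chrom", "pos"]], annotation, radius=np.iinfo(np.int64).max)
    host = pd.Series(dist["gene"].to_numpy(), index=dist["site_index"].to_numpy())
    out = pd.DataFrame(
        {
            "feature": features,
            "level": levels,
            "bin": gene_bins.reindex(host.reindex(sites.index)).to_numpy(),
        },
        index=sites.index,
    )
    return out.dropna(subset=["level", "bin"])


# ---------------------------------------------------------------------------
# Odds-ratio enrichment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContingencyResult:
    """2x2 enrichment: odds ratio, Woolf 95% CI, two-sided Fisher p.

    The OR and CI use a Haldane +0.5 correction when any cell is zero.
    """

    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    ci_low: float
    ci_high: float
    p: float


def enrichment_odds_ratio(a: int, b: int, c: int, d: int) -> ContingencyResult:
    """Odds ratio with Woolf CI and two-sided Fisher exact p for the 2x2
    table [[a, b], [c, d]]."""
    cells = np.array([a, b, c, d], dtype=float)
    if (cells < 0).any():
        raise ValueError("cell counts must be non-negative")
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        raise ValueError("a table margin is zero; enrichment undefined")
    corr = cells + 0.5 if (cells == 0).any() else cells
    ca, cb, cc, cd = corr
    or_ = (ca * cd) / (cb * cc)
    se = np.sqrt(1 / ca + 1 / cb + 1 / cc + 1 / cd)
    ci_low = float(np.exp(np.log(or_) - 1.96 * se))
    ci_high = float(np.exp(np.log(or_) + 1.96 * se))
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return ContingencyResult(int(a), int(b), int(c), int(d), float(or_), ci_low, ci_high, float(p))


def dm_de_association(
    dm_genes: set[str], de_genes: set[str], universe: set[str]
) -> ContingencyResult:
    """Association between differential methylation and differential
    expression over a gene universe (rows: DM / not DM; columns: DE /
    not DE)."""
    if not universe:
        raise ValueError("empty gene universe")
    dm = set(dm_genes) & set(universe)
    de = set(de_genes) & set(universe)
    a = len(dm & de)
    b = len(dm - de)
    c = len(de - dm)
    d = len(universe) - a - b - c
    return enrichment_odds_ratio(a, b, c, d)


def feature_enrichment(
    unit_features: pd.Series, significant: pd.Series, feature: str
) -> ContingencyResult:
    """Enrichment of significant units (DM CpGs, DM CGIs, ...) within one
    genomic feature vs the rest of the genome."""
    in_feat = unit_features == feature
    sig = significant.astype(bool)
    a = int((in_feat & sig).sum())
    b = int((in_feat & ~sig).sum())
    c = int((~in_feat & sig).sum())
    d = int((~in_feat & ~sig).sum())
    return enrichment_odds_ratio(a, b, c, d)
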