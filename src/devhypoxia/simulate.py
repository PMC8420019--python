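"""Synthetic genomes, methylomes, expression counts and haemodynamic
traces with the statistical structure the analysis pipeline assumes.

The generator emulates a two-group (normoxic N21 vs developmentally
hypoxic H10) vertebrate heart study:

* a CpG-depleted AT-rich background genome with GC- and CpG-rich islands
  planted at known coordinates, and non-overlapping genes on both strands;
* per-CpG methylation counts: totals Poisson around a target coverage,
  methylated counts beta-binomial around feature-dependent means
  (bimodal promoters: mostly-unmethylated or mostly-methylated; heavily
  methylated gene bodies; intermediate intergenic background), with a
  planted group offset at a known subset of sites;
* negative-binomial expression counts whose means are inversely coupled
  to promoter methylation, with planted oxygen effects at known genes
  over a full oxygen x age factorial;
* per-animal 5-min-window haemodynamic channel means with an anoxic
  bradycardia that is deeper in the normoxia-incubated group.

Every generator is deterministic given (config, seed): same inputs give
byte-identical outputs, and ground-truth tables are always returned.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genome import Gene, GenomeAnnotation, locate_cpgs, partition_features
from .methylation import CpGSiteMatrix

GROUPS = ("N21", "H10")


class SizingError(ValueError):
    """Requested genes/islands cannot be packed into the chromosomes."""


@dataclass(frozen=True)
class SimulationConfig:
    """Study-scale parameters of the synthetic dataset.

    Defaults are the conditions the pipeline is validated under: 30x
    beta-binomial coverage with three replicates per group, a bimodal
    promoter methylation mixture, heavily methylated gene bodies, a 40
    percentage-point planted group offset, and a 2x2x4 = 16-sample
    expression factorial.
    """

    seed: int = 0
    n_chroms: int = 1
    chrom_length: int = 2_000_000
    n_genes: int = 200
    n_exons_per_gene: tuple[int, int] = (3, 8)
    exon_length: tuple[int, int] = (100, 300)
    intron_length: tuple[int, int] = (200, 800)
    promoter_length: int = 1000
    background_gc: float = 0.40
    cpg_depletion: float = 0.70
    island_gc: float = 0.65
    island_obsexp: float = 0.75
    island_length: tuple[int, int] = (300, 800)
    n_planted_islands: int = 40
    coverage_mean: float = 30.0
    beta_precision: float = 50.0
    mean_meth: dict = field(
        default_factory=lambda: {"gene_body": 0.85, "intergenic": 0.75}
    )
    promoter_mixture: tuple[tuple[float, float], ...] = ((0.05, 0.45), (0.95, 0.55))
    n_samples_per_group: int = 3
    planted_dm_fraction: float = 0.02
    dm_effect: float = 0.40
    nb_dispersion: float = 0.05
    de_fraction: float = 0.10
    de_log2fc: float = 2.0
    meth_expr_coupling: float = -3.0
    n_expression_samples_per_cell: int = 4
    expression_baseline_log2: tuple[float, float] = (7.0, 1.5)

    def __post_init__(self):
        for name in ("background_gc", "cpg_depletion", "island_gc",
                     "planted_dm_fraction", "de_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for mean in self.mean_meth.values():
            if not 0.0 <= mean <= 1.0:
                raise ValueError("mean_meth values must lie in [0, 1]")
        if abs(sum(w for _, w in self.promoter_mixture) - 1.0) > 1e-9:
            raise ValueError("promoter mixture weights must sum to 1")
        if self.coverage_mean <= 0:
            raise ValueError("coverage_mean must be positive")
        if self.beta_precision <= 0:
            raise ValueError("beta_precision must be positive")
        if self.dm_effect < 0 or self.dm_effect > 1:
            raise ValueError("dm_effect must lie in [0, 1]")
        if self.n_samples_per_group < 1:
            raise ValueError("need at least one sample per group")


# ---------------------------------------------------------------------------
# Genome and annotation
# ---------------------------------------------------------------------------

def _random_sequence(rng, length: int, gc: float) -> np.ndarray:
    letters = np.frombuffer(b"ACGT", dtype=np.uint8)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return rng.choice(letters, size=length, p=probs)


def _deplete_cpgs(rng, seq: np.ndarray, fraction: float) -> None:
    """Mimic vertebrate CpG depletion: convert the C of a fraction of CpG
    dinucleotides to T (deamination-style), in place."""
    c, g = ord("C"), ord("G")
    pos = np.nonzero((seq[:-1] == c) & (seq[1:] == g))[0]
    hit = pos[rng.random(pos.size) < fraction]
    seq[hit] = ord("T")


def _island_sequence(rng, length: int, gc: float, min_obsexp: float) -> np.ndarray:
    """A GC-rich, CpG-rich segment meeting the island criteria.

    Built from 2-bp units: with probability rho an explicit "CG", else two
    letters drawn at a GC fraction that keeps the overall GC on target.
    rho is set comfortably above the level needed for the requested
    Obs/Exp; candidate draws are rejected until the realized segment
    passes both thresholds.  gc = 1 degenerates to a pure CG repeat.
    """
    c, g = ord("C"), ord("G")
    if gc >= 0.999:
        rho = 1.0
        fill_gc = 1.0
    else:
        # E[Obs/Exp] ~ 2*rho/gc^2 from the planted CG units alone
        rho = min(0.9, 0.5 * min_obsexp * gc * gc * 1.8)
        fill_gc = min(1.0, max(0.0, (gc - rho) / (1 - rho)))
    n_units = (length + 1) // 2
    for _ in range(100):
        units_cg = rng.random(n_units) < rho
        seq = np.empty(2 * n_units, dtype=np.uint8)
        seq[0::2] = np.where(units_cg, c, 0)
        seq[1::2] = np.where(units_cg, g, 0)
        fill = _random_sequence(rng, 2 * n_units, fill_gc)
        free = seq == 0
        seq[free] = fill[free]
        seq = seq[:length]
        n_c = int((seq == c).sum())
        n_g = int((seq == g).sum())
        n_cg = int(((seq[:-1] == c) & (seq[1:] == g)).sum())
        gc_frac = (n_c + n_g) / length
        obs_exp = n_cg * length / (n_c * n_g) if n_c and n_g else 0.0
        if gc_frac >= gc and obs_exp >= min_obsexp:
            return seq
    raise RuntimeError("island sequence rejection sampling failed")


def _place_genes(rng, config: SimulationConfig, chrom_genes: int, length: int):
    """Non-overlapping gene models separated by >= promoter_length + margin."""
    lo_e, hi_e = config.n_exons_per_gene
    gap_min = config.promoter_length + 500
    plans = []
    total = 0
    for _ in range(chrom_genes):
        n_ex = int(rng.integers(lo_e, hi_e + 1))
        ex_lens = rng.integers(*config.exon_length, size=n_ex, endpoint=True)
        in_lens = rng.integers(*config.intron_length, size=max(n_ex - 1, 0), endpoint=True)
        plans.append((ex_lens, in_lens))
        total += int(ex_lens.sum() + in_lens.sum())
    slack = length - total - gap_min * (chrom_genes + 1)
    if slack < 0:
        raise SizingError(
            f"cannot place {chrom_genes} genes in {length} bp: "
            f"footprint {total} + spacing exceeds chromosome"
        )
    extra = rng.multinomial(slack, np.full(chrom_genes + 1, 1 / (chrom_genes + 1)))
    genes = []
    cursor = 0
    strands = rng.permutation(
        np.array((["+", "-"] * chrom_genes)[:chrom_genes])
    )
    for i, (ex_lens, in_lens) in enumerate(plans):
        cursor += gap_min + int(extra[i])
        exons = []
        p = cursor
        for j, el in enumerate(ex_lens):
            exons.append((p, p + int(el)))
            p += int(el)
            if j < len(in_lens):
                p += int(in_lens[j])
        genes.append((strands[i], tuple(exons)))
        cursor = p
    return genes


def simulate_genome_and_annotation(
    config: SimulationConfig,
) -> tuple[dict[str, str], GenomeAnnotation, pd.DataFrame]:
    """Generate (genome sequences, gene annotation, planted-island truth).

    Islands (>= 200 bp, GC >= island_gc, Obs/Exp >= island_obsexp) are
    embedded at known coordinates in a CpG-depleted background; genes are
    non-overlapping with both strands represented.
    """
    rng = np.random.default_rng(config.seed)
    genome: dict[str, str] = {}
    genes: list[Gene] = []
    truth_rows = []
    per_chrom = np.full(config.n_chroms, config.n_genes // config.n_chroms)
    per_chrom[: config.n_genes % config.n_chroms] += 1
    isl_per_chrom = np.full(config.n_chroms, config.n_planted_islands // config.n_chroms)
    isl_per_chrom[: config.n_planted_islands % config.n_chroms] += 1

    gid = 0
    for ci in range(config.n_chroms):
        chrom = f"chr{ci + 1}"
        L = config.chrom_length
        seq = _random_sequence(rng, L, config.background_gc)
        _deplete_cpgs(rng, seq, config.cpg_depletion)

        placed = _place_genes(rng, config, int(per_chrom[ci]), L)
        for strand, exons in placed:
            gid += 1
            genes.append(Gene(f"gene{gid:05d}", chrom, strand, exons))

        # plant islands at positions separated from one another
        n_isl = int(isl_per_chrom[ci])
        occupied: list[tuple[int, int]] = []
        tries = 0
        while len(occupied) < n_isl:
            tries += 1
            if tries > 10000:
                raise SizingError(
                    f"cannot place {n_isl} islands on {chrom}: too crowded"
                )
            ilen = int(rng.integers(*config.island_length, endpoint=True))
            start = int(rng.integers(0, L - ilen))
            pad = 300  # clearance so neighbouring islands never merge
            if any(start < e + pad and s - pad < start + ilen for s, e in occupied):
                continue
            iseq = _island_sequence(rng, ilen, config.island_gc, config.island_obsexp)
            seq[start:start + ilen] = iseq
            occupied.append((start, start + ilen))
            n_c = int((iseq == ord("C")).sum())
            n_g = int((iseq == ord("G")).sum())
            n_cg = int(((iseq[:-1] == ord("C")) & (iseq[1:] == ord("G"))).sum())
            truth_rows.append(
                {
                    "chrom": chrom,
                    "start": start,
                    "end": start + ilen,
                    "gc_percent": 100.0 * (n_c + n_g) / ilen,
                    "obs_exp": n_cg * ilen / (n_c * n_g) if n_c and n_g else 0.0,
                }
            )
        genome[chrom] = seq.tobytes().decode("ascii")

    annotation = GenomeAnnotation({c: config.chrom_length for c in genome}, genes)
    truth = pd.DataFrame(
        truth_rows, columns=["chrom", "start", "end", "gc_percent", "obs_exp"]
    ).sort_values(["chrom", "start"]).reset_index(drop=True)
    return genome, annotation, truth


# ---------------------------------------------------------------------------
# Methylome
# ---------------------------------------------------------------------------

def _beta_binomial(rng, total: np.ndarray, mean: np.ndarray, precision: float) -> np.ndarray:
    mean = np.clip(mean, 1e-6, 1 - 1e-6)
    p = rng.beta(mean * precision, (1 - mean) * precision)
    return rng.binomial(total, p)


def simulate_methylome(
    config: SimulationConfig,
    genome: dict[str, str],
    annotation: GenomeAnnotation,
) -> tuple[CpGSiteMatrix, dict[str, str], pd.DataFrame]:
    """Per-sample CpG counts for both groups plus planted-DM ground truth.

    Returns (site matrix over all samples, sample -> group map, truth
    table).  Feature-dependent means: promoters draw a per-gene state
    from the bimodal mixture; gene bodies and intergenic sites use their
    configured means.  A ``planted_dm_fraction`` of sites get a +/-
    ``dm_effect`` offset (clipped to [0, 1]) in the H10 group.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    partition = partition_features(annotation, config.promoter_length)

    frames = []
    for chrom, seq in genome.items():
        pos = locate_cpgs(seq)
        frames.append(pd.DataFrame({"chrom": chrom, "pos": pos}))
    sites = (
        pd.concat(frames, ignore_index=True)
        .sort_values(["chrom", "pos"], kind="stable")
        .reset_index(drop=True)
    )

    # promoter state per gene: component of the bimodal mixture
    comp_means = np.array([m for m, _ in config.promoter_mixture])
    comp_w = np.array([w for _, w in config.promoter_mixture])
    gene_state = {
        g.gene_id: comp_means[rng.choice(len(comp_means), p=comp_w)]
        for g in annotation.genes
    }

    mean = np.empty(len(sites))
    label_all = np.empty(len(sites), dtype=object)
    for chrom, sub in sites.groupby("chrom", sort=False):
        labels = partition.label_positions(chrom, sub["pos"].to_numpy(), level="top")
        label_all[sub.index] = labels
        m = np.empty(len(sub))
        m[:] = config.mean_meth.get("intergenic", 0.75)
        m[labels == "gene_body"] = config.mean_meth.get("gene_body", 0.85)
        prom = labels == "promoter"
        if prom.any():
            genes = sorted(annotation.genes_on(chrom), key=lambda g: g.start)
            tss = np.array([g.tss for g in genes])
            ids = [g.gene_id for g in genes]
            nearest = np.argmin(
                np.abs(sub["pos"].to_numpy()[prom, None] - tss[None, :]), axis=1
            )
            m[prom] = [gene_state[ids[i]] for i in nearest]
        mean[sub.index] = m
    sites["feature"] = label_all
    sites["mean_n21"] = mean

    n_dm = int(round(config.planted_dm_fraction * len(sites)))
    dm_idx = rng.choice(len(sites), size=n_dm, replace=False) if n_dm else np.array([], int)
    sign = rng.choice([-1.0, 1.0], size=n_dm)
    if config.dm_effect == 0:
        dm_idx = np.array([], dtype=int)
        sign = np.array([])
    mean_h10 = mean.copy()
    mean_h10[dm_idx] = np.clip(mean[dm_idx] + sign * config.dm_effect, 0.0, 1.0)
    sites["mean_h10"] = mean_h10

    samples = [f"{g}_{i + 1}" for g in GROUPS for i in range(config.n_samples_per_group)]
    groups = {s: s.split("_")[0] for s in samples}
    n_sites = len(sites)
    meth = np.zeros((n_sites, len(samples)), dtype=np.int64)
    total = np.zeros_like(meth)
    for j, s in enumerate(samples):
        mu = mean if groups[s] == "N21" else mean_h10
        t = rng.poisson(config.coverage_mean, size=n_sites)
        meth[:, j] = _beta_binomial(rng, t, mu, config.beta_precision)
        total[:, j] = t

    matrix = CpGSiteMatrix(sites[["chrom", "pos"]].copy(), meth, total, samples)
    truth = sites.iloc[dm_idx][["chrom", "pos", "feature", "mean_n21", "mean_h10"]].copy()
    truth["effect"] = truth["mean_h10"] - truth["mean_n21"]
    truth = truth.sort_values(["chrom", "pos"]).reset_index(drop=True)
    # matrix rows were re-sorted identically, so per-site metadata aligns
    matrix.sites["feature"] = sites["feature"].to_numpy()
    return matrix, groups, truth


def promoter_methylation_by_gene(
    config: SimulationConfig,
    annotation: GenomeAnnotation,
    matrix: CpGSiteMatrix,
    groups: dict[str, str],
) -> pd.DataFrame:
    """Observed pooled promoter methylation per gene and group."""
    gidx = matrix.group_indices(groups)
    rows = []
    for g in annotation.genes:
        if g.strand == "+":
            lo, hi = g.tss - config.promoter_length, g.tss
        else:
            lo, hi = g.tss, g.tss + config.promoter_length
        sub = matrix.sites[
            (matrix.sites["chrom"] == g.chrom)
            & (matrix.sites["pos"] >= lo)
            & (matrix.sites["pos"] < hi)
        ]
        rec = {"gene": g.gene_id}
        for grp, ix in gidx.items():
            m = matrix.meth[sub.index][:, ix].sum()
            t = matrix.total[sub.index][:, ix].sum()
            rec[grp] = m / t if t else np.nan
        rows.append(rec)
    return pd.DataFrame(rows).set_index("gene")


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def simulate_expression(
    config: SimulationConfig,
    annotation: GenomeAnnotation,
    promoter_meth: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series, pd.DataFrame]:
    """Negative-binomial counts coupled to promoter methylation.

    ``promoter_meth`` is a genes x groups table of promoter methylation
    fractions (e.g. from :func:`promoter_methylation_by_gene`, or the
    generator's true means).  Mean counts are
    baseline * 2^(coupling * promoter_meth + oxygen effect for DE genes)
    over a full oxygen x age factorial; half the H10 samples are labelled
    as having enlarged hearts.  Returns (counts, design, gene lengths,
    DE ground truth).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    genes = [g.gene_id for g in annotation.genes]
    lengths = pd.Series(
        {g.gene_id: sum(e - s for s, e in g.exons) for g in annotation.genes},
        name="length",
    )

    n_cell = config.n_expression_samples_per_cell
    design_rows = []
    for ox in GROUPS:
        for age in ("7mo", "9mo"):
            for i in range(n_cell):
                design_rows.append({"oxygen": ox, "age": age})
    design = pd.DataFrame(design_rows)
    design.index = [
        f"{r.oxygen}_{r.age}_{i % n_cell + 1}" for i, r in enumerate(design.itertuples())
    ]
    design["heart"] = "normal"
    h10 = design.index[design["oxygen"] == "H10"]
    design.loc[h10[: len(h10) // 2], "heart"] = "enlarged"

    mu0, sd0 = config.expression_baseline_log2
    baseline = 2.0 ** rng.normal(mu0, sd0, size=len(genes))

    n_de = int(round(config.de_fraction * len(genes)))
    de_idx = rng.choice(len(genes), size=n_de, replace=False) if n_de else np.array([], int)
    de_sign = rng.choice([-1.0, 1.0], size=n_de)
    lfc = np.zeros(len(genes))
    lfc[de_idx] = de_sign * config.de_log2fc

    pm = promoter_meth.reindex(genes)
    counts = np.zeros((len(genes), len(design)), dtype=np.int64)
    disp = config.nb_dispersion
    for j, (sample, row) in enumerate(design.iterrows()):
        meth = pm[row["oxygen"]].to_numpy(dtype=float)
        meth = np.nan_to_num(meth, nan=float(np.nanmean(meth)) if np.isfinite(np.nanmean(meth)) else 0.5)
        log2_mu = (
            np.log2(baseline)
            + config.meth_expr_coupling * meth
            + np.where(row["oxygen"] == "H10", lfc, 0.0)
        )
        mu = 2.0 ** log2_mu
        if disp > 0:
            lam = rng.gamma(shape=1.0 / disp, scale=mu * disp)
        else:
            lam = mu
        counts[:, j] = rng.poisson(lam)

    counts_df = pd.DataFrame(counts, index=genes, columns=design.index)
    truth = pd.DataFrame(
        {"gene": np.array(genes)[de_idx], "log2fc": lfc[de_idx]}
    ).set_index("gene")
    return counts_df, design, lengths, truth


# ---------------------------------------------------------------------------
# Haemodynamics
# ---------------------------------------------------------------------------

def simulate_haemodynamics(
    seed: int = 0,
    n_n21: int = 6,
    n_h10: int = 5,
    n_baseline: int = 2,
    n_anoxia: int = 24,
    n_reox: int = 6,
    bradycardia: dict[str, float] | None = None,
    noise_sd: float = 0.03,
) -> pd.DataFrame:
    """Per-animal 5-min-window channel means for an anoxia protocol.

    Heart rate falls during anoxia by a group-dependent fraction
    (default 34% in N21 vs 20% in H10, the magnitudes the analysis is
    meant to recover), flows fall with it, and pressure falls mildly;
    multiplicative lognormal noise is applied throughout.
    """
    bradycardia = bradycardia or {"N21": 0.34, "H10": 0.20}
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    rows = []
    n_windows = n_baseline + n_anoxia + n_reox
    for group, n_animals in (("N21", n_n21), ("H10", n_h10)):
        for a in range(n_animals):
            animal = f"{group}_{a + 1}"
            base_fh = rng.normal(32.0, 3.0)
            base_flows = {
                "q_right_aorta_bundle": rng.normal(18.0, 2.0),
                "q_left_aorta": rng.normal(6.0, 1.0),
                "q_left_carotid": rng.normal(3.0, 0.5),
                "q_left_pulmonary": rng.normal(12.0, 1.5),
            }
            base_psys = rng.normal(3.2, 0.3)
            base_pdia = rng.normal(1.8, 0.2)
            drop = bradycardia[group]
            for w in range(n_windows):
                if w < n_baseline:
                    depth = 0.0
                elif w < n_baseline + n_anoxia:
                    # ramp to full bradycardia over the anoxic period
                    depth = drop * min(1.0, (w - n_baseline + 1) / (n_anoxia * 0.6))
                else:
                    depth = drop * 0.2  # partial recovery on reoxygenation
                noise = lambda: np.exp(rng.normal(0.0, noise_sd))
                fh = base_fh * (1 - depth) * noise()
                # pulmonary flow falls harder than systemic (R-L shunt)
                rec = {
                    "animal": animal,
                    "group": group,
                    "window": w,
                    "heart_rate": fh,
                    "q_right_aorta_bundle": base_flows["q_right_aorta_bundle"] * (1 - 0.8 * depth) * noise(),
                    "q_left_aorta": base_flows["q_left_aorta"] * (1 - 0.8 * depth) * noise(),
                    "q_left_carotid": base_flows["q_left_carotid"] * (1 - 0.8 * depth) * noise(),
                    "q_left_pulmonary": base_flows["q_left_pulmonary"] * (1 - 1.5 * depth * 0.9) * noise(),
                    "p_diastolic": base_pdia * (1 - 0.1 * depth) * noise(),
                }
                rec["p_systolic"] = rec["p_diastolic"] + (base_psys - base_pdia) * (1 - 0.2 * depth) * noise()
                rows.append(rec)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# File emission
# ---------------------------------------------------------------------------

def write_fasta(genome: dict[str, str], path) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(seq), id=chrom, description="") for chrom, seq in genome.items()]
    SeqIO.write(records, str(path), "fasta")


def simulate_all(config: SimulationConfig, outdir: str | os.PathLike) -> dict:
    """Run all generators and write the standard file set.

    Emits genome.fa, annotation.gff3/.bed12, per-sample cytosine reports,
    counts.tsv, samples.tsv, gene_lengths.tsv, haemodynamics.tsv, and
    ground-truth tables (islands_truth.bed, dm_truth.tsv, de_truth.tsv).
    """
    outdir = str(outdir)
    os.makedirs(outdir, exist_ok=True)
    genome, annotation, islands = simulate_genome_and_annotation(config)
    matrix, groups, dm_truth = simulate_methylome(config, genome, annotation)
    pm = promoter_methylation_by_gene(config, annotation, matrix, groups)
    counts, design, lengths, de_truth = simulate_expression(config, annotation, pm)
    haemo = simulate_haemodynamics(seed=config.seed)

    write_fasta(genome, os.path.join(outdir, "genome.fa"))
    annotation.to_gff3(os.path.join(outdir, "annotation.gff3"))
    annotation.to_bed12(os.path.join(outdir, "annotation.bed12"))
    matrix.to_cytosine_reports(outdir)
    counts.to_csv(os.path.join(outdir, "counts.tsv"), sep="\t")
    design.to_csv(os.path.join(outdir, "samples.tsv"), sep="\t")
    lengths.to_csv(os.path.join(outdir, "gene_lengths.tsv"), sep="\t")
    haemo.to_csv(os.path.join(outdir, "haemodynamics.tsv"), sep="\t", index=False)
    islands.to_csv(os.path.join(outdir, "islands_truth.bed"), sep="\t", index=False, header=False)
    dm_truth.to_csv(os.path.join(outdir, "dm_truth.tsv"), sep="\t", index=False)
    de_truth.to_csv(os.path.join(outdir, "de_truth.tsv"), sep="\t")
    pd.Series(groups, name="group").rename_axis("sample").to_csv(
        os.path.join(outdir, "methylome_groups.tsv"), sep="\t"
    )
    return {
        "genome": genome,
        "annotation": annotation,
        "islands": islands,
        "matrix": matrix,
        "groups": groups,
        "dm_truth": dm_truth,
        "counts": counts,
        "design": design,
        "gene_lengths": lengths,
        "de_truth": de_truth,
        "haemodynamics": haemo,
    }
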