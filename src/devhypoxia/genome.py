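"""Genome sequence features: CpG sites, CpG islands, and the genomic feature partition.

CpG islands are called with the classic sliding-window observed/expected
criterion (Gardiner-Garden & Frommer style, as implemented by EMBOSS
``newcpgreport`` defaults): a 100-bp window qualifies when GC% > 50 and
Obs/Exp = (#CpG x window)/(#C x #G) > 0.6; qualifying windows are merged,
trimmed to the outermost CpG, and the merged segment must still pass both
criteria at length > 200 bp.

The feature partition splits every base of the genome into exactly one of
{promoter, gene body, intergenic}, with gene bodies further divided into
{first exon, remaining exons, intron}.  Promoters are the 1000 bp
immediately upstream of the TSS (strand aware).  Where a promoter of one
gene overlaps the body of another, the gene body wins, so the three
top-level lengths always sum to the genome length.

All coordinates are 0-based half-open.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

FEATURE_LABELS = ("promoter", "gene_body", "intergenic")
SUBFEATURE_LABELS = ("promoter", "first_exon", "remaining_exons", "intron", "intergenic")

_A, _C, _G, _T = (ord(b) for b in "ACGT")


@dataclass(frozen=True)
class Gene:
    """A gene model: strand and sorted, non-overlapping exon intervals."""

    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        ex = tuple(sorted((int(s), int(e)) for s, e in self.exons))
        for (s1, e1), (s2, e2) in zip(ex, ex[1:]):
            if e1 > s2:
                raise ValueError(f"overlapping exons in gene {self.gene_id}")
        if any(s >= e for s, e in ex):
            raise ValueError(f"empty exon in gene {self.gene_id}")
        object.__setattr__(self, "exons", ex)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def tss(self) -> int:
        """Transcription start site: 5'-most boundary on the coding strand.

        On the minus strand this is the gene's highest genomic coordinate
        (half-open end), so the promoter is [tss, tss + L).
        """
        return self.start if self.strand == "+" else self.end

    @property
    def first_exon(self) -> tuple[int, int]:
        return self.exons[0] if self.strand == "+" else self.exons[-1]


@dataclass
class GenomeAnnotation:
    chrom_lengths: dict[str, int]
    genes: list[Gene] = field(default_factory=list)

    def __post_init__(self):
        for g in self.genes:
            if g.chrom not in self.chrom_lengths:
                raise ValueError(f"gene {g.gene_id} on unknown chrom {g.chrom}")
            if g.end > self.chrom_lengths[g.chrom]:
                raise ValueError(f"gene {g.gene_id} extends past chrom end")

    @property
    def genome_length(self) -> int:
        return sum(self.chrom_lengths.values())

    def genes_on(self, chrom: str) -> list[Gene]:
        return [g for g in self.genes if g.chrom == chrom]

    # ---- I/O ------------------------------------------------------------
    def to_gff3(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for chrom, length in self.chrom_lengths.items():
                fh.write(f"##sequence-region {chrom} 1 {length}\n")
            for g in sorted(self.genes, key=lambda g: (g.chrom, g.start)):
                fh.write(
                    f"{g.chrom}\tdevhypoxia\tgene\t{g.start + 1}\t{g.end}\t.\t"
                    f"{g.strand}\t.\tID={g.gene_id}\n"
                )
                for i, (s, e) in enumerate(g.exons, 1):
                    fh.write(
                        f"{g.chrom}\tdevhypoxia\texon\t{s + 1}\t{e}\t.\t"
                        f"{g.strand}\t.\tID={g.gene_id}.exon{i};Parent={g.gene_id}\n"
                    )

    @classmethod
    def from_gff3(cls, path, chrom_lengths: dict[str, int] | None = None) -> "GenomeAnnotation":
        lengths: dict[str, int] = dict(chrom_lengths or {})
        gene_strand: dict[str, tuple[str, str]] = {}
        exons: dict[str, list[tuple[int, int]]] = {}
        with open(path) as fh:
            for line in fh:
                if line.startswith("##sequence-region"):
                    _, chrom, _one, end = line.split()[:4]
                    lengths.setdefault(chrom, int(end))
                    continue
                if line.startswith("#") or not line.strip():
                    continue
                chrom, _src, ftype, start, end, _score, strand, _phase, attrs = (
                    line.rstrip("\n").split("\t")
                )
                tags = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
                if ftype == "gene":
                    gene_strand[tags["ID"]] = (chrom, strand)
                elif ftype == "exon":
                    exons.setdefault(tags["Parent"], []).append((int(start) - 1, int(end)))
        genes = [
            Gene(gid, chrom, strand, tuple(sorted(exons.get(gid, []))))
            for gid, (chrom, strand) in gene_strand.items()
        ]
        for chrom in {g.chrom for g in genes}:
            lengths.setdefault(chrom, max(g.end for g in genes if g.chrom == chrom))
        return cls(lengths, genes)

    def to_bed12(self, path) -> None:
        with open(path, "w") as fh:
            for g in sorted(self.genes, key=lambda g: (g.chrom, g.start)):
                sizes = ",".join(str(e - s) for s, e in g.exons)
                starts = ",".join(str(s - g.start) for s, _ in g.exons)
                fh.write(
                    f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\t"
                    f"{g.start}\t{g.end}\t0\t{len(g.exons)}\t{sizes},\t{starts},\n"
                )


# ---------------------------------------------------------------------------
# CpG sites and islands
# ---------------------------------------------------------------------------

def _seq_to_array(sequence: str) -> np.ndarray:
    return np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)


def locate_cpgs(sequence: str) -> np.ndarray:
    """Positions (of the C, 0-based, forward strand) of every CpG dinucleotide.

    A CpG dyad is palindromic; the site is anchored at the forward-strand C
    and represents both strands.
    """
    s = _seq_to_array(sequence)
    if s.size < 2:
        return np.empty(0, dtype=np.int64)
    return np.nonzero((s[:-1] == _C) & (s[1:] == _G))[0]


@dataclass(frozen=True)
class CpGIsland:
    chrom: str
    start: int
    end: int
    gc_percent: float
    obs_exp: float

    @property
    def length(self) -> int:
        return self.end - self.start


def _segment_stats(s: np.ndarray, start: int, end: int) -> tuple[float, float]:
    """(GC%, Obs/Exp) over s[start:end]."""
    seg = s[start:end]
    n_c = int((seg == _C).sum())
    n_g = int((seg == _G).sum())
    n_cg = int(((seg[:-1] == _C) & (seg[1:] == _G)).sum())
    length = end - start
    gc = 100.0 * (n_c + n_g) / length
    obs_exp = (n_cg * length / (n_c * n_g)) if n_c and n_g else 0.0
    return gc, obs_exp


def call_cpg_islands(
    sequence: str,
    chrom: str = "chr",
    window: int = 100,
    min_len: int = 200,
    min_gc: float = 50.0,
    min_obsexp: float = 0.6,
) -> list[CpGIsland]:
    """Call CpG islands by the sliding-window Obs/Exp criterion.

    Every 1-bp-step window of ``window`` bp is scored; windows with
    GC% > ``min_gc`` and Obs/Exp > ``min_obsexp`` are merged, the merged
    segment is trimmed to its outermost CpG dinucleotides, and kept only if
    its whole-segment GC%, Obs/Exp and length (> ``min_len``) still pass.
    """
    s = _seq_to_array(sequence)
    if s.size < window:
        warnings.warn("sequence shorter than window; no islands called", stacklevel=2)
        return []

    is_c = (s == _C).astype(np.int64)
    is_g = (s == _G).astype(np.int64)
    is_cg = np.zeros(s.size, dtype=np.int64)
    if s.size >= 2:
        is_cg[:-1] = (s[:-1] == _C) & (s[1:] == _G)

    cum_c = np.concatenate([[0], np.cumsum(is_c)])
    cum_g = np.concatenate([[0], np.cumsum(is_g)])
    cum_cg = np.concatenate([[0], np.cumsum(is_cg)])

    starts = np.arange(s.size - window + 1)
    n_c = cum_c[starts + window] - cum_c[starts]
    n_g = cum_g[starts + window] - cum_g[starts]
    # CpGs fully inside the window: the C at most at position start+window-2
    n_cg = cum_cg[starts + window - 1] - cum_cg[starts]

    gc_ok = (n_c + n_g) * 100.0 > min_gc * window
    with np.errstate(divide="ignore", invalid="ignore"):
        oe_ok = (n_cg * window) > (min_obsexp * n_c * n_g)
    qual = gc_ok & oe_ok & (n_c > 0) & (n_g > 0)

    islands: list[CpGIsland] = []
    if not qual.any():
        return islands

    # merge runs of qualifying window starts; run [a, b] covers [a, b + window)
    q = np.nonzero(qual)[0]
    breaks = np.nonzero(np.diff(q) > 1)[0]
    run_starts = np.concatenate([[q[0]], q[breaks + 1]])
    run_ends = np.concatenate([q[breaks], [q[-1]]]) + window

    cpg_pos = np.nonzero(is_cg)[0]
    for seg_start, seg_end in zip(run_starts, run_ends):
        inside = cpg_pos[(cpg_pos >= seg_start) & (cpg_pos + 2 <= seg_end)]
        if inside.size == 0:
            continue
        t_start, t_end = int(inside[0]), int(inside[-1] + 2)
        if t_end - t_start <= min_len:
            continue
        gc, oe = _segment_stats(s, t_start, t_end)
        if gc > min_gc and oe > min_obsexp:
            islands.append(CpGIsland(chrom, t_start, t_end, gc, oe))
    return islands


def islands_to_frame(islands: list[CpGIsland]) -> pd.DataFrame:
    return pd.DataFrame(
        [(i.chrom, i.start, i.end, i.length, i.gc_percent, i.obs_exp) for i in islands],
        columns=["chrom", "start", "end", "length", "gc_percent", "obs_exp"],
    )


# ---------------------------------------------------------------------------
# Interval arithmetic (plain sorted half-open interval lists)
# ---------------------------------------------------------------------------

def merge_intervals(intervals) -> list[tuple[int, int]]:
    ivs = sorted((int(s), int(e)) for s, e in intervals if e > s)
    out: list[tuple[int, int]] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def subtract_intervals(a, b) -> list[tuple[int, int]]:
    """Set difference a \\ b; both merged-sorted half-open interval lists."""
    b = merge_intervals(b)
    out: list[tuple[int, int]] = []
    for s, e in merge_intervals(a):
        cur = s
        for bs, be in b:
            if be <= cur or bs >= e:
                continue
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
            if cur >= e:
                break
        if cur < e:
            out.append((cur, e))
    return out


def total_length(intervals) -> int:
    return sum(e - s for s, e in intervals)


# ---------------------------------------------------------------------------
# Feature partition
# ---------------------------------------------------------------------------

@dataclass
class FeaturePartition:
    """Disjoint labeled intervals per chromosome, at two resolutions.

    ``top`` labels each base promoter / gene_body / intergenic; ``sub``
    splits gene bodies into first_exon / remaining_exons / intron.
    """

    top: dict[str, dict[str, list[tuple[int, int]]]]
    sub: dict[str, dict[str, list[tuple[int, int]]]]
    chrom_lengths: dict[str, int]

    @property
    def lengths(self) -> dict[str, int]:
        out = {lab: 0 for lab in FEATURE_LABELS + SUBFEATURE_LABELS[1:-1]}
        for chrom in self.top:
            for lab in FEATURE_LABELS:
                out[lab] += total_length(self.top[chrom].get(lab, []))
            for lab in ("first_exon", "remaining_exons", "intron"):
                out[lab] += total_length(self.sub[chrom].get(lab, []))
        return out

    def label_positions(self, chrom: str, positions, level: str = "top") -> np.ndarray:
        """Feature label of each position (vectorised interval lookup)."""
        table = (self.top if level == "top" else self.sub)[chrom]
        positions = np.asarray(positions)
        labels = np.full(positions.shape, "intergenic", dtype=object)
        for lab, ivs in table.items():
            if not ivs:
                continue
            starts = np.array([s for s, _ in ivs])
            ends = np.array([e for _, e in ivs])
            idx = np.searchsorted(starts, positions, side="right") - 1
            ok = (idx >= 0) & (positions < ends[np.clip(idx, 0, None)])
            labels[ok] = lab
        return labels

    def to_bed(self, path, level: str = "top") -> None:
        table = self.top if level == "top" else self.sub
        with open(path, "w") as fh:
            for chrom in sorted(table):
                rows = [
                    (s, e, lab)
                    for lab, ivs in table[chrom].items()
                    for s, e in ivs
                ]
                for s, e, lab in sorted(rows):
                    fh.write(f"{chrom}\t{s}\t{e}\t{lab}\n")


def partition_features(
    annotation: GenomeAnnotation, promoter_length: int = 1000
) -> FeaturePartition:
    """Partition the genome into promoter / gene-body / intergenic intervals.

    Strand-aware promoters are the ``promoter_length`` bases immediately
    upstream of each TSS, clipped at chromosome bounds.  Precedence is
    gene_body > promoter > intergenic, so the partition is exact.
    """
    top: dict[str, dict[str, list[tuple[int, int]]]] = {}
    sub: dict[str, dict[str, list[tuple[int, int]]]] = {}
    for chrom, length in annotation.chrom_lengths.items():
        genes = annotation.genes_on(chrom)
        bodies = merge_intervals([(g.start, g.end) for g in genes])

        promoters = []
        for g in genes:
            if g.strand == "+":
                p = (g.tss - promoter_length, g.tss)
            else:
                p = (g.tss, g.tss + promoter_length)
            clipped = (max(0, p[0]), min(length, p[1]))
            if clipped != p:
                warnings.warn(
                    f"promoter of {g.gene_id} clipped to chromosome bounds",
                    stacklevel=2,
                )
            promoters.append(clipped)
        promoters = subtract_intervals(merge_intervals(promoters), bodies)
        intergenic = subtract_intervals(
            [(0, length)], merge_intervals(list(promoters) + bodies)
        )
        top[chrom] = {
            "promoter": promoters,
            "gene_body": bodies,
            "intergenic": intergenic,
        }

        first_exons, remaining = [], []
        for g in genes:
            first_exons.append(g.first_exon)
            remaining.extend(ex for ex in g.exons if ex != g.first_exon)
        first_exons = merge_intervals(first_exons)
        # precedence within gene bodies: first_exon > remaining_exons > intron
        remaining = subtract_intervals(merge_intervals(remaining), first_exons)
        introns = subtract_intervals(
            bodies, merge_intervals(first_exons + remaining)
        )
        sub[chrom] = {
            "promoter": promoters,
            "first_exon": first_exons,
            "remaining_exons": remaining,
            "intron": introns,
            "intergenic": intergenic,
        }
    return FeaturePartition(top=top, sub=sub, chrom_lengths=dict(annotation.chrom_lengths))


# ---------------------------------------------------------------------------
# Expected island counts (proportional allocation)
# ---------------------------------------------------------------------------

def expected_island_counts(
    feature_lengths: dict[str, int], total_islands: int
) -> dict[str, int]:
    """Expected CGI count per feature, proportional to feature length.

    Rounded with the largest-remainder method so the expecteds sum exactly
    to ``total_islands``.
    """
    genome_length = sum(feature_lengths.values())
    if genome_length <= 0:
        raise ValueError("feature lengths must sum to a positive genome length")
    if total_islands < 0:
        raise ValueError("total_islands must be >= 0")
    raw = {k: total_islands * v / genome_length for k, v in feature_lengths.items()}
    out = {k: int(np.floor(v)) for k, v in raw.items()}
    short = total_islands - sum(out.values())
    by_remainder = sorted(raw, key=lambda k: (raw[k] - out[k], k), reverse=True)
    for k in by_remainder[:short]:
        out[k] += 1
    return out


# ---------------------------------------------------------------------------
# Nearest gene
# ---------------------------------------------------------------------------

def nearest_gene(
    interval: tuple[str, int, int], annotation: GenomeAnnotation
) -> tuple[str, int] | None:
    """Gene whose TSS is nearest the interval midpoint.

    Distance 0 if the midpoint falls inside a gene body; otherwise the
    signed strand-aware distance midpoint-to-TSS (negative upstream of the
    gene).  Ties break toward the lower-coordinate gene.  Returns ``None``
    when the chromosome has no genes.
    """
    chrom, start, end = interval
    genes = sorted(annotation.genes_on(chrom), key=lambda g: (g.start, g.gene_id))
    if not genes:
        return None
    mid = (int(start) + int(end)) // 2
    inside = [g for g in genes if g.start <= mid < g.end]
    if inside:
        return inside[0].gene_id, 0
    best = min(genes, key=lambda g: (abs(g.tss - mid), g.start, g.gene_id))
    raw = mid - best.tss
    signed = raw if best.strand == "+" else -raw
    return best.gene_id, int(signed)
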