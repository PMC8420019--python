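# Methods

This note records the statistical and numerical choices behind each
pipeline stage, what the synthetic-data generator does and does not
emulate, and the package's known limitations.

## Coordinates and CpG sites

All internal coordinates are 0-based half-open; GFF3 and cytosine-report
positions are converted on I/O, BED is native. A CpG dyad is palindromic,
so the package keeps **one site per dyad**, anchored at the
forward-strand C; minus-strand cytosine counts from cytosine reports are
merged into the forward anchor on load. Site counts are therefore dyad
counts, not strand-resolved counts.

## CpG-island calling

The caller implements the sliding-window Gardiner-Garden & Frommer
criterion with the defaults GC% > 50, Obs/Exp > 0.6, length > 200 bp,
window 100 bp, step 1 bp. Obs/Exp for a region of length L is
(#CpG × L)/(#C × #G), counting only CpGs fully inside the region.
Qualifying windows are merged, each merged segment is trimmed to its
outermost CpG dinucleotides, and the segment is kept only if its
whole-segment GC%, Obs/Exp and length still pass. The merge/trim
micro-behaviour of historical island callers differs between
implementations and is not fully documented anywhere; the rule above is
fixed as this package's definition and is validated against a
brute-force enumerate-all-windows oracle rather than against any
particular binary's output.

## Feature partition

Promoters are the `promoter_length` (default 1000 bp) bases immediately
upstream of the TSS, strand-aware, clipped at chromosome bounds; the TSS
is the 5′-most exon boundary of the gene (one promoter per gene, not per
transcript). Precedence is gene body > promoter > intergenic, which
makes the three top-level labels an exact partition of the genome —
the property that length-proportional expected island counts rely on.
Within gene bodies the 5′-most exon is the first exon, other exons are
"remaining exons", and introns are the body minus all exons
(first exon > remaining exons > intron where annotations overlap).
Expected island counts use largest-remainder rounding so they sum
exactly to the observed total.

## Differential methylation

*Per-CpG test.* A two-group binomial logistic regression on
(methylated, total) counts with a group indicator, tested by likelihood
ratio against χ²(1). Because all replicates within a group share one
proportion, the MLEs are the read-pooled group proportions and the LRT
has a closed form — this is the replicate-pooling default of the
standard WGBS callers. The significance rule is |Δ| > 25 percentage
points (pooled levels) **and** BH *q* < 0.01. No overdispersion
correction is applied by default, matching those callers' defaults; a
per-site Pearson-dispersion scaling is available via
`overdispersion="scale"`. Empirical FDR on beta-binomial nulls
(precision 50) stays well under the nominal level because the Δ > 25
filter removes nearly all null rejections.

*Windows.* 200-bp windows at 50-bp steps starting at coordinate 0;
counts are summed over contained sites and tested identically; DMRs are
windows with *q* < 0.001, and a gene is differentially methylated when
at least one DMR overlaps its promoter or gene body.

*Islands.* Per island and group, the level is the read-pooled fraction
ΣM/ΣT over contained sites (the "sum of methylated CpGs over total
CpGs" reading of region-level methylation; a per-site-average
alternative is available via `level_method="site_mean"`). Groups are
compared by a two-sided Fisher exact test on the pooled 2×2 table at
*q* < 0.05.

BH correction is applied within each unit family (sites, windows,
islands) separately, mirroring the separate q thresholds.

## Differential expression

The contribution here is the **decision procedure**, not a count-model
novelty: a gene is differentially expressed only when two models with
different variance philosophies agree and the call is not driven by a
single animal.

* Primary leg: per-gene negative-binomial GLM Wald tests (sum-coded
  oxygen, age, interaction; log size-factor offset). Size factors are
  DESeq-style median-of-ratios; the per-gene dispersion is a
  method-of-moments estimate pooled over design cells, floored at 1e-8
  (no shrinkage across genes — the hierarchical shrinkage of dedicated
  DE packages is deliberately out of scope, and an external per-gene
  p-value table can be slotted in as the primary leg instead).
* Confirmation leg: two-way ANOVA (type-II F tests) on log₂(FPKM+1).
  The confirmation threshold is not dictated by the upstream study
  design and defaults to 0.05 (exposed).
* Concordance: both legs significant for the effect; for the oxygen
  main effect the coefficient signs must also agree (direction of
  interaction terms has no natural definition and is not checked).
* Outlier screen: the "manually inspect for outlier-driven calls" step
  is formalised as leave-one-out stability — drop the single sample
  with the largest internally studentized ANOVA residual and require
  both legs to remain significant. This proxy is deterministic and
  logged per gene.
* Heart-size contrast (normal vs enlarged): single-factor NB Wald with
  BH FDR < 0.1, reported separately; the final DE set is oxygen ∪
  interaction ∪ heart-size (age-only genes are not followed up).

FPKM uses exon-union gene lengths and library sizes = column sums.
Expression deciles/quintiles rank detectable genes (mean FPKM > 0,
configurable) ascending with stable tie-breaking; bin sizes differ by at
most one.

The qPCR-style ANCOVA standardises ≥3 control genes, takes PC1 of the
sample scores as a covariate for RNA-quality/RT-efficiency variation,
and reports type-II F tests for oxygen, age, interaction and the
covariate per target gene; rank-deficient designs fail loudly naming
the aliased term.

## Integration

Spearman correlations are **site-wise**: every CpG contributes one
(level, host-gene expression bin) observation, with the host gene being
the one with the nearest TSS. TSS meta-profiles use signed strand-aware
distances (upstream negative on both strands) within ±3 kb, smoothed per
expression bin by local-linear tricube LOESS (span 0.3, exposed)
evaluated on a 50-bp grid; the lowess anchor spacing (`delta`) equals
the grid step so genome-scale fits stay linear-time, which leaves
local-linear exactness on linear signals intact. Bins with fewer than
50 sites are suppressed rather than smoothed.

Enrichment comparisons use OR = ad/bc with a Haldane +0.5 on all cells
when any cell is zero, a Woolf log-OR normal 95% CI on the (possibly
corrected) table, and a two-sided Fisher exact p (sum of hypergeometric
probabilities ≤ the observed table's). Conditional-MLE odds ratios and
their CIs, as printed by some statistics suites, differ slightly from
Woolf CIs; the simpler documented method is fixed here.

## Haemodynamics

Channel aggregation reflects the probe layout: one probe measures the
right aorta + both subclavians + right carotid as a bundle, so systemic
flow = bundle + left aorta + left carotid (no vessel double-counted)
and pulmonary flow = 2× the left pulmonary artery (left/right assumed
equal). Stroke volumes are Q̇/f_H per circuit; net shunt Q̇_Pul − Q̇_Sys
(negative = right-to-left); shunt ratio Q̇_Pul/Q̇_Sys; mean ventricular
pressure (P_sys + 2·P_dia)/3; power output PO = Q̇_Tot·ΔP/heart mass
with flow converted to mL s⁻¹ so kPa·mL s⁻¹ = mW and PO is in mW g⁻¹
(the defining formula is unit-agnostic; this convention is fixed and
must be kept in mind when comparing absolute PO values across studies).
Zero heart rate or zero systemic flow yield flagged NaNs, not errors.
Group time-courses are summarised as mean ± SEM of per-animal percent
changes from baseline; mixed-effects modelling of the time-courses is
out of scope.

## Synthetic-data generator

The generator is first-class, tested code; its defaults are the
conditions the pipeline is validated under.

* **Genome**: i.i.d. background at GC 0.40 with 70% of background CpGs
  deaminated C→T, giving the CpG depletion (background Obs/Exp well
  below the island threshold) characteristic of vertebrate genomes.
  Islands (default 40 per 2 Mb, 300–800 bp) are built from a mixture of
  explicit CG units and GC-rich filler, rejection-sampled until the
  realized segment meets GC ≥ 0.65 and Obs/Exp ≥ 0.75 — comfortably
  clear of the 0.50/0.60 calling thresholds, as real islands are;
  `island_gc=1` degenerates to a pure CG repeat. Genes (default 200)
  are placed non-overlapping with ≥1.5-kb spacing on both strands, so
  the feature partition is unambiguous and the expected-count
  arithmetic exact.
* **Methylome**: per sample, site totals ~ Poisson(30); methylated
  counts ~ beta-binomial with precision 50 around feature means —
  gene bodies 0.85, intergenic 0.75, promoters a per-gene two-component
  mixture (0.05 w.p. 0.45, 0.95 w.p. 0.55) reproducing the observed
  bimodality of promoter methylation. Precision 50 gives the modest
  replicate overdispersion of good-quality WGBS libraries; it exists so
  the per-CpG test is exercised against overdispersed replicates rather
  than idealized binomial ones. A planted 2% of sites get a ±0.40 group
  offset (clipped to [0,1]); 0.40 sits clearly above the 25-point
  calling threshold, the only anchor available for an effect size.
* **Expression**: a 2×2×4 oxygen × age factorial (16 samples, the
  scale of the motivating study), counts ~ gamma-Poisson with
  dispersion 0.05 around baseline × 2^(−3 × promoter methylation +
  planted oxygen effect). The −3 coupling makes promoter methylation
  and expression strongly anticorrelated by construction; planted DE
  genes (10%) carry |log2FC| = 2. Half the hypoxic samples are labelled
  as enlarged hearts. Because expression is coupled to group-specific
  promoter methylation, planted promoter DM can itself induce
  expression differences — a deliberate, biologically motivated
  leakage.
* **Haemodynamics**: per-animal 5-min window means over baseline,
  anoxia and reoxygenation, with anoxic bradycardia ramping to −34%
  (N21) vs −20% (H10), pulmonary flow falling harder than systemic
  (right-to-left shunt) and mild pressure decline, under multiplicative
  lognormal noise.

Everything is deterministic given (config, seed): identical
configurations give byte-identical outputs, and ground-truth tables are
always returned/emitted alongside the data.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: read-level artefacts (mapping bias,
incomplete bisulfite conversion, PCR duplicates), spatial correlation
of methylation beyond feature identity, repeat structure and
non-uniform gene density, expression covariance between genes, batch
effects, and biological covariance between the methylome and
haemodynamic phenotypes.

## Verification sizes

The test suite validates the island caller against the brute-force
oracle on one hundred 50-kb sequences; the Fisher p against explicit
hypergeometric enumeration exhaustively for every 2×2 table with
n ≤ 60 (via canonical representatives under row/column/transpose
symmetry, which is itself spot-checked) plus 2,000 random tables up to
n = 200; BH against the literal step-up definition on random vectors;
empirical FDR of the per-CpG test on >10,000 simulated null sites;
detection power at planted 0.2-vs-0.6 sites (100 replicates) and
planted 4-fold DE genes (100 replicates); and partition closure on
every simulated annotation. The acceptance script's end-to-end run uses
a 2-Mb, 200-gene genome with 3 vs 3 methylome replicates and 16
expression samples — sizes chosen so the full pipeline, including the
per-gene dual-model fits, completes in well under a minute while every
stage still operates far from small-sample degeneracy.

## Known limitations

* The NB leg uses per-gene method-of-moments dispersion without
  cross-gene shrinkage; with 3–4 samples per cell its dispersion
  estimates are noisy, which the concordance-with-ANOVA requirement is
  designed to absorb.
* The per-CpG LRT ignores replicate overdispersion by default (by
  design, matching the standard callers); heavily overdispersed data
  should use `overdispersion="scale"`.
* Island-level Fisher tests pool reads across replicates and therefore
  treat reads, not animals, as the unit of evidence.
* CHG/CHH methylation, bisulfite-conversion-rate estimation and
  alignment are out of scope; inputs start at cytosine-report /
  count-matrix level.
* Woolf CIs (with Haldane correction) are reported for odds ratios;
  exact conditional CIs are not implemented.
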