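# Methods

## The model

The package treats a genome assembly as a mosaic of two compartments. TE
islands are intervals whose windowed TE content sits in the extreme upper
tail of the genome-wide distribution; low-density regions (LDRs) are the
complement on the same scaffolds. The working hypothesis behind every
downstream statistic is that the two compartments evolve at different rates:
islands accumulate structural divergence between lineages, carry fewer,
more weakly expressed and more strongly methylated (CpG-depleted) genes, and
are populated unevenly by repeat superfamilies.

All internal coordinates are 1-based inclusive (GFF convention); 0-based
half-open appears only in BED output. Strand is carried everywhere but used
only by codon translation — density statistics are strand-blind.

## Island calling

1. **1 kb tiling.** Each scaffold is tiled into non-overlapping 1 kb windows
   carrying TE bp, exon bp, per-lineage/per-zygosity SNV counts and mean
   depth. Overlapping annotations of the same kind are union-merged first,
   so window content never exceeds window length; the terminal partial
   window keeps its true effective length.
2. **200 kb aggregation.** Sliding 200 kb windows advance in 1 kb steps and
   sum their constituent full 1 kb tiles; windows that would overhang the
   scaffold end are not emitted, which restricts the analysis to scaffolds
   of at least 200 kb (the `min_scaffold` default).
3. **Quantile threshold.** The TE-bp threshold is the type-7 empirical
   quantile (default 0.95) over *all* eligible-scaffold windows, not per
   scaffold: per-scaffold thresholds would force an island onto every
   scaffold regardless of content (a per-scaffold mode exists behind
   `per_scaffold_quantile` for comparison). Qualification is closed
   (`te_bp ≥ threshold`), matching a 95–100 % quantile band. If every window
   has identical nonzero TE content the call is degenerate: a warning is
   raised and everything qualifies, leaving inspection to the caller. A
   genome with no TE annotation at all yields zero islands.
4. **Boundary refinement.** A 200 kb window overhanging an island edge still
   qualifies, so raw unions overshoot island boundaries by up to one window
   length. Each raw interval is therefore shrunk at 1 kb resolution to the
   outermost run of ≥ 3 consecutive tiles whose TE fraction reaches
   `max(genome mean tile fraction, interval mean tile fraction / 2)`.
   A run criterion is used rather than tile-by-tile peeling because the
   genome-wide *median* 1 kb TE fraction is typically zero in an
   LDR-dominated genome (most tiles carry no TE), which would make any
   single-tile peel rule stop at the first stray covered tile and leave tens
   of kb of overhang. Intervals shorter than `min_island` (default 10 kb —
   permissive, intended only to suppress one-window specks) are dropped.
5. **Summary.** Island count, span and % of assembly; TE bp inside islands
   and its share of all TE sequence; genes assigned by midpoint; exon bp/kb
   per compartment.

On the default synthetic conditions this recovers planted islands with
interval Jaccard ≈ 0.86–0.97 over 20 seeds.

## Divergence between lineages

* **Coverage ratio.** Per 1 kb window, `r = depth_A/depth_B` (orientation is
  fixed by the order the two depth tracks are supplied). Windows below
  `min_depth` (default 5×) in either lineage are masked — ratios at
  negligible coverage are mapping artifacts, so no pseudocounts are used.
  Deviation is `d = |r/median(r) − 1|`; the median (over unmasked windows)
  is the default center for outlier robustness, the mean is available via
  `ratio_center`. Region medians are compared with a two-sided Mann–Whitney
  *U*-test; windows are assigned by midpoint, which is unambiguous for
  windows straddling island edges.
* **CNV candidates.** Unmasked windows with `d ≥ deviation_threshold`
  (default 0.5, a free parameter exposed in the config) are merged when
  adjacent, annotated with overlapping genes and region, and ranked by `d`.
* **Collapsed duplications.** For each lineage, het calls are split by depth
  fold over the lineage's median depth: fold ≥ 1.5 (boundary inclusive) is
  labeled `collapsed_duplication`, otherwise `true_het`. The 1.5 default is
  the valley between the 1× mode of true heterozygotes and the 2× mode that
  collapsed duplicated loci produce in haploid pools; the twofold depth is
  the signature, not the cutoff. Zero-depth sites are masked, hom calls pass
  through labeled `hom`.
* **Coding effects.** An SNV inside a complete CDS is annotated by
  translating the codon containing it for both alleles (standard nuclear
  code; minus-strand genes via reverse complement). Incomplete CDS (length
  not divisible by 3), N in the codon, or a reference-allele mismatch with
  the supplied sequence yield `unknown`. Per gene, dN and dS counts give
  `dN/(dN+dS)`; genes with dN+dS = 0 are excluded from the island-vs-LDR
  comparison. Synonymous SNVs per CDS kb are reported per region.

## Composition statistics

* **Fisher exact test, two-sided.** p is the sum of hypergeometric
  probabilities of all tables (same margins) whose probability does not
  exceed the observed table's; conventions for two-sided Fisher tests
  differ between packages, so the rule is implemented explicitly with a
  relative tie tolerance of 1e-12 (a zero margin admits a single table:
  p = 1, odds ratio undefined). The reported odds ratio is the conditional
  MLE. Tests verify exact agreement with integer-arithmetic enumeration for
  every table with total ≤ 40, and with scipy's implementation.
* **BH FDR.** Benjamini–Hochberg step-up (statsmodels), original order
  preserved.
* **Mann–Whitney U.** Midrank ties throughout. Exact p (standard counting
  distribution) when both samples are tie-free and small; full enumeration
  of label assignments for small tied samples when feasible; otherwise the
  normal approximation with tie-corrected variance and continuity
  correction. Two-sided exact p is `P(U ≤ u_lo) + P(U ≥ nm − u_lo)` with
  `u_lo = min(u, nm−u)`, capped at 1. Degenerate all-tied data gives p = 1.
* **Superfamily enrichment.** Per superfamily, the 2×2 table
  [in-island vs in-LDR] × [this superfamily vs all others], run separately
  on copy counts (midpoint assignment) and on bp counts (split exactly at
  island boundaries), each with BH across superfamilies. Under a label
  permutation null ≤ 5 % of superfamilies reach q < 0.05.
* **Term enrichment.** The same machinery per gene term, two-tailed: over-
  and under-represented terms are both reported from the two-sided test's
  direction (odds ratio vs 1).

## CpG and expression

* **o/e CpG.** `o/e = n_CpG · L / (n_C · n_G)` with an overlapping CG scan.
  N bases are excluded from all counts and from L; sequences without C or G
  (or shorter than 2 informative bases) are undefined rather than zero.
  Gene-level values scan exons separately and sum counts, so CG pairs
  spanning exon junctions are not counted — this makes the value independent
  of exon order. Counting is strand-symmetric (CG is its own reverse
  complement; C and G counts swap), so the reference strand is always used.
* **Lineage o/e ratio F-test.** Exon-level o/e is computed on each lineage's
  consensus sequence (homozygous-alt substitutions applied; het sites left
  as reference). Per exon, `ratio = o/e_A / o/e_B` where both values are
  defined and positive; `F = var(island ratios)/var(LDR ratios)` with a
  two-sided p from F(n_isl−1, n_ldr−1). Zero variance in both regions is
  flagged degenerate.
* **Size factors.** Median-of-ratios: the per-gene reference is the
  geometric mean across samples over genes with no zero count (standard
  behavior — genes with any zero would zero the reference); each sample's
  factor is the median ratio to that reference. Because the reference is
  internal, scaling one of m libraries by c rescales all normalized counts
  by the global constant c^(1/m); between-sample structure is exactly
  invariant, and the tests assert exactly that.
* **Expression summaries.** Normalized counts are untransformed per-group
  means. Rank percentiles (0 = least expressed) are defined over genes with
  nonzero total count only; fully silent genes are reported separately, not
  ranked. The rank × o/e curve buckets expressed genes into equal-width
  percentile bins (default 100) and reports the median gene o/e per bin and
  region. Region expression comparisons include zeros in the medians.

## The synthetic generator

The generator produces the statistical structure the analysis assumes, with
ground truth, from a single seed (all outputs byte-identical per seed):

* **Genome.** Uniform-background scaffolds (default 3 × 2 Mb) with planted
  islands (default 2, ~250–350 kb). TE copies are annotation-only intervals
  placed by a renewal walk (exponential gaps tuned to the target occupancy:
  0.45 inside islands, 0.05 outside), with island copies drawn longer
  (1.5–6 kb vs 0.2–1.5 kb) and superfamily weights optionally island-biased.
* **Genes.** Sequential placement rejecting sites with ≥ 50 % TE overlap
  (which naturally thins island genes). CDS frames are valid: ATG start,
  terminal stop, internal stops rewritten. Exon sequence CpG content is
  thinned by removing each CpG with region- and expression-dependent
  survival: island genes keep ~0.4–0.6 of CpGs (increasing with a latent
  expression level), LDR genes ~0.6–1.0 (decreasing) — planting the opposite
  o/e-vs-expression trends the analysis should detect. Thinning can create
  stop codons (e.g. TGG→TAG), so stops are patched again afterwards with
  codons that introduce no CpG.
* **Coverage.** Per-base Poisson around 60× per lineage; planted
  duplications (default 8, 3–8 kb, inside islands) double the rate in one
  randomly chosen lineage. Each 1 kb block additionally carries a lognormal
  depth multiplier per lineage (σ = 0.25 in islands, 0.10 in LDRs),
  emulating locally varying mapping efficiency between diverged pools —
  without it, coverage-ratio deviation would be pure counting noise with
  medians near 0.004, nothing like pooled resequencing data; with it the
  synthetic medians (~0.24 islands / ~0.10 LDRs) have the magnitude and
  contrast real pools show.
* **SNVs.** Homozygous divergence SNVs at region rates (2/kb islands,
  0.5/kb LDRs; hom-alt in one random lineage), background true hets at
  0.05/kb, and spurious hets at 5/kb inside planted duplications in the
  affected lineage. Site read depths in the VCF are Poisson at 1× (2× inside
  a duplication for its lineage) — the clean twofold signature the
  classifier is defined on.
* **Counts.** Negative-binomial (dispersion 0.3; Poisson at dispersion 0)
  around lognormal gene base means, island genes scaled by 0.02, a 4× queen
  effect applied to island genes only, and per-sample library-size factors
  (lognormal σ = 0.2) to exercise normalization.

### What the generator does not emulate

TE copies have no sequence content (annotation intervals only); there is no
read-level error model, no mapper or variant-caller artifacts beyond the
block-level depth noise, no indels, no nested/fragmented TE structure, and
no recombination or phylogenetic structure among copies. Passing recovery
tests therefore demonstrates that the statistical machinery detects the
planted structure under realistic noise magnitudes — not that the pipeline
is robust to alignment pathologies of real pooled data.

## Numerical choices and degenerate inputs

* Quantiles: numpy type-7 (linear interpolation), the default of R and
  numpy.
* Windows: terminal partial 1 kb tiles are kept (with true effective
  length) in the tiling but excluded from 200 kb aggregation sums.
* Region assignment ties: always by interval midpoint (windows, TE copies,
  genes); integer midpoint `(start+end)//2`.
* Empty regions: medians over empty sets are NaN and flagged; tests with an
  empty side are skipped and flagged rather than erroring the pipeline.
* All analysis is deterministic; the only randomness is in the generator,
  seeded once.

## Problem sizes used by the test suite

Recovery properties run the full default conditions (3 × 2 Mb scaffolds)
over 20 seeds; unit and pipeline tests use a reduced genome (2 × 600 kb, one
planted island) whose single island is shorter than one 200 kb aggregation
window — boundary precision is accordingly lower there, and the tests bound
it separately. Oracle tests enumerate all 2×2 tables with total ≤ 40 and 500
random gene/SNV pairs.
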