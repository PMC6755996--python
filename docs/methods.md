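# Methods

## The meta-analysis model

The package treats each differential-expression dataset as a noisy binary
reporter of a gene's true regulation under active p53. A dataset calls a
gene up when log₂FC ≥ 0.5 and BH-adjusted p ≤ 0.05 (both inclusive), down
symmetrically, otherwise not-significant; "present" means the gene has a
row in the dataset's table at all, whatever the verdict — this matches
how pre-processed expression tables behave, where absence means the gene
was not measured or was filtered upstream. The expression score is the
signed vote count `#up − #down`. No attempt is made to model effect-size
magnitude across platforms: different platforms are not directly
comparable, which is the reason for vote counting in the first place.
Genes present in fewer than `min_present = 3` datasets are unscored.
Some studies use thresholds deviating from the 0.5/0.05 defaults to match
their original analyses; per-dataset overrides live in the dataset-config
table (columns `lfc_min`, `p_max`) rather than in code.

Binding evidence is scored the same way: a ChIP dataset supports a gene
when at least one of its peaks has its midpoint within a symmetric window
of the TSS — ±5000 bp for p53, ±1000 bp for E2F4/DREAM, both inclusive at
the boundary. The midpoint (not any-overlap) convention keeps the window
semantics unambiguous; the midpoint of an even-length interval is
`start + floor(len/2)`. Consensus peak sets merge peaks across datasets
by single-linkage on ≥ 1 bp overlap (half-open intervals: touching does
not overlap), with support counted as distinct datasets, not peaks.

A direct-target call requires expression score ≥ `es_min = 5`, binding in
≥ `chip_min` ChIP datasets (default 3 for a 9-dataset compendium, 5 for a
28-dataset one), and — implemented as an explicit post-filter rather than
an arithmetic consequence of the thresholds — support from at least two
distinct studies on each evidence axis, so no single study can carry a
call. DREAM candidates mirror the rule symmetrically (score ≤ −5, E2F4
binding in ≥ 3 datasets within the 1 kb window); no separate published
threshold exists for the repressive side, so the mirrored default is a
package choice, exposed as parameters.

## Ortholog comparison and divergence

Only one-to-one ortholog pairs where both genes carry a score are
compared. Spearman correlations are reported per regulation direction,
restricting pairs by the *reference* species' score sign (> 0 for up,
< 0 for down) and reporting both reference orientations; which gene
subset the published per-direction correlations used is not fully
specified anywhere, so the sign-based subsetting here is a documented,
committed interpretation.

A pair diverges in direction *d* toward species *s* when species *s*
reaches `es_min` in that direction, the scores differ by ≥ `diff_min = 8`,
and fewer than `other_support_max = 3` datasets call the gene in
direction *d* in the other species. "Support in the other species" is the
same-direction dataset count, not the net score: a gene up in 3 and down
in 3 datasets nets to 0 but is clearly not unsupported. Tags are assigned
per direction, so a pair down-regulated in one species and up-regulated
in the other carries two tags — this is exactly the interesting
DREAM-vs-p53 conversion case, and it is why the divergence subgroups may
sum to more than the number of divergent pairs.

The common direct-target intersection annotates each pair by whether any
TSS-proximal consensus peak of species A projects (through the chain
alignment) onto a TSS-proximal consensus peak of species B; pairs bound
only at non-overlapping sites in the two genomes are species-specific —
the same target gene retained through different binding sites.

## Interval projection and turnover

The chain mapper supports plus-strand co-linear chains (inversions are
out of scope). An interval maps when ≥ `min_match` of its bases fall in
aligned blocks of a single best chain — the chain covering the most of
its bases, ties broken by file order for determinism. `min_match`
defaults to 0.1, the usual cross-species liftover practice (same-assembly
conversions use ~0.95; a flag exposes it). The target interval spans the
images of the first and last aligned bases. Turnover classification
requires ≥ 1 bp overlap with a target-species consensus site; the
conserved fraction excludes unmappable sites from the denominator, since
a site whose DNA does not exist in the other genome cannot be scored for
binding conservation there.

Conservation profiles average a bedGraph track per bp offset around site
centers (±2500 bp default). Bases with no track segment are excluded from
the mean, not imputed as zero — conservation tracks are sparse, and
zero-imputation biases profiles downward.

## Motif model

The p53RE is modelled as two decameric RRRCWWGYYY half sites with zero
spacer — the dominant canonical arrangement; whether published scans
allowed spacers or mismatched half sites is not stated, so a fixed-spacer
matrix is committed here. The IUPAC consensus expands to a position
weight matrix: permitted bases get count 1, non-permitted a pseudocount
of 0.25, columns normalised and scored as log-odds against a uniform
background; N scores as background (log-odds 0). A window is a hit at
≥ 0.85 of the maximum attainable score, scanned on both strands
(overlapping opposite-strand hits are reported separately). E2F (TTSSSSS)
and CHR (TTYGAA) elements use the same machinery.

Feature enrichment assigns each peak by its midpoint under a fixed
priority — promoter (<1 kb) > promoter (1–5 kb) > 5′UTR > 3′UTR > exon >
intron > distal intergenic — and compares against each feature's share of
the genome after the same priority resolution, so observed and expected
fractions both sum to 1. Genome not covered by any feature is distal
intergenic; a feature covering zero bp reports NaN enrichment rather than
dividing by zero.

Over-representation of gene sets is the standard upper-tail
hypergeometric test with Benjamini–Hochberg correction across terms; the
universe defaults to all scored genes of the species, standard ORA
practice for a score-derived list.

## Synthetic universe

The generator plants a known two-species truth and emits every input the
pipeline reads. Design choices, with the reasoning:

* **Scale.** Defaults: 120 genes per species, 2 Mb single-chromosome
  genomes, 15 expression datasets per species, ChIP compendia of 9 (p53)
  and 7 (E2F4) datasets for species A and 28/9 for species B — mirroring
  typical mouse-style and human-style compendium sizes. These sizes keep
  a full scenario under a second to generate and the whole pipeline a few
  seconds, while every count (datasets, studies, classes) is large enough
  to exercise the thresholds meaningfully.
* **Layout.** Each gene occupies a 6 kb cassette with the TSS at its
  center, separated by ≥ 4 kb filler, so neighbouring promoter windows
  never collide and peak-to-gene assignment is unambiguous by
  construction. Cassettes and filler segments are either aligned
  (identical sequence, one chain block) or species-private; conserved
  regulation classes always get aligned cassettes so their planted sites
  are mappable, other segments align with probability
  `conserved_block_fraction = 0.6`.
* **Noise model.** Regulated genes carry |log₂FC| = 0.5 + Gamma(2, 0.5)
  — bounded away from the call threshold — and cross the p-value cutoff
  with probability `detection_sensitivity` (0.9), so sensitivity alone
  governs detection rather than an entangled effect-size distribution.
  Unregulated genes get log₂FC ~ N(0, 0.2) with null p-values; spurious
  calls are forced at `false_call_rate` (0.02) with random direction, and
  accidental threshold crossings are suppressed so the false-call rate is
  exactly the configured one.
* **Regulation classes** per ortholog pair: conserved up/down (0.10
  each), single-species up (0.06 each) and down (0.04 each), opposite
  (0.02), unregulated (0.58) — a mix weighted toward unregulated genes,
  with up-divergence commoner than down-divergence. The "opposite" class
  plants DREAM-style repression (E2F4 site + down-regulation) in one
  species and a TSS-proximal p53 site with up-regulation in the other.
* **ChIP noise.** True sites drop out of each dataset with probability
  0.2, surviving peaks get ±30 bp edge jitter (exercising consensus
  merging), and each dataset adds 3 uniformly placed background peaks.
  Background peaks rarely produce false binding calls because a call
  needs ≥ 3 datasets hitting the same window.
* **Sequence and motifs.** Genomes are uniform-random ACGT; every planted
  p53 site carries a concrete p53RE instance (conserved pairs share one
  instance at aligned coordinates), every E2F4 site an adjacent E2F + CHR
  pair. Conservation tracks are piecewise-constant bedGraphs: U(0.0, 0.3)
  outside aligned blocks, U(0.4, 0.9) inside, U(0.85, 1.0) over conserved
  planted sites.

What the generator does **not** emulate: multi-chromosome karyotypes,
strand-inverted or rearranged alignment blocks, realistic base
composition or repeats, probe-level expression artifacts (one row per
gene per dataset), correlated noise between datasets from the same study,
and peak-width/summit structure. Passing tests therefore demonstrate the
algorithms' correctness and calibration under the stated noise model, not
performance on real genomes — in particular, real motif background rates,
liftover edge cases around rearrangements, and cross-study correlation
structure are untested here.

## Numerical and degenerate-input conventions

All intervals are 0-based half-open (BED). All score thresholds are
inclusive exactly as written. Ties in best-chain selection break by file
order; histogram tail-merging (off by default) folds sub-minimum extreme
score groups toward zero and preserves total gene counts. Spearman
correlations on a constant vector return NaN rather than raising.
Duplicate (gene, dataset) rows, genes in two one-to-one ortholog rows,
probability masses not summing to 1, empty site sets, peaks beyond contig
ends and missing dataset→study mappings are hard errors; peaks on
chromosomes absent from the annotation warn and are skipped. The pipeline
is deterministic: identical config and inputs give byte-identical outputs
(each table carries the tool version and a hash over the analysis
parameters, excluding file locations).

## Known limitations

The mapper rejects minus-strand chains. Motif scanning materialises
per-window score vectors, fine for the megabase scale used here but not
tuned for mammalian genomes. The expression model assumes one row per
gene per dataset; collapsing multi-probe genes is left to the caller.
Divergence subgroup membership permits one pair in two subgroups by
design; consumers wanting disjoint groups must deduplicate by their own
rule.
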