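# Methods

## The simulated study conditions

The simulator generates a paired-condition genome in base-pair coordinates
and derives binned contact maps, peak sets, signal tracks and expression
tables from one shared truth table, so the same planted architecture can be
analysed at any resolution.

Contact counts are Poisson around the expected intensity

    Λ_ij = depth · norm · s⁻ᵅ · (1 + δ·e_i·e_j) · t^[same TAD] · l^[anchor pixel]

with `s` the bin separation (floored at one bin), `α` the decay exponent,
`e_i ∈ {−1, +1}` the compartment sign of bin *i*, `δ` the plaid strength,
and `t`, `l` the TAD and loop multipliers.  Poisson (rather than negative
binomial) keeps every closed-form oracle exact; overdispersion would only
widen the recovery margins tested here.

Defaults (all configurable on `SimConfig`):

| parameter | default | meaning |
|---|---|---|
| `n_chroms`, `chrom_length_bp` | 2 × 20 Mb | genome size; large enough for ~80 TADs and ~40 compartment blocks |
| `bin_size_bp` | 40 kb | native resolution; 100 kb for compartments, 10/20 kb for loops via `at_resolution` |
| `decay_exponent` | 1.0 | contact-decay power law, the canonical fractal-globule slope |
| `compartment_delta` | 0.4 | plaid contrast; same-sign pixels 1.4×, opposite 0.6× |
| `tad_boost`, `loop_boost` | 2, 4 | within-domain and anchor-pixel multipliers |
| `n_flipped_blocks` | 3 | compartment blocks whose sign flips between conditions |
| `tad_edits`, `loop_edits` | 2 merges + 1 split; 1 gain + 1 loss | planted structural differences |
| `sequencing_depth` | 5 × 10⁶ | expected cis read pairs; ample for compartments/TADs at these sizes |
| `n_genes` | 2000 | placed in A blocks with probability 0.8 (gene-density orientation) |
| `atac_local_fraction` | 0.174 | local share of OCRs, matching the ~83% distal fraction reported for plant ATAC data |
| `deg_fraction`, `deg_effect` | 0.1, 4× | planted differential expression; DEGs inside flipped blocks follow the flip direction |
| `expression_sigma` | 0.25 | log-normal replicate noise of FPKM |
| `trans_fraction` | 0.05 | uniform trans background for the cis/trans partition |

Structural layout choices worth knowing:

* **Compartment blocks** are contiguous alternating-sign runs with geometric
  lengths (mean 1 Mb, minimum 400 kb) on a 200-kb grid — the least common
  multiple of the 100-kb eigenvector bins and 40-kb TAD bins.  Flipped
  blocks are chosen pairwise non-adjacent so each flip is one unambiguous
  maximal differing run.
* **TADs nest inside compartment blocks** (uniform 320–800 kb, cut to
  refine block edges).  A plaid transition is itself an insulation
  discontinuity; recording block edges as TAD boundaries keeps the truth
  table complete with respect to every break in the expected matrix, which
  is what boundary-recovery precision is measured against.
* **Loops** have 10-kb anchors on a 10-kb grid with separations of
  0.3–1.5 Mb, away from each other by ≥30 kb per anchor.
* Coordinates are 0-based half-open throughout; bin *i* covers
  `[i·bin, (i+1)·bin)`.

What the generator does **not** emulate: read-level artefacts (mappability,
duplicates, restriction-fragment geometry), replicate batch effects,
overdispersed counts, nested/hierarchical TADs, trans compartment structure,
and sequence-driven signals (GC, motif content).  Passing recovery tests
therefore demonstrates the correctness of the analysis rules under the
stated generative model, not robustness to every artefact of real libraries.

## Analysis procedures and numerical choices

**Balancing.**  Iterative correction per chromosome: weights updated by
`w ← w/√(rowsum/mean)` until the relative row-sum spread is ≤ 1e−5
(≤ 200 iterations; non-convergence returns partial weights with a warning
flag).  Bins with coverage below the 2nd percentile of nonzero rows (lower
quantile method, so small matrices keep their minimum row) or with zero
coverage are masked.  Weights are scaled so balanced rows sum to ~1.

**P(s), O/E, z-scores.**  The decay profile is the per-separation mean of
balanced pixels pooled genome-wide, one stratum per bin offset.  O/E divides
by that expectation.  Z-scores standardise each pixel by its stratum's mean
and SD; strata with ≥ 100 pixels use their own statistics (so the per-stratum
mean is ~0 and SD ~1 by construction), sparse strata borrow a LOWESS fit
(span 0.3) of log-mean and log-SD over log distance, with σ floored at 1e−6.
A pure LOWESS μ(s) cannot satisfy a per-stratum centring tolerance of 0.05 —
the sampling noise of a ~200-pixel stratum alone exceeds it — hence the
hybrid.  Difference matrices subtract z-maps elementwise; antisymmetry under
argument swap is exact by construction.

**Compartments.**  Dense symmetric eigendecomposition of the Pearson
correlation of O/E per chromosome (the genomes handled here are small at
100 kb); sign fixed per chromosome by positive correlation with gene
density; PC1 = 0 gives label NA rather than a forced class.  Chromosomes
with < 10 usable bins return all-NA with a warning.  The saddle ranks bins
genome-wide, trims to the 0.02–0.98 quantile range, averages cis O/E over
10 × 10 quantile pairs, and reads strengths off 20% corner sets.

**TADs.**  Insulation uses the diamond `{u<i<v, |u−i|,|v−i| ≤ w}` with the
first two diagonals masked, w = 10 bins (400 kb) by default — the upstream
tool takes the window as a free parameter; 10 bins sits mid-range of common
practice and above the minimum TAD size.  Scores are NA within w bins of
chromosome ends or where > 50% of the diamond is masked.  Boundary strength
is prominence (the smaller flanking rise to the nearest local maximum);
plateau ties resolve to the lower bin index; calls within 5 bins of a masked
bin are vetoed outright; adjacent calls closer than 3 bins keep the stronger
one so derived TADs span ≥ 3 bins.  TAD-change classification builds the
bipartite bp-overlap graph and labels connected components; "more than 75%"
is strict.

**Loops.**  For every cis pixel within 2 Mb the local expectation is the
distance-decay expectation scaled by the *maximum* mean O/E over five
kernels — the classic donut (inner radius 2, outer 5, arms excluded) and the
four diagonal quadrants of the same annulus.  The quadrants matter: at a TAD
or compartment-block corner the donut dips outside the enriched square and
underestimates the background, which a single-kernel test converts into
hundreds of corner artefacts.  Raw counts are tested against the Poisson
upper tail of that expectation (mapped through the balancing weights),
BH-corrected within log2-distance strata, gated at ≥ 2-fold enrichment, and
clustered by 8-connectivity, keeping each cluster's highest-enrichment pixel.
Multi-resolution sets merge finest-first with score-descending order inside
a resolution; a call is dropped only if both anchors overlap an already-kept
call.  Loop-recovery experiments run at 3 × 10⁷ pairs on merged 10 + 20-kb
calls: single resolutions are not sufficient here (20 kb alone is biased
against loops in contact-poor plaid regions by the conservative max-kernel
background; 10 kb alone is depth-limited), and merging resolutions is
exactly how the multi-resolution calling strategy is meant to be used.
This depth is still ~30× shallower than a real tissue Hi-C comparison.

**Differential gates.**  Region counts are scaled to CPM (pseudocount 1 for
fold changes); expression fold changes use pseudocount 0.01 and are
two-sided (`max(a,b)/min(a,b)`).  With replicates, p-values come from a
moderated t-test: per-feature pooled variances are shrunk toward their
global mean with 20 prior degrees of freedom and the t statistic is referred
to the inflated df.  A plain Welch test at n = 3 with a genome-wide q < 0.01
gate recovers almost nothing (its per-gene df is ~4, so even 4-fold effects
cannot clear a BH threshold shared with 2000 tests); variance moderation is
the standard remedy in expression analysis and its null behaviour is
verified by simulation in the test suite.  Single-replicate designs fall
back to an exact equal-rate Poisson (conditional binomial) test on summed
counts.  BH correction is applied across features; the gates are
|log2FC| > 0.5 & FDR < 0.05 for regions and q < 0.01 & FC > 1.5 for genes.

**Histone cases and enhancers.**  "Strong" is operationalised as ≥ 1 bp
overlap with a called peak of the mark.  Mixed repressive/active states
resolve by covered fraction, ties conservatively to the repressed Case 1;
a region strong only in H3K4me3 carries no H3K9ac evidence and falls to
Case 2, i.e. it is not promoted to an enhancer.  Putative enhancers are
Case 3 ∪ Case 4 regions overlapping no ±3-kb TSS window.

**Integration.**  dOCR containment in anchors and enhancer/promoter–anchor
links use any-overlap (≥ 1 bp); "gene anchor" means gene body or 3-kb
promoter (flag-switchable to body only).  dOCR activity combines A/B-
enriched accessibility with oppositely-directed H3K27me3 within a 2-kb
flank (the flank distance is unstated upstream; 2 kb spans a nucleosome
array without reaching the next gene); conflicting evidence yields `static`
with a flag.  Shifted controls draw uniform shifts in ±500 kb, resampling
off-chromosome draws, preserving the width multiset exactly.  Reported
percentages round to one decimal.

## Determinism and problem sizes

Every stochastic step derives its stream from a single seed via SHA-256 of a
stage label, so identical configs give byte-identical outputs (the pipeline
test hashes two full runs).  The shipped test suite and acceptance script
run the analyses at 1–2 chromosomes × 8–20 Mb — large enough that every
stage has hundreds of recoverable structures — with depths of 5 × 10⁶
(compartments, TADs, expression) and 3 × 10⁷ (loop calling); these sizes are
the package's validation conditions, chosen so the whole suite runs on a
laptop in minutes.

## Known limitations

* The loop caller's error-rate contract is verified under Poisson noise;
  overdispersed real data would need the gamma multiplier the simulator
  exposes plus a negative-binomial tail, which is not implemented.
* Compartment calling assumes one dominant plaid eigenvector per
  chromosome; sub-compartments and trans saddles are out of scope.
* The insulation window and the boundary-match tolerance are free
  parameters (defaults 10 bins and 1 bin); published boundary counts cannot
  be reproduced without knowing the upstream settings.
* Genome-wide counts printed for the real tissues (OCR totals, enriched
  genes, enhancer counts, interaction totals) depend on the deposited
  sequencing data and are out of scope; the package reproduces the rules
  and validates them on planted truth.
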