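# Methods

## The regulon model

A regulon is a TF → peak → target triple: a transcription factor
regulating a target gene through one accessible cis-element that
contains a scored binding site of the TF's motif. The pipeline
assembles triples from three independently derived layers of evidence
and then filters them:

* **TF-motif role** — the Pearson correlation over cells between a TF's
  (log-normalized) expression and its motif's deviation z-score.
  r > 0.05 makes the pair an activator, r < −0.05 a repressor; pairs in
  the dead zone carry no usable direction and are dropped.
* **Peak-to-gene link** — correlation between a peak's accessibility
  and a gene's expression across pseudo-bulk aggregates, retained at
  |r| > 0.25 and BH FDR < 0.01 over all tested candidate pairs.
  Candidates are constrained by genomic context: promoter peaks
  (overlapping TSS ± 500 bp) and gene-body peaks link only to the
  overlapped gene; intergenic peaks to every gene whose TSS lies within
  200 kb of the peak center (precedence promoter > gene body >
  intergenic; the distal distance is measured TSS-to-peak-center).
* **Binding site** — a motif match (exact p-value threshold, below)
  inside a retained peak whose corrected Tn5 insertion signal shows
  protection: NL + NR − 2·NC > 0.1, where NC is the mean signal over
  the motif window and NL/NR over flanks of triple the motif width.
  The score is invariant under adding a constant to the whole track,
  and scales linearly with the units of the corrected signal — the 0.1
  default presumes a track normalized to O(1) values and is exposed as
  a parameter (`footprint_min`).
* **TF→target edge** — per target, a stochastic gradient-boosted
  regression of the target's normalized expression on all TF columns
  (100 trees, depth 3, learning rate 0.1, subsample 0.9, seeded,
  single-threaded). Gain importances are normalized to sum to 1 per
  target; pairs below the global 95th percentile of all importances are
  discarded (a per-target cut is available behind `per_target_cut`),
  and surviving pairs are signed by Pearson correlation with a ±0.03
  dead zone.

A candidate triple must agree in direction (activator ↔ positive edge,
repressor ↔ negative), its TF must be enriched in the MG-lineage cell
groups, and duplicate (tf, peak, target) records collapse onto the
maximal footprint score.

Condition-enriched sub-networks keep triples whose TF is an up-DEG in
the condition (down for repressors) in at least one MG group, whose
peak is not significantly less accessible there in any group, and whose
target is an up-DEG in at least one group. Key activators are called
per (TF, DEG cluster) with the hypergeometric upper tail — population =
the TF's targets in the total network, sample = its targets in the
sub-network, successes = the cluster's genes — at p < 0.001 and
coverage (overlap / cluster size) > 0.01. Note an asymmetry that the
directional rules create and that we verified on simulation: a
condition-specific *repressor* appears in the opposite condition's
sub-network, because that is where its targets are de-repressed and the
TF is comparatively down. `GroundTruthGRN.expected_subgrn_condition`
encodes this when scoring recovery.

## Statistical machinery

* **Normalization** — ln(1 + 10⁴·x/rowsum) per cell; all-zero rows map
  to zeros with a warning.
* **Two-group test** — two-sided Wilcoxon rank-sum; exact null for
  small tie-free samples, tie-corrected normal approximation with
  continuity correction otherwise (scipy's `method="auto"`).
* **Fold changes** — reported on the de-logged expression scale,
  log2((mean expm1 + 1)/(mean expm1 + 1)), the convention of the
  single-cell toolkits whose thresholds (0.25, 0.5, 2) the calls use.
  A ratio of log-scale means compresses a 40-fold expression change to
  ≈0.4 and would make those thresholds dead letters. Motif z-scores can
  be negative, so motif "fold changes" are differences of group means
  on the z scale against the same 0.25 threshold.
* **Multiple testing** — step-up Benjamini–Hochberg with monotonicity
  enforcement, capped at 1; agrees with the statsmodels reference to
  10⁻¹².
  DEG/CEG/DM/CM use adjusted p < 0.05; DAR/CAR use raw p < 0.05 — the
  asymmetry is deliberate and mirrors how the calls are defined.
* **Motif matching** — PWM probabilities are floored at 10⁻⁴ before the
  log-odds against the background frequencies; scores are discretized
  at 10⁻³ and the threshold for the exceedance probability (default
  5·10⁻⁵) is computed exactly by convolving the per-position score
  distributions. The same discretization makes the DP threshold equal
  the exhaustive-enumeration threshold for every width. Both strands
  are scanned; a position yields one record for the better strand.
  Consequence of exactness: a width-6 motif cannot reach p ≤ 5·10⁻⁵
  (the single best word already has probability 0.25⁶ ≈ 2.4·10⁻⁴);
  width ≥ 8 is needed at the default cut-off.
* **Deviation z-scores** — background peaks are drawn with replacement
  from 10×10 joint quantile bins on (GC content, expected accessibility
  fraction), B = 50 sets by default. Background standard deviations at
  float-jitter scale (≤10⁻⁸) are treated as degenerate and give z = 0.
* **Differential motifs** — likelihood-ratio test of a logistic
  regression of group membership on one motif's z versus intercept
  only; on perfect separation the rank test substitutes with a warning.
* **Pseudo-bulk aggregates** — cells are embedded by PCA (30
  components) of the concatenated log-normalized modalities; each
  aggregate sums the raw counts of the k nearest neighbours of a random
  seed cell (k = 100, scaled down proportionally below 10,000 cells).
  Aggregates pool identical cell numbers, so summed counts are
  depth-homogeneous and are log1p-transformed *without* per-aggregate
  CPM rescaling: dividing by the library total couples every flat
  feature to whatever is regulated (the regulated features drag every
  other feature's fraction down) and manufactures spurious negative
  peak–gene correlations.
* **Peak matrix ceiling** — per-cell per-peak counts are capped at 4
  before differential-peak calls, links and aggregation; the deviation
  z-scores use the raw counts.

## The synthetic multiome

The generator plants a known network and emits everything the pipeline
consumes. Default conditions: 30 TFs (70% activators), 300 candidate
targets, 1500 non-overlapping 501-bp peaks on one synthetic chromosome,
150 triples, two conditions ("LD", "NMDA") × 2000 cells, five ordered
cell groups (restMG → actMG → MGPC → two precursor stages) tiling
pseudotime t ∈ [0, 1].

* **Latent TF activity** — z_f(cell) = 0.05 + bump + η, a Gaussian bump
  in pseudotime (width 0.05–0.09) plus a per-cell N(0, 0.5)
  idiosyncratic term. The same realized z drives the TF's own
  expression, its targets and its peaks, which is what makes regulator
  attribution identifiable when several TFs peak at similar times.
  Bump centers sit at the midpoints of the three MG-lineage groups
  (with jitter), so every planted TF is genuinely MG-enriched and its
  group-wise fold change clears the 0.25 bar; TF self-expression uses
  amplitude 3.0 (clipped at z = 1.6 so no single TF dominates a
  library) while regulated features use `effect_size` (default 1.5).
* **Counts** — RNA is negative binomial (dispersion 0.3) with mean
  baseline·exp(Σ sign·effect·z); peaks are Poisson (rate 2/cell,
  lognormal per-peak accessibility, lognormal per-cell depths). These
  are the simplest count models that preserve overdispersion.
* **Condition specificity** — assigned per triple but grouped by TF
  (a TF's specific triples share one condition); a specific triple's
  effect exists only in its condition, and the TF's own expression is
  gated in the off condition (×0.15 when fully specific, ×0.3 when
  mixed). Two "master" activators (20 targets each, half specific, one
  per condition) are the planted key regulators.
* **Genome layout** — one 35-Mb chromosome. Each triple owns a locus
  (target TSS + its peak at a planted category: promoter, gene body or
  intergenic at 3–70 kb); loci are spaced ≈220 kb so at most the two
  flanking loci fall inside the 200-kb linking window, and the locus
  order interleaves TFs with distant bump centers so genomic neighbours
  are uncorrelated — otherwise every locus would have several
  correlated neighbours and planted-link precision would be
  unidentifiable in principle. TF and mitochondrial genes live in a
  peak-free tail region. Peak sequences are i.i.d. nucleotides with
  per-peak GC ~ Beta(5, 5); planted sites overwrite the sequence with
  the motif's consensus word (one width-8 motif per TF, consensus
  probability 0.94).
* **Insertion signal** — per planted site, 7×width per-base values at
  level 1.0 with N(0, 0.05) noise; bound sites are depressed by
  `footprint_depth` (default 1.0, i.e. 20 noise SDs) over the center
  window. With these defaults an unbound site's score exceeds 0.1 with
  probability ≈0.4%, which is what makes ≥95% bound/unbound separation
  attainable.
* **QC failures** — 2% of cells are planted as failures cycling through
  the six failure modes; the flag `plant_qc_failures=False` disables
  them. nCount metadata fields are recomputed from the final matrices,
  so the row-sum invariant holds exactly. Tiny test configurations get
  a depth floor (expected totals below twice the QC minima are rescaled)
  so the "clean data passes QC" contract holds at any size.

What the generator does **not** emulate — and what passing recovery
therefore does not demonstrate on real data: batch and ambient-RNA
effects, doublet expression profiles (doublet scores are planted
labels, not mixtures), fragment-level ATAC structure and Tn5 sequence
bias, linked genes sharing enhancers (each planted peak regulates one
target), TF cooperativity, unregulated genes with autonomous temporal
programs, and realistic motif redundancy (one motif per TF by default,
though the feature calls support many-to-one).

## Pipeline composition

Stages run simulate → qc → activity → features → links → grn → subgrn →
keytfs; disabling a stage another enabled stage depends on is a
configuration error detected before execution. DAR/CAR calls need the
peak-to-gene links, so the features stage computes the per-group peak
statistics and the links stage finalizes those calls. The pipeline
builds one total GRN over both conditions pooled and extracts the two
condition-enriched sub-networks from it; per-condition total networks
can be built through the library API by subsetting cells first. DEG
clusters for the key-TF test come from k-means (k = 4, 10 restarts,
seeded) on the DEG pseudotime-bin profiles of both conditions
concatenated. TSS enrichment is consumed from cell metadata; fragment
files are out of scope. Mature-marker exclusion is available in
`find_degs` but idle under the default simulation, which plants no
mature neuron types.

All text outputs use tab separators with floats at 6 significant
digits, and every source of randomness descends from the single
configured seed, so re-running a configuration reproduces byte-identical
files.

## Known limitations

* The footprint threshold (0.1) is meaningful only on the scale of the
  corrected signal supplied; tracks in other units need
  `footprint_min` adjusted.
* Matches without a signal record are skipped rather than scored; with
  sparse site-level signal the binding-site layer, not the matcher, is
  the limiting evidence.
* The global importance cut assumes targets are broadly comparable; on
  data where a few targets absorb most signal the per-target variant is
  more appropriate.
* Per-cell CPM normalization carries the usual library-composition
  effect: when a strong condition-specific program inflates a group's
  library totals, genes outside that program drift slightly the other
  way and can surface as weak DEGs (|log2FC| just above 0.25 at
  adjusted p ≈ 0.01–0.05). For the key-activator test this can inflate
  a master TF's cluster overlap in the *total* network and dilute its
  hypergeometric enrichment at some seeds — the same behaviour the
  underlying single-cell toolkits exhibit on real data.
* Recovery figures quoted in the README are properties of the default
  synthetic conditions (problem sizes above, chosen to keep a full run
  around 1–2 minutes); they are upper bounds on, not estimates of,
  performance on biological data.
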