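# multigrn

Gene-regulatory-network inference from paired single-cell multiome data
(scRNA-seq + scATAC-seq), built around the regulon model used to study
Müller glia (MG) reprogramming in the injured zebrafish retina: resting
MG activate, form MG-derived progenitor cells (MGPCs) and produce neuron
precursors, and the question is which transcription factors drive the
condition-specific parts of that response.

The package implements the full construction as a tested, reusable
pipeline and ships a synthetic-data generator with a planted ground
truth, so every stage can be validated by parameter recovery:

1. **QC** — per-cell count metrics and the study's exact filters
   (nCount_RNA ∈ (500, 50000), nCount_ATAC ∈ (1000, 100000), TSS
   enrichment ≥ 4, RNA doublet score ≤ 0, ATAC doublet enrichment ≤ 2,
   mitochondrial fraction ≤ 15% for RNA-only data), plus the iterative
   501-bp fixed-width peak merge.
2. **Motif activity** — PWM scanning with an exact dynamic-programming
   p-value threshold (default p ≤ 5·10⁻⁵, both strands), and per-cell
   motif deviation z-scores à la chromVAR:
   z<sub>im</sub> = (Y<sub>im</sub> − mean<sub>b</sub> Y<sub>im</sub><sup>b</sup>) / sd<sub>b</sub> Y<sub>im</sub><sup>b</sup>
   with Y = (X − E)/E and B background peak sets matched on
   (GC, expected accessibility) bins.
3. **Feature calls** — Wilcoxon rank-sum tests with BH adjustment;
   DEG/CEG (genes), DAR/CAR (peaks) and DM/CM (motifs, logistic LR test)
   with the study's thresholds and cross-condition consistency filters;
   pseudotime binning (20–50 bins, smoothed, z-scaled) and k-means
   profile clustering.
4. **Links** — TF-motif activator/repressor classification
   (Pearson r ≷ ±0.05 between TF expression and motif activity), peak
   categorization (promoter ±500 bp > gene body > intergenic ≤200 kb),
   peak-to-gene correlation across kNN pseudo-bulk aggregates
   (|r| > 0.25, FDR < 0.01), and TF footprint scoring on corrected Tn5
   insertion signal: score = NL + NR − 2·NC > 0.1, flanks triple the
   motif width.
5. **GRN** — gradient-boosted TF→target importances (100 trees, depth 3,
   lr 0.1, subsample 0.9; global 95th-percentile cut; sign by Pearson
   r ≷ ±0.03), TF-peak-target triple assembly with direction-consistency
   and MG-enrichment filters, condition-enriched sub-network extraction,
   and the hypergeometric key-activator test
   (coverage = N_overlap/N_cluster > 0.01, upper-tail p < 0.001).

## Worked example

```python
from multigrn import PipelineConfig, run_pipeline_with_state, recovery_metrics

cfg = PipelineConfig(seed=1, out_dir="out")          # default study conditions
manifest, state = run_pipeline_with_state(cfg)
print(manifest.stages["grn"]["info"])
print(recovery_metrics(state, cfg))
```

With the default conditions (30 TFs, 300 candidate targets, 1500 peaks,
150 planted TF→peak→target triples, 2 × 2000 cells in two injury-like
conditions "LD" and "NMDA") this prints, for seed 1:

```
{'n_edges': 365, 'n_triples': 150, 'n_mg_tfs': 30}
{'role_accuracy': 1.0, 'link_precision': 0.9375, 'link_recall': 1.0,
 'footprint_accuracy': 0.9933, 'triple_f1': 1.0,
 'subgrn_assignment_accuracy': 0.9778, 'key_tf_recovery': 1.0, ...}
```

meaning: all 30 planted activator/repressor roles were classified
correctly; the peak-to-gene stage recovered every planted enhancer–gene
link at 94% precision; the assembled network contains exactly the 150
planted triples (F1 = 1.0); 97.8% of the recovered condition-specific
triples landed only in the correct condition's sub-network; and both
planted master regulators were flagged as key activators — e.g. TF000
in the LD sub-network covers 10 of 19 genes of DEG cluster c2
(coverage 0.53, hypergeometric p = 6·10⁻⁵).

The same run from a shell:

```sh
multigrn run-all --seed 1 --out-dir out            # writes TSV/BED/JSON + manifest.json
multigrn qc --seed 1 --out-dir out_qc              # stop after an earlier stage
```

Every stage writes tab-separated text (floats at 6 significant digits);
re-running with the same seed reproduces byte-identical files.

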