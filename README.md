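# ecatlas

Analysis pipeline for single-cell atlases of tumour endothelial cells
(ECs), built around the kind of study that profiles CD31-enriched cells
from paired glioblastoma tumour-core and tumour-periphery tissue: quality
control and normalization, clustering and canonical-marker cell-class
annotation, in-silico EC selection with heterotypic-doublet removal,
per-cluster marker discovery, cross-atlas similarity of EC subtypes,
blood-brain-barrier (BBB) gene-module construction, module co-expression,
and anatomic-region enrichment of marker sets. A first-class synthetic
data generator plants every structure the pipeline is meant to recover
and records it in a truth manifest, so each stage is tested against known
ground truth.

It is written for computational biologists who want a transparent,
reimplementable version of this analysis rather than a stack of
package-specific calls — every statistical primitive is implemented
and tested in this package.

## The methods, briefly

**QC and normalization.** A cell is removed when its mitochondrial count
fraction exceeds 10% or it has fewer than 200 detected genes (strict
inequalities). Remaining cells are depth-normalized and log-transformed:
`value(g,c) = ln(1 + count(g,c) / total(c) × 10,000)`.

**Marker discovery.** Each gene is tested cluster-vs-rest with a
two-sided Wilcoxon rank-sum test on normalized expression (exact null
enumeration for small samples, tie-corrected normal approximation with
continuity correction otherwise), Bonferroni-corrected over the genes in
the comparison; markers are up-regulated genes with adjusted *P* < 0.05,
ranked by *P*, then fold-change, then symbol.

**Cross-atlas similarity.** Top-50 marker sets are compared by the
Jaccard coefficient `J(A,B) = |A∩B| / |A∪B|` and embedded in 2-D by
classical (Torgerson) multidimensional scaling of `d = 1 − J`:
double-center `−½d²`, eigendecompose, scale the top eigenvectors by the
square roots of their eigenvalues.

**BBB modules.** The core BBB module keeps genes that, in a multi-organ
EC bulk panel, have (a) ≥ 100 CPM in brain ECs, (b) > 2-fold enrichment
(rank-sum *P* < 0.05) over kidney, lung, heart and liver ECs
individually, and (c) brain-EC expression no less than whole brain
vasculature. The BBB dysfunction module keeps genes up-regulated in at
least 3 of 4 brain-disease models (stroke, multiple sclerosis, traumatic
brain injury, seizure). Modules are homolog-mapped (mouse → human) and
restricted to genes detected in the single-cell data, with a full
per-gene audit and provenance chain, then profiled by gene–gene
correlation over EC cells.

**Anatomic mapping.** Region-labelled bulk profiles are normalized by a
per-sample microvascular score (mean expression of a vascular-enriched
gene panel) before marker sets are averaged per region, removing the
vascular-abundance confound between regions.

## Worked example

```bash
ecatlas run-all --seed 2 --out demo_run
```

simulates the default synthetic study (3,000 cells × 2,000 genes, five
EC subclusters, four patients, paired core/periphery regions) and runs
every stage. Output actually printed by the command above:

```
  cells_removed_qc: 152
  n_clusters: 12
  ec_cells: 1564
  doublets_flagged: 9
  ec_subclusters_found: 5
  ec_subcluster_ari: 0.9968107067629883
  n_ec_enriched: 400
  n_up_in_core: 188
  n_down_in_core: 120
  core_module_raw: 162
  core_module_matches_planted: True
  core_module_mapped: 155
  core_module_detected: 147
  dysfunction_module_mapped: 131
  dysfunction_module_detected: 128
  vascular_score_r: 0.9999251348618108
  region_argmax: {'Pe1': 'leading_edge', 'Co2': 'cellular_tumor',
                  'Co1': 'microvascular_proliferation',
                  'Pe2': 'infiltrating_tumor',
                  'Co3': 'pseudopalisading_necrosis'}
```

Reading this: 152 of 3,000 cells failed QC; the atlas resolved 12
clusters; 1,564 EC cells were selected in silico and 9 heterotypic
doublets removed; re-clustering the EC cells recovered the five planted
subclusters almost exactly (adjusted Rand index 0.997); 400 EC-enriched
genes were found and split into 188 up- and 120 down-regulated in the
tumour core; the core BBB module was recovered exactly (162 genes, 155
with human homologs, 147 detected in the atlas; dysfunction module
136 → 131 → 128); and after microvascular-score normalization each EC
subtype's markers peak in their planted anatomic region — the
angiogenic Co1 subtype in microvascular proliferation, the quiescent
Pe1 subtype in the leading edge — despite a planted 3× vascular-abundance
confound. Per-stage files (marker tables, GMT sets, Jaccard/MDS
coordinates, module audits, a digest-bearing run manifest) are written
under `demo_run/`.

Individual stages are available as `ecatlas simulate|qc|cluster|markers|
cross-atlas|bbb-modules|anatomic`, and everything is importable from the
`ecatlas` package (`simulate_atlas`, `qc_filter`, `find_all_markers`,
`jaccard_matrix`, `classical_mds`, `build_core_module`, …).

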