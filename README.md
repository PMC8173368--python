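# stmia

Integration of spatial transcriptomics (ST) with single-cell RNA-seq
(scRNA-seq), built around **multimodal intersection analysis (MIA)**: map
dissociated cell types onto tissue regions by testing whether their marker
gene sets overlap more (enrichment) or less (depletion) than chance under a
hypergeometric null.

The package targets developmental-tissue studies of the fetal-liver kind —
barcoded Visium-style spot arrays (each ~100 µm spot pooling 5–100 cells)
profiled alongside dissociated single cells — and provides the complete
analysis path:

* **I/O** — MatrixMarket count-matrix directories (MTX + features/barcodes
  TSV), Visium-dialect tissue-positions CSV, GMT gene sets, YAML/JSON config.
* **Preprocessing** — QC filters (spots with < 200 detected genes; cells with
  < 200 genes or mitochondrial UMI fraction > 20%; genes detected in < 3
  units), median-of-totals normalization with log2(1+x) transform,
  dispersion-based variable-gene selection, Ward hierarchical clustering,
  balanced subsampling.
* **Marker detection** — one-vs-rest differential expression with the
  *bimodal likelihood-ratio test* (point mass at zero + normal on positive
  values; χ², 3 df), with the conventional gates (`logfc.threshold = 0.1`,
  `min.pct = 0.01`) and Benjamini–Hochberg adjustment per cluster.
* **MIA** — for marker sets A (cell type) and B (region) in a gene universe
  of size N: k = |A∩B|, enrichment p = P(X ≥ k) and depletion p = P(X ≤ k)
  for X ~ Hypergeometric(N, |A|, |B|); display score is −log10 p signed
  positive for enrichment, negative for depletion.
* **Cell-cycle staging** — G1/S and G2/M scores as set-average normalized
  expression over packaged core sets (43 G1/S + 54 G2/M genes); cells with
  both scores < 2 are quiescent, otherwise the larger score names the phase.
* **Trend calling** — "gradually up/down-regulated" genes along an ordered
  stage series: strictly monotone stage means plus a significant
  first-vs-last bimodal LRT (BH-adjusted).
* **Simulator** — negative binomial (gamma-Poisson) counts with lognormal
  gene baselines and library sizes, planted region/cell-type markers with
  known fold change, mitochondrial content, planted cell-cycle phases,
  planted monotone genes, and a controllable fraction of QC-failing units —
  with the full planted truth returned for recovery testing.

## Worked example

Plant five tissue regions and five matched cell types (50 markers each,
4-fold change, 200 units per group, 10% deliberately degraded units), then
recover the correspondence end to end:

```python
from stmia.simulate import SyntheticParams, generate_st, generate_sc
from stmia.preprocess import (QCThresholds, apply_qc, normalize,
                              select_variable_genes, cluster_hierarchical)
from stmia.markers import find_all_markers, marker_sets
from stmia.mia import mia_map, assign_regions

params = SyntheticParams(seed=42, phase_frac={"G1": 1.0, "S": 0.0, "G2M": 0.0})
st_counts, positions, st_truth = generate_st(params)
sc_counts, sc_truth = generate_sc(params)

th = QCThresholds()
st_nm = normalize(apply_qc(st_counts, th))
sc_nm = normalize(apply_qc(sc_counts, th))

st_ca = cluster_hierarchical(st_nm, select_variable_genes(st_nm, 300), 5)
sc_ca = cluster_hierarchical(sc_nm, select_variable_genes(sc_nm, 300), 5)
st_sets = marker_sets(find_all_markers(st_nm, st_ca), name_prefix="region")
sc_sets = marker_sets(find_all_markers(sc_nm, sc_ca), name_prefix="celltype")

universe = set(st_nm.gene_ids) & set(sc_nm.gene_ids)
res = mia_map(list(sc_sets.values()), list(st_sets.values()), universe)
print(assign_regions(res).to_string(index=False))
```

prints

```
  region  cell_type     score
region_0 celltype_4 71.226755
region_1 celltype_0 76.093800
region_2 celltype_3 80.119588
region_3 celltype_1 62.411862
region_4 celltype_2 67.703807
```

QC removed exactly the 100 planted low-quality spots and 100 low-quality
cells (900 of 1000 kept on each side).  Every region maps to a distinct cell
type with a large positive (enrichment) score — cluster numbers are
arbitrary on each side, so `region_0 ↔ celltype_4` means ST cluster 0 and SC
cluster 4 recovered the same planted population; each diagonal pair shares
50–51 marker genes, i.e. the 50 planted markers plus the occasional spurious
marker.

Cell-cycle staging on the same simulator with the default phase mix
(60% G1, 20% S, 20% G2/M):

```python
from stmia.cellcycle import (cc_scores, cc_classify,
                             default_cell_cycle_sets, phase_fractions)
g1s, g2m = default_cell_cycle_sets()
calls = cc_classify(cc_scores(sc_nm, g1s, g2m))
print(phase_fractions(calls).round(3).to_string(index=False))
```

```
 cluster  n_units  G1_quiescent   G1S   G2M  proliferative
       0      900         0.602 0.197 0.201          0.398
```

recovering the planted phase composition to the third decimal.

The same analyses are scriptable from the shell — `stmia simulate`,
`stmia preprocess`, `stmia markers`, `stmia mia`, `stmia cellcycle`,
`stmia trends`, or `stmia run --config cfg.yaml` for the whole pipeline with
provenance-stamped, byte-reproducible outputs.

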