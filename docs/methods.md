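# Methods

## The analysis model

### Normalization

UMI counts in each unit (spot or cell) are divided by the unit's total count,
multiplied by the **median** total across units, and transformed as
log2(1 + x).  The median total is recorded as `scale_target`; by construction
the back-transformed linear values of every unit sum exactly to it.  The
pseudocount of 1 keeps the transform defined at zero and is the ubiquitous
convention; the scale matters downstream because both the marker log-fold
gate and the cell-cycle score threshold are interpreted on it.

### Quality control

Three filters, each with exact boundary semantics:

| filter | rule | boundary |
|---|---|---|
| spots | detected genes ≥ 200 | 200 kept, 199 removed |
| cells | detected genes ≥ 200 **and** mito fraction ≤ 0.20 | exactly 20% kept ("exceeds" is strict) |
| genes | detected in ≥ 3 units | 3 kept, 2 removed |

The two cell criteria combine as OR-removal: a cell failing either goes.
Mitochondrial genes are recognized by the human "MT-" name prefix; with no
such genes present the mitochondrial criterion is skipped with a warning.
Filters run once each, units before genes, with detected-gene counts taken
on the matrix as passed in; an `iterative=True` flag on `apply_qc` re-filters
to a fixed point instead.  On matrices whose low-quality units fail by a wide
margin (as the simulator plants them) the two filters commute.

### Clustering

Agglomerative clustering with Ward linkage on Euclidean distances over a
chosen gene subset (by default the top-variable genes by linear-scale
dispersion, variance/mean), cut to a configured k, labels renumbered by
decreasing cluster size.  k and the number of variable genes are config
parameters with no claimed defaults — cluster counts in real tissue are a
judgment call — and the pipeline default (k=5, 300 genes) simply matches the
synthetic study design.  Ties in the variable-gene ranking break
lexicographically on gene id.

### The bimodal likelihood-ratio test

Single-cell expression of one gene in one group is modelled as a mixture of
a point mass at zero (probability 1−π) and a normal distribution on the
positive values.  With m positives among n values, the fitted log-likelihood
uses π̂ = m/n clamped to [1e-5, 1−1e-5], μ̂ the mean of positives, and σ̂
their *sample* (ddof = 1) standard deviation, replaced by 1 when there are
fewer than two positives or they are constant.  The statistic
2·[L(A)+L(B)−L(A∪B)] is referred to χ² with 3 degrees of freedom (π, μ, σ).
Because σ̂ is not the exact MLE the statistic can dip microscopically below
zero; it is clipped.  Two all-zero groups short-circuit to (0, 1).

One-vs-rest marker detection applies the conventional gates *before*
testing — max(pct_in, pct_out) ≥ 0.01 and |log fold change| ≥ 0.1, where the
fold change is ln((mean₁+1)/(mean₂+1)) on the back-transformed linear scale
(the +1 "pseudo-mean" keeps it finite at zero) — then adjusts p-values by
Benjamini–Hochberg within each cluster's tested set.

A deliberate caveat, verified experimentally: the test is well calibrated
under a true null (random splits of homogeneous data give ~5% of p < 0.05
and zero BH discoveries), but gating on the *observed* fold change selects
null genes with inflated effects, and when a cluster also has many strong
true markers the BH threshold rises.  The realized false-discovery
proportion inside a "significant markers" set is therefore above the nominal
5% — on the synthetic study ~10–25% of a recovered set, with recall of the
planted markers essentially 1.0.  This mirrors the behavior of the
fold-gated marker pipelines in common use; the recovery tests assert recall
and a precision floor rather than a nominal FDR.

### Multimodal intersection analysis

For cell-type marker set A and region marker set B inside a background
universe of N genes, the overlap k = |A∩B| is referred to
X ~ Hypergeometric(N, |A|, |B|): enrichment p = P(X ≥ k), depletion
p = P(X ≤ k), both tails including the observed k (the standard one-sided
exact-test convention).  Tails are computed by `scipy.stats.hypergeom`,
which works in log-space internally and is verified in the test suite
against exact integer enumeration (≤ 1e-12 absolute over every universe up
to N = 20, and well-behaved at N = 1e5).

The universe is the **intersection** of the gene ids present in the two
processed datasets — an overlap is only observable for genes measured on
both sides; callers may pass a union universe instead.  The display score is
−log10(p_enr) when the enrichment tail is smaller, +log10(p_dep) otherwise,
so enrichment is positive and depletion negative (the red/blue heatmap
convention).  Raw p-values drive the map; BH-adjusted values are serialized
alongside for reference, but no adjustment is applied to the scores.  Region
assignment takes each region's best-scoring cell type, with a configurable
score floor below which the region is "unassigned" and lexicographic
tie-breaking.

### Cell-cycle staging

G1/S and G2/M scores are arithmetic means of normalized expression over two
core sets shipped as package data (43 G1/S genes, 54 G2/M genes, the
canonical human symbol lists; any GMT can be substituted — the gene identity
is data, not contract).  Classification: both scores < 2 → quiescent (G1);
otherwise proliferative, taking G2/M when the G1/S score is the smaller and
G1/S when the G2/M score is the smaller.  The threshold 2 is interpreted on
the pipeline's log2-normalized scale and is a config parameter; the strict
inequalities leave a tie between two proliferative scores undefined, which
is resolved to G1/S and logged.  Scores here are raw set averages — the
regression-based, control-bin-centered scoring of some toolkits is a
different algorithm and out of scope.

### Gradual trends

A gene is "gradually up-regulated" along an ordered stage series when its
per-stage mean normalized expression increases strictly at every step
(optionally by at least a margin ε, default 0) *and* the bimodal LRT between
the first and last stages is significant after BH adjustment across all
genes; "gradually down-regulated" is symmetric.  Per-adjacent-pair
significance was the alternative reading; extremes-only was chosen because
with monotonicity already required it is the sharper and cheaper test, and
reversing the stage order then swaps the up and down sets exactly.  The
balanced PCA view draws an equal number of units per group (sampling
without replacement, seeded, sorted-id order so the draw is input-order
invariant) and projects centered, unscaled log2 values onto the top two
components, with component signs canonicalized (largest-magnitude loading
positive) for run-to-run comparability.

## The simulator

`simulate` generates what the analysis assumes, with the truth recorded:

* **Counts**: negative binomial via gamma-Poisson with per-gene lognormal
  baselines (σ = 1) scaled to a target mean library (6,000 counts/unit —
  chosen to land detected-genes/UMIs per unit in the 1.1–2.3k genes,
  6–9k UMIs range typical of liver-tissue spot arrays), per-unit lognormal
  library sizes (σ = 0.35), NB size r = 2.
* **Groups**: disjoint marker sets (default 50 genes/group) multiplied by a
  known fold change (default 4) inside their group.  Spatial regions are
  contiguous row-blocks of a square array — deterministic layout, randomness
  only in counts.  Cell types in the single-cell generator reuse the same
  marker assignment, giving the planted region↔type correspondence MIA
  should recover.
* **Mitochondria**: ~1% of genes are "MT-"-prefixed and carry ~8% of a
  healthy unit's UMIs.
* **Cell cycle** (cells only): phases drawn to fixed per-phase counts
  (default 60/20/20% G1/S/G2M); S cells express the packaged G1/S set, G2M
  cells the G2/M set, at 6× a baseline placed at normalized value ≈ 1.2, so
  quiescent set-averages sit near 1.2 and active ones near 2.6 — separated
  by construction around the threshold of 2.
* **QC failures**: a chosen fraction of units (default 10%) is degraded.
  Spots (and half of bad cells) are binomially thinned until they detect
  fewer than 200 genes — thinning, not redrawing, so gene rank structure is
  preserved; the other half of bad cells get one MT gene inflated until the
  mitochondrial share reaches ~30%.  The counts are exact by construction,
  which is what makes the QC boundary tests sharp.
* **Stage series**: planted monotone genes drift geometrically between 1×
  and the fold change across the ordered stages (up and down sets, 50 genes
  each by default); all other genes are flat.

Identical parameters and seed give bit-identical output.

### What the simulator does not emulate

No spatial autocorrelation within regions (regions are blocks, but counts
are independent across spots), no doublets, no batch or section effects, no
gene-gene correlation beyond the group structure, no ambient RNA.  Cell
identities carry exactly the planted markers — far fewer genes than real
cell types differ by.  One measured consequence: with the default phase mix
the planted cell-cycle program (97 genes at 6×, strong enough to clear the
score threshold) can dominate Ward clustering of the single-cell data at
small k, splitting cells by phase before type — something much rarer in real
data, where identity programs span thousands of genes.  The end-to-end MIA
recovery experiment therefore generates its single-cell side with all cells
in G1, isolating the structure it tests; the phase program is exercised by
its own recovery experiment.  Passing tests demonstrate correctness of the
procedures under this generative model, not performance on any real tissue.

## Reproducibility experiments and problem sizes

`stmia.experiments` (driven by `scripts/acceptance.py` and the acceptance
tests) runs: exhaustive hypergeometric enumeration for all universes N ≤ 20
(10,625 cases); bimod null calibration with 5,000 replicate genes of 100
units per group drawn from one zero-inflated half-normal (π = 0.5,
|N(2,1)|); 20-seed MIA recovery at 5 groups × 200 units × 50 markers at
fold 4; 20-seed cell-cycle recovery at 1,000 cells; 20-seed trend recovery
at 3 stages × 200 units.  These sizes keep every study statistically
comfortable while the full suite runs in well under a minute; per-replicate
seeds derive deterministically from the single base seed.

## Numerical choices and degenerate inputs

* π̂ clamping (1e-5) and the σ̂ = 1 fallback prevent infinite likelihoods at
  all-zero or constant-positive groups; two all-zero groups return p = 1.
* p-values are floored at 1e-300 before log10 for display scores.
* Empty marker sets propagate as empty with warnings (a cluster can have no
  significant markers); an empty universe is an error.
* All tie-breaks (variable-gene ranking, marker-table ordering, region
  assignment) are lexicographic on ids, making every table deterministic.
* Percentages are reported half-up to two decimals.
* Pipeline TSVs carry `stmia` version, seed and a config digest in comment
  headers; fixed float formatting makes re-runs byte-identical.

## Known limitations

The χ²(3) reference for the bimodal LRT is asymptotic; at very small groups
(< ~20 units) p-values are approximate.  The hypergeometric model treats
marker sets as uniform random draws from the universe, ignoring detection
bias by expression level.  Ward/Euclidean clustering assumes roughly
spherical clusters on the selected genes and needs k supplied.  Graph-based
clustering, embedding computation (UMAP/t-SNE), pseudotime, deconvolution
and label transfer are deliberately out of scope.
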