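# Methods

## Data model and standardization

The pipeline operates on a dense genes × samples abundance grid in which
every sample column is one (condition, omic layer) pair — typically 7
conditions × {transcript, protein} = 14 columns. Columns are standardized
independently, `Z = (x − μ)/σ`, with **population** standard deviation
(divisor N): with thousands of genes per column the N vs N−1 distinction is
immaterial, and divisor-N matches the conventional standard-scaler
behaviour. A zero-variance column is a hard error naming the sample; there
is no silent fallback.

Raw omics abundances are heavy-tailed, so `standardize` accepts a
`log2(x+1)` pre-transform; the CLI applies it by default when reading raw
abundance tables, and the transform actually applied is recorded on the
result so downstream consumers can interpret contrast units. Whether a
given study z-scored raw or logged values is often unreported; both paths
are first-class here and the choice is a single flag.

Diagnostics (per-column histograms on fixed bins over z ∈ [−5, 5],
skewness, min/max) mirror the manual QC of checking that every column has a
reasonable sigmoidal CDF and comparable range. A column is flagged when its
|min| or |max| differs from the across-column median of that extreme by
more than a factor (default 2.0). Flags warn and never abort: QC evidence
belongs to the analyst, not the pipeline.

## PCA orientation and the word "loading"

With ~10³–10⁴ genes and ~14 columns, the decomposition is a full dense SVD
`Z = U S Vᵀ` (no truncated/randomized solver is warranted at this size).
The package treats **genes as observations and samples as features**:

* sample coordinates = rows of `V` (unit-norm axis weights) — the points
  shown when the samples are plotted in PC1/PC2 space; a variant scaled by
  the singular values is exposed alongside, since plotting conventions
  differ and both are defensible;
* gene scores = `U S` — each gene's projection onto the axes.

In the applied literature "loading" is used loosely for both quantities.
The two usages coexist only under this orientation: samples get weights,
genes get projections, and the per-gene projections are what get ranked
and averaged into pathway scores. Variance explained is `s_k²/Σ s_j²`
computed over the **full** spectrum, so retained fractions are unaffected
by how many components the caller keeps.

Sign convention: each component is flipped so that the sample weight of
largest magnitude is positive. SVD signs are otherwise arbitrary and this
rule makes repeated runs bit-identical.

## The A1/A2 rotation

For each condition *i* with standardized transcript column `Ztᵢ` and
protein column `Zpᵢ`, the rotation emits `A1ᵢ = Ztᵢ + Zpᵢ` (magnitude-like,
amplifying structure shared by the layers) and `A2ᵢ = Ztᵢ − Zpᵢ`
(difference-like, isolating layer disagreement). The rotated matrix is
**not** re-standardized by default: the rotation acts on already-z-scored
columns, and rescaling would erase exactly the A1-vs-A2 magnitude contrast
the analysis inspects (a tightly-near-zero A2 band is a finding, not a
normalization defect). A flag exposes re-standardization; it errors on
identically-zero A2 columns, which is the correct behaviour for a
degenerate layer-identical input. The inverse map `(A1 ± A2)/2` restores
the original columns and labels exactly (to fp round-off), and is tested as
a bijection.

## Pathway scoring

A pathway's score on component *k* is the signed arithmetic mean of the
component-*k* gene scores of its members **present in the matrix**. Two
ranking modes exist: `signed_mean` (descending score) and `abs_mean`
(descending |score|, score column still signed) — the latter is what
recovery simulations use, since a planted effect may load either end of an
axis depending on the SVD's overall orientation. Design choices:

* `min_size` default 3 — means over 1–2 genes are noise-dominated;
* genes annotated to several pathways contribute fully to each (no
  down-weighting); the score is a ranking device, not a test statistic, and
  no permutation/hypergeometric p-values are attached by design;
* all annotated members present in the data are averaged, not only
  "differential" ones — any differential pre-filter would build the answer
  into the question.

`top_k_annotation_fraction` reports how many of the k highest-loading genes
carry a target annotation. On synthetic data at the default effect size
this fraction is deliberately weak (individual planted genes sit inside
the noise floor) while the pathway *mean* ranks first almost always — the
contrast between the two statistics is the method's core argument for
averaging over gene sets.

## Condition contrasts and map colouring

Per-gene contrasts between two conditions on one layer default to the
difference of standardized values (dimensionless z-units); a
`log2((a+1)/(b+1))` raw-scale mode is exposed. For KEGG-map colouring the
contrast is clipped to ±`clip` (default 2.0 z-units ≈ the dynamic range of
typical z-scored panels) and binned into an odd number of bins (default
11) so an exact neutral centre exists. Bins are computed symmetrically
from |v| and sign, so negating a contrast mirrors its bin exactly, ties
included. The ramp is fixed (blue → turquoise → yellow → orange → red;
blue = most under-expressed) and exported as `gene<TAB>#RRGGBB` per the
KEGG colour-mapper convention.

## Bicluster heatmaps

Rows and columns are clustered independently (scipy agglomerative linkage;
defaults euclidean/average — the settings such heatmaps most commonly use
when unstated, and robust on z-scored data). Leaf order is a deterministic
recursive traversal: smaller child cluster first, ties by the
lexicographically smallest label in the cluster. This makes the order a
pure function of data + labels (permutation-invariant), at the cost of not
minimizing adjacent-leaf distance; scipy's optimal leaf ordering is
available behind a flag. Pathway-subset heatmaps keep the z-values of the
full matrix — the subset's columns are intentionally no longer mean-0/sd-1,
so colours remain comparable to the full heatmap.

## Synthetic-data generator

Log-normal abundance model with additive effects on the log2 scale:

```
log2 x[g, c, l] = baseline_log_mean + b_g + λ_g·[l = protein]
                  + Σ planted δ·[g ∈ pathway, c affected, l affected] + ε
b_g ~ N(0, baseline_log_sd²),  λ_g ~ N(layer_offset, layer_sd²),
ε ~ N(0, noise_sd²) i.i.d. per cell,  abundance = 2^log2x
```

Defaults: 2000 genes, 20 pathways × 25 genes (first 500 genes annotated in
blocks), 7 conditions (Ferm9h/19h/30h, LB20/60/100, HighUrea) × 2 layers,
`layer_offset = 1.0` with `layer_sd = layer_offset/2 = 0.5`,
`noise_sd = 1.0`, `baseline_log_mean = 8`, `baseline_log_sd = 0.2`, and one
planted effect: pathway 1 shifted by δ = +2 log2 units in LB20 and LB100 on
both layers. All draws come from one seeded generator in a fixed order, so
identical configs give bit-identical outputs.

Two modelling points are load-bearing:

* **The layer effect must vary per gene.** A constant transcript-vs-protein
  offset is a column-constant shift and vanishes under per-column
  z-scoring; it is the gene-to-gene spread of λ_g (per-gene translation
  behaviour) that survives standardization and lets PC1 separate the
  layers. A test documents the trap.
* **The shared baseline spread is deliberately small** (0.2 log2 units vs
  noise 1.0). `b_g` is common to all 14 columns, so its variance feeds an
  all-positive "overall abundance" component; at a realistic spread of
  ~2 log2 units that component would dominate PC1 and absorb the variance
  the layer and pathway factors need to surface on PC1/PC2. Keeping it
  sub-dominant is what makes the generator produce the qualitative
  structure the pipeline is designed to detect — at the cost that the
  synthetic data do not reproduce the large gene-to-gene dynamic range,
  the condition-wide regulatory programs, or the mRNA–protein correlation
  profile of real datasets. Passing recovery tests therefore demonstrate
  correctness of the machinery under the stated model, not performance on
  real data.

`recovery_harness` runs generate → standardize(log2p1) → PCA → abs-mean
pathway scoring on PC2 per replicate (seeds `seed+0 … seed+n−1`) and
reports the planted pathway's rank, its score, the top-10 annotation
fraction along the planted direction, PC1 layer separability (disjoint
transcript/protein weight ranges), and PC1/PC1+PC2 variance fractions.

Frozen regression value: with no planted effects and no layer structure
the mean PC1 variance fraction at the default dimensions was measured once
by simulation at 0.108 (max 0.114 over 30 seeds) and is asserted to stay
below 0.12.

## Numerical conventions and edge cases

* Tolerances: standardization moments to 1e-9; PCA vs brute-force
  eigendecomposition to 1e-8; rotation round-trip to 1e-12; pathway score
  vs an fsum oracle to 1e-12 (summation-order ulps are the only
  difference); table write→read round-trip to 1e-12 (`%.17g` floats).
* Component indices are 1-based everywhere a user supplies them
  (`component=2` means PC2), matching the PC1/PC2 column names.
* Duplicate gene ids, missing cells (unless imputation by within-layer
  gene median is requested), unpaired condition/layer columns, empty
  annotations, even bin counts and zero-variance columns are all typed
  hard errors; validation in `run-all` happens before any computation.
* Problem sizes in the test-suite simulations (100 replicates of the
  2000 × 14 default; smaller grids for unit tests) were chosen as the
  smallest sizes at which the measured rates are stable across seeds.

## Known limitations

* The generator's realism limits are described above; in particular PC1
  variance fractions on synthetic data (~0.17) are well below what real
  panels show, because real layer differences are far larger.
* Pathway scores carry no significance calibration; ranks are descriptive.
* The bicluster view emits orderings and linkages (plus an optional static
  image); interactive exploration is out of scope.
* Heatmap distance/linkage defaults are conventions, not inferences; with
  unstated upstream settings, visual comparisons to published heatmaps are
  qualitative only.
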