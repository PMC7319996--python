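# tissuedecoder

Cell-type composition of bulk tissue from gene expression.

Bulk (whole-tissue) transcriptomes average over every cell type present —
in adipose tissue: adipocytes, adipose stem/stromal cells (ASCs), a dozen
immune populations, endothelial cells, fibroblasts and more. Counting
those populations directly (immunohistochemistry, flow cytometry) is
labor-intensive, marker-dependent and poorly standardized across studies.
`tissuedecoder` estimates the relative cell-type fractions of bulk samples
computationally, so that any archived expression dataset becomes a
cell-composition dataset.

## The model

A bulk profile **m** (linear-scale expression over signature genes) is
modeled as a convex combination of cell-type-specific profiles:

```
m ≈ S f,    f_j ≥ 0,   Σ_j f_j = 1
```

where **S** is a *signature matrix* (genes × K cell types) of mean
expression of isolated cell types, and **f** the fraction vector to
estimate. The pieces:

- **Signature construction** (`build_signature`): per cell type, genes are
  ranked by a differential test (unequal-variance t-test vs. all other
  samples, Benjamini–Hochberg FDR, fold-change ranking); the per-type
  marker-set size G is swept and the union whose mean-profile submatrix
  minimizes the condition number κ = σ_max/σ_min is kept. Lower κ means
  the cell-type columns are more mutually distinguishable.
- **Deconvolution** (`deconvolve_sample` / `deconvolve_dataset`):
  linear-kernel ν-support-vector regression of the standardized mixture on
  the standardized signature, ν selected per sample from {0.25, 0.5, 0.75}
  by reconstruction RMSE; negative coefficients are clipped and the rest
  normalized to fractions. The ε-insensitive SVR loss tolerates genes that
  violate the linear-mixing assumption.
- **Marker scoring** (`primary_criterion` / `secondary_criterion`): for
  mean expression g′_ij of gene i in type j,
  `crit_primary(i,j) = g′_ij − max_{k≠j} g′_ik` (exclusive markers, what an
  antibody assay needs) and
  `crit_secondary(i,j) = g′_ij − mean_{k≠j} g′_ik` (enriched markers,
  combinable when no exclusive marker exists).
- **Literature unit conversion** (`to_percent_total`): published cell
  counts in percent-of-SVF, per gram, per 100 adipocytes or per total
  nuclei map linearly onto percent of total cells given an explicit
  adipocyte fraction and cells-per-gram; per-high-power-field and per-mm²
  counts are excluded.
- **Phenotype statistics** (`paired_test`, `unpaired_test`,
  `spearman_perm`, `adjust_bh`): rank-based tests (fractions are bounded
  and skewed) with joint Benjamini–Hochberg adjustment over the whole
  cell-type × trait grid.
- **Synthetic data** (`simulate_reference`, `simulate_mixtures`,
  `simulate_phenotypes`): log-normal expression with planted disjoint
  markers, Dirichlet mixture fractions and planted group effects, so every
  component is testable with known ground truth.

## Worked example

```python
import numpy as np
import tissuedecoder as td

cfg = td.SimulationConfig(
    n_features=300, n_types=6, markers_per_type=10, marker_effect=8.0,
    replicates_per_type=5, noise_cv=0.05, dirichlet_alpha=np.ones(6),
    n_mixtures=100, seed=1)
ref, _ = td.simulate_reference(cfg)
sig = td.build_signature(ref, g_min=5, g_max=15)
mixtures, truth = td.simulate_mixtures(td.type_profiles(ref), cfg)
frame = td.fractions_frame(td.deconvolve_dataset(mixtures, sig))
print(np.abs(frame[truth.columns].to_numpy() - truth.to_numpy()).mean())
```

Running `python examples/deconvolve_mixtures.py` (this scenario) prints:

```
signature: 30 features x 6 cell types, condition number kappa = 3.466 at G = 5 markers/type

per-type mean absolute error (fractions, 0-1 scale):
  type_1: 0.0056
  type_2: 0.0064
  ...
overall MAE: 0.0069  (well under 0.05 means near-perfect recovery at 5% noise)

pure 'type_1' profile -> fraction 1.000 for type_1 (rest 0.000)
```

i.e. with six well-separated cell types and 5% multiplicative noise, the
estimated fractions are within ~0.7 percentage points of the simulated
truth on average, and a pure cell-type profile is assigned entirely to its
own type. The other scripts in `examples/` walk through marker scoring
(`score_markers.py`), literature comparison (`literature_comparison.py`)
and phenotype association (`phenotype_associations.py`).

## Command line

The same steps are available as subcommands for shell pipelines:

```
tissuedecoder simulate --out fixtures/ --seed 7
tissuedecoder build-signature --ref fixtures/ref.tsv --labels fixtures/labels.tsv --out sig.tsv --gmin 50 --gmax 150
tissuedecoder deconvolve --sig sig.tsv --mix fixtures/mixtures.tsv --out fractions.tsv --perm 100 --seed 7
tissuedecoder markers --ref fixtures/ref.tsv --labels fixtures/labels.tsv --out markers.tsv --top 10
tissuedecoder convert-units --records literature.tsv --out converted.tsv --adipocyte-fraction 0.74 --cells-per-gram 2e7
tissuedecoder compare --fractions fractions.tsv --pheno fixtures/pheno.tsv --out associations.tsv --seed 7
```

All outputs are TSV, sorted for reproducible diffs; identical seeds give
byte-identical files.

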