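# ccv — chemical characteristics vectors for LC-MS/MS sample comparison

`ccv` compares the chemical space of untargeted LC-MS/MS samples without
requiring structural annotation of individual peaks. Per-peak probabilistic
substructure (molecular fingerprint) and compound-class predictions are
binarized at a threshold (default 0.5) and averaged per sample — optionally
within precursor-mass bins — into fixed-length *chemical characteristics
vectors* (CCVs) whose entries are the fraction of MS/MS-characterized peaks
carrying each characteristic. Six sample representations are supported:

| tag | description |
| --- | --- |
| `ms1_presence` | binary detection of aligned MS1 peaks |
| `ms1_log10` | log10 peak areas (0 when absent) |
| `mfp_avg` | whole-sample averaged fingerprint CCV |
| `mfp_massgrouped` | per-mass-bin fingerprint CCVs, concatenated |
| `cc_avg` | whole-sample averaged compound-class CCV |
| `cc_massgrouped` | per-mass-bin compound-class CCVs, concatenated |

Both branches apply the same precursor m/z window (default 100–900 Th); the
default mass-group scheme has seven bins (100–250, 250–300, 300–350, 350–400,
400–450, 450–550, 550–900).

Downstream, the package provides recursive feature elimination under k-fold
cross-validation with elbow-selected target size and two aggregation rules
(`rfe1` = union over folds, `rfe2` = intersection), clustering validity
indices (Calinski-Harabasz, Dunn, silhouette) computed with biome labels as
cluster assignments on Euclidean distances, PCA/UMAP projections,
cross-validated classification (random forest, kNN, Gaussian naive Bayes with
uniform priors, plus uniform-random and most-frequent baselines), per-biome
compound-class ratio summaries, and Wilcoxon rank-sum contrasts between
metadata-defined subgroups. A synthetic-study generator emulates the complete
input layer (quantification table, prediction tables, metadata) with planted
biome effects so every stage is testable offline.

## CLI

```sh
# generate a synthetic study (quant.csv, prediction TSVs, metadata.tsv)
ccv simulate --preset tiny --out study/ --seed 1

# build representation matrices (TSV with a "# method:" header)
ccv build --in study/ --method all --out matrices/

# feature selection on one matrix
ccv select --matrix matrices/mfp_avg.tsv --metadata study/metadata.tsv \
    --k 10 --seed 1 --n-target 150 --out selection.json

# clustering indices + classifier accuracies for the full variant grid
ccv evaluate --matrices matrices/ --metadata study/metadata.tsv \
    --folds 10 --seed 1 --out report.tsv

# compound-class interpretation
ccv analyze classes --matrix matrices/cc_avg.tsv --metadata study/metadata.tsv \
    --classes 3,7 --out ratios.tsv
ccv analyze contrast --matrix matrices/cc_avg.tsv --metadata study/metadata.tsv \
    --biome biome_01 --groupby contributor --out contrast.tsv

# or the whole workflow from one declarative config
ccv run --config config.yaml --out run/
```

A minimal pipeline config:

```yaml
study: {preset: tiny}        # or `inputs: {dir: path/to/study}`
selection: {n_target: 3, k: 3}
evaluation: {k: 3}
seed: 7
```

Every run directory contains a `manifest.json` with the config snapshot,
per-stage seeds, input digests and wall-clock times; deterministic stages
reproduce bit-identically from the same manifest inputs.

## Package layout

```
src/ccv/
  types.py       domain containers (FeatureTable, PredictionSet, SampleMetadata,
                 MethodMatrix, MassGroupScheme) and shared defaults
  formats_io.py  quant CSV / prediction TSV / metadata / matrix readers+writers
  core.py        binarization, averaging, mass grouping, MS1 matrices, filters
  selection.py   RFE per fold, elbow rule, rfe1/rfe2 aggregation
  evaluation.py  clustering indices, normalization, PCA/UMAP, classifiers
  biome.py       class-ratio tables, rank-sum contrasts, mass-group profiles
  simulate.py    synthetic study generator with planted ground truth
  pipeline.py    end-to-end orchestration with run manifests
  cli.py         click-based command-line interface
```
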