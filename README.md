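# atlasforge

Single-cell atlas construction and annotation toolkit. Implements the
computational stages of a hierarchical brain-atlas pipeline as a tested,
reusable Python package:

- **data_model** — sparse cell×gene matrices (Matrix Market I/O), log
  normalization, QC filtering (UMI / mitochondrial fraction), HVG selection,
  deterministic PCA, doublet-cluster and multi-signature-cluster flagging.
- **synthetic** — seeded generators for every pipeline input with exported
  ground truth: hierarchical cell types with per-node markers, per-batch
  effects, doublets, a fasting-like IEG condition effect, an ISH voxel grid
  with region-specific marker energies, bulk IP-vs-input signatures as noisy
  cluster mixtures, and a distorted second modality.
- **batch** — within-dataset batch detection by iterative sample merging
  gated on normalized out-of-bag classifier entropy (random-forest default,
  pluggable classifier contract).
- **tree** — SNN graph (Jaccard k-NN), multi-resolution Leiden ladder,
  greedy level selection (~3× clusters per level), plurality-overlap tree
  reconciliation with strict nesting, and marker-based sibling pruning.
- **markers** — stratified rank-sum (van Elteren) testing, expression
  fractions, fold changes, and the specificity score
  S = log2FC × pct_in / pct_out.
- **annotation** — automated node naming via
  T = S_all × S_siblings / max(child S_siblings), with exclusion prefixes,
  ancestor-reuse rules and concatenated hierarchical names.
- **regions** — rank-based region prediction from voxel probe energies
  (normalized median marker rank, top-4 voxel aggregation, dataset-origin
  down-scaling).
- **projection** — query embedding into the reference latent space (PCA
  projector by default, pluggable) and similarity-weighted k-NN label
  propagation with per-cell probabilities (sim = 1 − d²/2).
- **signatures** — ranked bulk signature construction and extrapolated
  rank-biased overlap (RBO) mapping onto cluster marker lists.
- **activation** — immediate-early-gene activation scoring per cluster and
  condition, per-cluster differential expression, cross-cluster DEG overlap.
- **xmodality** — per-gene and per-cluster Pearson correlation of
  cluster-level pseudobulk between modalities, with gene-class summaries.

## Tests

```sh
python -m pytest tests/
```

`tests/test_acceptance.py` holds the acceptance suite: oracle equivalences
(rank-sum test, exact-arithmetic RBO series, brute-force Pearson), exact
hand-computed values, and planted-ground-truth recovery bounds (batches,
tree ARI, naming, regions, projection, signature mapping, activation,
cross-modality) on seeded synthetic data.

## CLI

```sh
atlasforge simulate --config sim.yaml --out data/      # YAML SimConfig, seed required
atlasforge qc --counts data/ --out qc/ --min-umi 1000 --max-mito 0.1
atlasforge doublet-clusters --counts qc/ --labels labels.tsv --threshold 0.7
atlasforge batches --counts qc/ --out batches/ --threshold 0.9 --seed 0
atlasforge tree --counts qc/ --out tree/ --min-markers 10 --k 25
atlasforge enrich --signature sig.csv --markers tree/markers.tsv \
    --tree tree/tree.json --level 2 --p 0.98 --out enrichment.tsv
```

All commands operate on a counts directory (`matrix.mtx`, `genes.tsv`,
`cells.tsv` with metadata columns).

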