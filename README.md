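# pfasqsar

Semi-supervised metric-learning QSAR workflow for per- and polyfluoroalkyl
substances (PFASs): from SMILES + bioassay tables through fingerprinting,
pairwise-constraint metric learning, embedding, clustering with
silhouette-based model selection, and maximum-common-substructure (MCS)
attribution with a bioactive-ratio statistic. Ships with a seedable
synthetic-data generator so every stage runs at desk scale with no
downloads.

## What it does

1. **chemio** — parse/validate molecule tables (CSV/TSV, optional SDF),
   canonicalize SMILES, and apply PFAS membership filters: any C–F bond
   (`[#6][F]`) or a perfluoroalkyl chain of ≥ 3 carbons.
2. **featurize** — 2048-bit ECFP4 (Morgan radius-2) fingerprints, Tanimoto
   similarity, and an optional binding-affinity co-descriptor column scaled
   to be commensurate with the binary bits.
3. **metric_learning** — the core: a linear map `L` is learned from
   same-label / opposite-label pairs among the (few) labeled molecules by
   minimizing a margin-based contrastive loss
   `Σ_similar d² + Σ_dissimilar max(0, margin − d)²` with
   `d(x, y) = ‖L(x − y)‖`; the map then embeds every molecule, labeled or
   not.
4. **embed_cluster** — PCA, 2-D t-SNE maps, k-means (k-means++ / Lloyd with
   inertia traces), silhouette scoring, and silhouette-based selection of
   the cluster count.
5. **substructure** — MCS motifs of bioactive cluster members, dataset-wide
   SMARTS matching, and the bioactive ratio: the fraction of labeled,
   motif-matching molecules that are active.
6. **affinity** — ingest externally computed docking affinities (kcal/mol)
   and summarize them against a bioactivity threshold.
7. **synthetic_data** — seedable generator with planted ground truth (ester
   motif, conditional activity, fluorination fractions, label sparsity,
   affinity separation).

## CLI

```bash
# generate a synthetic dataset (molecules.csv + ground_truth.csv sidecar)
pfasqsar generate --n 2000 --seed 1 --out data/ --with-affinities

# end-to-end run from a config file
pfasqsar run config.yaml

# individual stages
pfasqsar filter data/molecules.csv --mode c3f6 --out kept.csv
pfasqsar featurize data/molecules.csv --out descriptors.coo.csv
pfasqsar fit-metric data/molecules.csv --target T1 --seed 1 --out model.json
pfasqsar cluster data/molecules.csv --metric-model model.json --k 8 --seed 1 --out clusters.csv
pfasqsar motifs data/molecules.csv clusters.csv --target T1 --out motifs.csv
pfasqsar affinity-summary data/affinities.csv --target T1 --threshold -5
```

A minimal config (`config.yaml`) needs only the input path and a seed; all
other keys have defaults and unknown keys are rejected:

```yaml
input:
  molecules: data/molecules.csv
  affinities: data/affinities.csv   # optional
target: T1
cluster:
  k: 8            # or k_grid: [5, 10, ..., 60] for silhouette selection
seed: 1
output_dir: run
```

`pfasqsar run` writes per-stage artifacts (molecules, descriptors, metric
model, cluster assignments, motif reports), a manifest with every resolved
parameter plus library versions, and a human-readable summary. Exit codes:
0 ok, 2 config error, 3 data error, 4 numeric divergence.

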