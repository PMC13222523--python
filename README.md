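# oorkit

Post-processing for probabilistic cell-type annotation outputs (e.g. a
CellTypist probability matrix). `oorkit` turns each cell's probability row
into a compact uncertainty representation, assigns an identity-stability
group, and quantifies each cell's deviation from a control population as a
covariance-aware **out-of-reference (OOR)** score with cluster-level
enrichment statistics.

## What it computes

1. **Uncertainty features** per cell: assurance `P1` (top probability),
   confidence gap `delta = P1 - P2`, admixture ratio `P2 / P1`, and
   normalized entropy `H` (Shannon entropy of the renormalized row divided
   by `log K`).
2. **Stability groups** from threshold logic and a label hierarchy
   (tissue + cell class): `G0` single confident identity, `G1` no
   confident identity, `G2`/`G3` multiple confident identities within /
   across lineages, and soft-threshold analogues `G2s`/`G3s`. An adaptive
   mode suggests thresholds from the IQR of the `P1` distribution.
3. **OOR scores**: squared Mahalanobis distance of each cell's feature
   vector from its cluster's reference (control-cell) mean under a shrunk
   covariance `(1 - λ)Σ + λ·diag(Σ) + εI` (default `λ = 0.1`), with a
   global fallback for clusters holding fewer than 50 reference cells.
4. **Cluster summaries**: median OOR shift between conditions, tail
   enrichment beyond a reference quantile (default 0.9), binomial or
   within-cluster permutation tests, and Benjamini–Hochberg FDR across
   clusters.

A synthetic-fixture module generates probability matrices with known group
truth and calibrated condition shifts, so the whole pipeline is testable
without any external data.

## CLI

```sh
# synthetic fixture (probabilities.csv, metadata.csv, hierarchy.json, config.yaml)
oorkit simulate --out demo --n-ref 300 --n-query 300 --clusters 2 --seed 1

# full pipeline from YAML: writes cells.csv, clusters.csv, manifest.json
oorkit run --config demo/config.yaml --plots

# or stage by stage (stages compose through CSVs)
oorkit classify --probs demo/probabilities.csv --hierarchy demo/hierarchy.json \
    --hard 0.5 --soft 0.3 --out stage1
oorkit score --cells stage1/cells.csv --metadata demo/metadata.csv \
    --ref-level control --cluster-col cluster --out stage2
oorkit summarize --cells stage2/cells.csv --ref-level control \
    --cluster-col cluster --quantile 0.9 --test binomial --out stage3
```

Input formats: probability matrix and metadata as UTF-8 CSV (cell id in
the first column), label hierarchy as JSON
(`{"label": {"tissue": ..., "cell_class": ...}}`), configuration as YAML.
Rows are *not* renormalized by default (one-vs-rest annotator scores need
not sum to 1); set `renormalize_rows: true` to force distributions.
Entropy is always computed on the renormalized row.

## Python API

```python
import oorkit as ok

m = ok.read_probability_matrix("probs.csv")
hierarchy = ok.read_hierarchy("hierarchy.json")
features = ok.compute_feature_table(m)
assignments, fractions = ok.classify_all(m, ok.ThresholdSpec(hard=0.5, soft=0.3), hierarchy)
```

See `oorkit.reference` (fit/score) and `oorkit.stats` (summaries/tests)
for the OOR layer, and `oorkit.pipeline.run_pipeline` for the orchestrated
run.

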