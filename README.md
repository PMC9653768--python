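# teratoclass

Reusable pipeline for transcriptomics-based classification of developmental
toxicants from hiPSC differentiation assays (neuroepithelial "UKN1" and
cardiomyoblast "UKK2" style studies). It covers:

- **`core_io`** — domain types (conditions, expression studies, score sets,
  classification reports), TSV readers/writers, and the packaged
  per-condition study tables (SPS counts, cytotoxicity flags, truth labels,
  confusion labels, published operating points).
- **`synthetic_data`** — a seeded study generator with planted per-compound
  deregulation, replicate noise, batch effects shared with matched
  controls, and cytotoxic conditions that contribute no expression data,
  plus a ground-truth manifest and a qPCR panel simulator.
- **`diffexp`** — control-matched normalization, empirical-Bayes moderated
  one-sample t-test (variance shrinkage fitted from the marginal
  distribution of log-variances), Benjamini–Hochberg FDR, and
  significant-probe-set (SPS) selection (adjusted p < 0.05 and |FC| > 2,
  both strict).
- **`sps_classifier`** — SPS-count classification: cytotoxic score
  assignment (max observed count + 5), 1× stand-ins for untestable 20×
  conditions, strict `score > threshold` classification, confusion
  metrics, tie-aware ROC/AUC, and exhaustive threshold search with
  lexicographic (accuracy, sensitivity, specificity) tie-breaking; three
  cytotoxicity modes (cytotoxicity-only, gene-only, combined).
- **`top1000`** — leave-one-compound-out ℓ1-regularized logistic
  regression on the 1000 highest-variance probe sets of each training
  fold, penalty tuned by inner stratified 10-fold CV minimizing mean
  cross-validated deviance; replicate probabilities averaged per
  condition; cytotoxic conditions assigned probability 1.
- **`combine`** — condition-wise min/max/mean combination of two systems'
  score sets, including the gene-only removal variant.
- **`downstream`** — condition-mean PCA, Venn partitioning of
  teratogen-deregulated probe sets across systems, two-level top-gene
  ranking with probe-set→gene collapse, and Fisher / bottom-up 'elim'
  overrepresentation on user-supplied annotations.
- **`qpcr`** — the 7-gene RT-qPCR confirmation classifier (2^−ΔΔCT
  fold-changes, one-sample t significance, cytotoxic imputation, SPS-like
  and top-1000-like classification).
- **`cli`** — the `teratoclass` command with `run`, `simulate`,
  `diffexp`, `classify-sps`, `classify-top1000`, `combine`, `enrich`,
  `qpcr`, and `report` subcommands.

## CLI quick start

```bash
# performance summary of the packaged study tables
teratoclass report --out summary.tsv

# end-to-end synthetic run (simulate -> diffexp -> classify -> report)
cat > cfg.yaml <<'YAML'
mode: synthetic
seed: 7
simulation:
  n_probe_sets: 2000
  compounds:
    - {compound_id: T0, truth: teratogen, bucket: 20x, n_deregulated: 300}
    - {compound_id: T1, truth: teratogen, bucket: 20x, cytotoxic: true}
    - {compound_id: N0, truth: non_teratogen, bucket: 20x}
    - {compound_id: N1, truth: non_teratogen, bucket: 20x}
YAML
teratoclass run --config cfg.yaml --out runs/demo
```

Expression matrices are TSV (probe sets × samples); sample metadata is TSV
with columns `sample_id, compound_id, concentration_label, replicate,
batch, is_control, matched_controls` (comma-joined control sample ids).

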