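# methrisk

Marker discovery and disease-stage prediction from DNA methylation, built
around an aging axis: degenerative diseases unfold along the aging process,
so CpG sites that drive an accurate *epigenetic clock* are a principled
place to look for disease markers.  `methrisk` implements that idea as a
reproducible, fully testable pipeline:

1. **Clock** — a multi-scale convolutional network predicts age from beta
   values β ∈ [0, 1] (one fully connected sigmoid layer, parallel 1-D
   convolutions with kernel sizes 1/8/16/32, global average pooling, linear
   age output).  Accuracy is measured as MAD = mean |predicted − true| age
   in years.
2. **Shapley screen** — permutation-sampling Shapley values
   φ<sub>i</sub> (years, satisfying Σφ = f(x) − E<sub>ref</sub>[f])
   attribute predictions to sites; the top-k by mean |φ| are kept.  An
   exact 2<sup>n</sup> enumerator serves as the oracle for the estimator.
3. **Network panel** — screened sites map to genes; an MCODE-style
   clustering (vertex weight = k·density of the closed-neighborhood
   k-core, complex score = density × size) finds dense modules in a
   STRING-like interaction graph; upper-tail hypergeometric tests with
   Benjamini–Hochberg correction pick the best-supported module; its genes'
   CpGs form the marker panel.
4. **Stage classifier** — an MLP (default 3×64, batch norm, SeLU, Elastic
   Net) predicts early/late stage (0/1) from the panel, evaluated by
   stratified nested cross-validation (5 outer folds; grid search scored by
   3-fold inner mean AUC), beside six classical baselines on identical
   folds.

Everything runs on plain TSV/GMT inputs (beta matrix, cohort table, CpG
annotation, weighted edge list, gene sets), and a seeded synthetic-data
generator plants age signal, stage signal and a dense network module so
that every stage of the pipeline is validated by *recovering* known ground
truth.  Intended users: computational biologists prototyping
methylation-marker pipelines and anyone needing an oracle-tested reference
implementation of permutation Shapley values, MCODE-style clustering or
nested-CV classifier evaluation.

## Worked example

Simulate a study (400 samples × 2000 CpGs; 50 age-informative sites, 30
stage-informative sites concentrated on a planted 12-gene module) and run
the full pipeline:

```bash
methrisk simulate --seed 7 --outdir study/
cat > config.yaml <<EOF
inputs:
  beta: study/beta.tsv
  cohort: study/cohort.tsv
  annotation: study/annotation.tsv
  edges: study/edges.tsv
  gmt: study/pathways.gmt
seed: 7
outdir: out/
EOF
methrisk run-all --config config.yaml
```

which prints (about two minutes on one core):

```
stages: ['clock', 'attribution', 'netselect', 'ddr']
panel: 16 CpGs on 8 genes
     disease model  auc  acc  precision  recall
degenerative   mlp  1.0  1.0        1.0     1.0
```

Reading the output: the clock was trained, the Shapley screen kept the top
150 sites (`out/shap.tsv`, Table-style: CpG id, score in years, gene,
position), the network stage chose the top-ranked dense complex
(`out/panel_provenance.json` shows it at rank 0 with minimum BH-adjusted
enrichment p ≈ 7·10⁻¹¹ against the planted-module gene set) and back-mapped
it to a 16-CpG/8-gene marker panel — 14 of the 16 CpGs are planted
stage-informative sites, and all 8 genes belong to the planted module.
The nested-CV stage classifier separates early from late stage perfectly
on this strongly-signaled cohort (mean outer-fold AUC 1.0).  Every
intermediate artifact (`predicted_ages.tsv`, `shap.tsv`, `complexes.tsv`,
`enrichment.tsv`, `panel.tsv`, `stage_metrics.tsv`) is written, and
`manifest.json` records content hashes per stage; rerunning with
`--resume` skips unchanged stages, and two fresh runs with one seed
produce byte-identical manifests.

Individual phases are also available as subcommands (`train-clock`,
`predict-age`, `compare-subset`, `attribute`, `select-panel`, `train-ddr`,
`compare-baselines`) and as a library API (`methrisk.clock`,
`methrisk.attribution`, `methrisk.netselect`, `methrisk.ddr`).

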