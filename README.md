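# uriexc

Toolkit for predicting whether a protein can be excreted into urine, and
for screening paired tumor/control expression data for candidate urinary
markers.

Components:

- **Feature extraction** — an ordered registry of 243 sequence-derived
  feature values per protein (amino-acid composition, CTD descriptors over
  7 physicochemical partitions, secondary-structure content, fold-index
  disorder, a signal-peptide heuristic, transmembrane/beta-barrel/twin-
  arginine motifs, glycosylation sequons, charge, classic protein
  parameters, and length-normalized sequence statistics). All scores are
  computed offline from shipped coefficient tables; they approximate, and
  do not reproduce, external prediction servers.
- **F-score feature selection** — per-feature class-separation statistic,
  ranking, and threshold filtering.
- **SVM pipeline** — nested training procedure: per-threshold feature
  filtering, repeated stratified half-splits, exhaustive RBF (C, gamma)
  grid search, threshold choice by lowest average validation error, final
  refit. Models serialize to self-contained JSON.
- **Evaluation** — SEN/SP/ACC/MCC from confusion counts, rank-based AUC,
  and the 5-fold antibody-array confirmation rule.
- **Negative-set sampling** — family-proportional draws restricted to
  protein families containing no positive example.
- **Paired DE screen** — per-gene K_exp (count of pairs at >= 2-fold
  change) with a within-pair label-swap permutation p-value.
- **Synthetic data** — seeded generators for two-class protein sets,
  family tables, and paired expression matrices with planted effects.

## CLI

```sh
# synthetic fixtures
uriexc simulate proteins   --seed 4 --out-dir sim/
uriexc simulate families   --seed 4 --out-dir sim/
uriexc simulate expression --seed 4 --out-dir sim/

# feature matrix (243 columns) from FASTA
uriexc extract --fasta sim/proteins.fa --out matrix.tsv

# F-score selection report
uriexc select --matrix matrix.tsv --labels sim/labels.tsv \
              --threshold 0.05 --out selected.json --report-out fscores.tsv

# nested threshold-search training, prediction, evaluation
uriexc train --matrix matrix.tsv --labels sim/labels.tsv --seed 1 --out model.json
uriexc predict --model model.json --fasta sim/proteins.fa --out pred.tsv
uriexc evaluate --pred pred.tsv --truth sim/labels.tsv --out report.json

# family-proportional negative sampling
uriexc sample-negatives --families sim/families.tsv --positives sim/positives.txt \
                        --budget 100 --seed 1 --out negatives.txt

# paired fold-change screen
uriexc de --matrix sim/expression.tsv --fold 2 --alpha 0.05 --seed 1 --out de.tsv

# whole pipeline with provenance checksums
uriexc run --config run.json --out-dir artifacts/
```

All tabular formats are tab-delimited with a header row. Label files map
`protein_id` to `+1`/`-1`. Expression matrices use alternating
`<pair>_tumor` / `<pair>_control` columns.

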