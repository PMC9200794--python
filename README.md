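# seqboost

Binary classification of DNA sequences (e.g. disease-associated vs not)
from FASTA input, built from four pieces:

- **sequence I/O** — FASTA parsing, sanitization (non-ACGT handling),
  `seqkit rmdup`-style deduplication by id or by sequence, gene lists.
- **two feature families**
  - *composition / gapped k-mers* (`seqboost.kgap`): 13 blocks — terminal
    Z-curve coordinates, GC content, AT/GC ratio, GC/AT skews, word
    frequencies for lengths 1–3, and eight gapped-pair families
    (mono/di/tri × mono/di/tri words, gaps 1–5) — 14,891 features total.
  - *spectral descriptors* (`seqboost.mappings`): five numeric encodings
    (binary indicators, integer, real, cumulative Z-curve, EIIP), FFT power
    spectra, and 18 statistics per spectrum (PAPR, SNR, percentiles,
    moments, ...) = 90 fused features.
- **feature selection** (`seqboost.selection`): real-valued (SAMME.R)
  AdaBoost of depth-limited trees; features scored by ensemble-averaged
  impurity decrease, kept by nonzero score or top-k.
- **classifier** (`seqboost.gbdt`): gradient-boosted regression trees on
  the logistic loss written from first principles — half-log-odds init,
  pseudo-residual targets, greedy variance-reduction splits, Newton-solved
  leaf values, shrinkage, `p = sigmoid(2H)` link.

Evaluation (`seqboost.evaluation`) reports ACC / AUC / AUPR / F1 / MCC /
SEN / SPC with stratified k-fold cross-validation; negatives organised in
batches are each paired with the full positive set and the per-batch
reports averaged. `seqboost.synthetic` generates labeled FASTA datasets
with planted gapped patterns, composition shifts and optional period-3
bias so the whole pipeline is testable offline.

## CLI

Each stage is a subcommand reading/writing plain files:

```bash
seqboost simulate --preset protein --seed 7 --out-dir data/
seqboost preprocess --in raw.fasta --out clean.fasta --dedup id
seqboost featurize --in clean.fasta --out X.tsv --family pyfeat
seqboost select --matrix X.tsv --labels labels.json --mask-out mask.json
seqboost train --matrix X.tsv --labels labels.json --mask mask.json --model-out model.json
seqboost evaluate --pos pos.fasta --neg neg0.fasta --neg neg1.fasta --cv 10 --out metrics.json
seqboost rank --model model.json --mask mask.json --in queries.fasta --out ranked.tsv
```

`labels.json` maps record id → 0/1. `evaluate` performs in-fold selection
by default (disable with `--no-selection`).

## Layout

```
src/seqboost/
  io.py          FASTA/gene-list I/O, sanitize, dedup
  mappings.py    numeric encodings, power spectra, spectral descriptors
  kgap.py        composition + gapped k-mer features, canonical schema
  selection.py   SAMME.R importance ranking and masks
  gbdt.py        gradient-boosted trees (logistic loss)
  evaluation.py  metrics, CV, batch averaging
  synthetic.py   labeled dataset generator + label permutation
  pipeline.py    orchestration, config hashing, candidate ranking
  cli.py         click CLI
```
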