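# pretata

A toolkit for predicting TATA-binding proteins (TBPs) — and, more generally,
any narrow protein class — from primary sequence and predicted secondary
structure, using fingerprint features, max-relevance-max-distance (MRMD)
feature ranking, a two-step optimal-dimensionality search, and an RBF-kernel
support-vector machine.

## Who this is for

Computational biologists who need a sequence-only classifier for a protein
family where positives are scarce and the negative universe is huge and
heterogeneous. The toolkit covers the full workflow: feature extraction,
redundancy-aware feature ranking, dimensionality selection by cross-validated
accuracy, negative-training-set construction, and SN/SP/ACC evaluation.

## The method

**Features.** Each protein contributes a 661-dimensional fingerprint:

* **188D** from the primary sequence: the 20 amino-acid composition
  percentages `E_i = 100 · n_i / L`, plus a 21-value
  composition/transition/distribution (CTD) block for each of eight
  physicochemical properties (hydrophobicity, van der Waals volume, polarity,
  polarizability, charge, surface tension, secondary-structure propensity,
  solvent accessibility). Each property partitions the 20 residues into three
  groups; per property the block holds the three group percentages `C_i`,
  the three cross-group adjacent-pair frequencies
  `T_ij = 100 · n_ij / (L−1)`, and for each group the normalized sequence
  positions of its first, 25%, 50%, 75% and last occurrence
  (`D`, quantile positions `P_j = ⌊N·j/4⌋`, 1-based, clamped to ≥ 1).
  20 + 8 × 21 = 188.
* **473D** from the predicted secondary structure, read as a string over
  {H, E, C} (PSIPRED `.ss2`/`.horiz` output or plain FASTA): k-mer
  frequencies for k = 1..5 (363), CTD over the three states (21), 8-bin
  positional composition (24), per-state segment statistics (9), per-state
  segment-length histograms (54), and longest H/E runs (2).

**Ranking.** MRMD scores every feature as
`score_j = |pearson(x_j, y)| + dist_j`, where `dist_j` is the mean
normalized Euclidean distance from feature `j` to all other (min-max scaled)
features — relevance to the label plus resistance to redundancy.

**Dimensionality search.** The classifier (RBF-SVM, `C = 128`,
`gamma = 0.5`) is cross-validated on top-`d` ranked prefixes: a coarse pass
steps `d` down by 20 from the initial dimensionality, then a fine pass scans
±50 around the coarse optimum in steps of 2. The reported model is the
accuracy argmax over both passes (ties favor the smaller `d`).

**Negative sets.** Four strategies balance the training set: random
undersampling; iterative hard-negative refinement (swap in pool negatives the
current model misclassifies until CV accuracy stops improving); a
support-vector "plus" set pooled over repeated draws; and farthest-from-
positive-centroid retention with pool refills.

**Metrics.** SN = 100·TP/(TP+FN), SP = 100·TN/(TN+FP),
ACC = 100·(TP+TN)/total, from pooled stratified k-fold confusion counts.
Min-max scaling is refit inside every fold on the training split only.

## Worked example

Generate a synthetic positive/negative protein set (no downloads needed),
extract the joint 661D features, rank, and search:

```sh
pretata simulate --preset sequences --seed 7 --n-pos 60 --n-neg 60 --out data/
pretata extract --mode 661 --in data/proteins.fasta --ss data/ss.fasta --out features.csv
# attach labels (data/labels.csv has columns id,label), then:
pretata rank   --in labeled.csv --out ranking.tsv
pretata search --in labeled.csv --ranking ranking.tsv \
               --initial 661 --tolerable 30 --primary-step 100 \
               --secondary-step 10 --window 20 --folds 5 --seed 7 --out trace.tsv
pretata eval   --in labeled.csv --folds 5 --seed 7
```

Output:

```
best_dim 41 best_acc 100.0000 best_sn 100.0000 best_sp 100.0000
SN 35.0000 SP 100.0000 ACC 67.5000
```

The contrast is the method's point: cross-validating the SVM on all 661
features yields only 67.5% accuracy (in 661 dimensions the RBF kernel is
dominated by noisy feature-sampling variance), while the searched 41-feature
prefix classifies the same records perfectly. The same pipeline runs
end-to-end from a YAML config:

```sh
pretata run --config config.yaml --out run/
cat run/metrics.json
# {"best_dimension": 41, "SN": 100.0, "SP": 100.0, "ACC": 100.0}
```

`run/manifest.json` records the seed, config hash and per-stage outputs;
re-running with the same config reproduces the metrics byte-for-byte.

## Layout

* `src/pretata/seqio.py` — FASTA / PSIPRED / CSV / TSV / ARFF I/O
* `src/pretata/ctd.py` — 188D composition + CTD fingerprint
* `src/pretata/ss_features.py` — 473D secondary-structure features, 661D join
* `src/pretata/mrmd.py` — MRMD feature ranking
* `src/pretata/dimsearch.py` — two-step dimensionality search
* `src/pretata/sampling.py` — negative-set construction strategies
* `src/pretata/model.py` — RBF-SVM, cross-validation, SN/SP/ACC
* `src/pretata/synthetic.py` — seeded synthetic data generators
* `src/pretata/cli.py` — `pretata` command-line interface and pipeline

See `docs/methods.md` for modelling assumptions, parameter defaults, and
known limitations.
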