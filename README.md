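# plantmeth

Detection of 5-methylcytosine (5mC) in all three plant sequence contexts —
CpG, CHG and CHH (H = A, C or T) — from event-aligned nanopore signal data.

In plants, cytosine methylation in the three contexts regulates distinct
processes (gene-body methylation, transposon silencing), so genome-wide
calling cannot stop at CpG.  Nanopore sequencing reads native DNA, and a
modified base perturbs the pore current of the k-mers that contain it, so
5mC can be read directly from the signal — including in repetitive regions
that short-read bisulfite sequencing cannot map.  `plantmeth` implements a
complete signal-level calling pipeline for researchers who want to train,
evaluate and dissect such a caller at desk scale:

- **Feature extraction.** Per-read signals are median-centered and
  MAD-scaled; for each cytosine the k-mer centered on it (k = 13) yields a
  k×4 sequence-feature matrix (base, mean, standard deviation and count of
  each base's signals) and a k×m signal-feature matrix (m = 16 sampled
  signals per base, zero-padded).
- **Model.** A two-branch bidirectional LSTM: each feature matrix passes
  through a BiLSTM and a fully connected layer; the concatenated outputs
  feed a deeper BiLSTM stack, two fully connected layers and a softmax
  producing P_m and P_um with P_m + P_um = 1.  Training uses Adam on
  cross-entropy with dropout and early stopping on validation accuracy.
  The network and its backpropagation are implemented in numpy.
- **Training-set curation.** High-confidence sites come from bisulfite
  reports (coverage ≥ 5; frequency ≥ 0.9 for positives, 0 in all replicates
  for negatives).  Negatives are balanced against positives per k-mer so
  sequence composition alone cannot separate the classes, and an iterative
  two-fold cross-prediction procedure removes mislabelled positives
  (mean methylation score < 0.5 over R rounds), stopping after I
  iterations or at 99% retention.
- **Calling and aggregation.** A site in a read is methylated iff
  P_m > P_um; per-site frequency = methylated reads / mapped reads;
  coverage-filtered sites bin into low (≤ 0.3), intermediate and high
  (≥ 0.7) classes.
- **Evaluation.** Pearson r, r², Spearman ρ and RMSE against bisulfite
  frequencies (inner join, both sides ≥ 5 reads), plus class-balanced
  read-level accuracy/sensitivity/specificity/AUC.
- **Repeat pairs.** Near-identical interval pairs from a reference
  self-alignment (length ≥ 100, identity ≥ 0.99) are flagged
  differentially methylated when ≥ 10% of position-matched cytosines
  differ in frequency by ≥ 0.5.
- **Synthetic data.** A generator emulating re-squiggled reads (sequence-
  dependent Gaussian currents, methylation-induced mean shift δ around the
  modified base, Poisson signal counts, read-level gain/offset jitter),
  bisulfite tables, and mislabel injection — every experiment here runs
  without downloads.

## Worked example

```
plantmeth simulate --out demo --genome-length 1500 --coverage 8 --read-length 500 --seed 5
plantmeth extract  --reference demo/reference.fa --reads demo/reads.jsonl --out demo/samples.tsv
plantmeth select-sites --report demo/bisulfite.tsv --context CpG --out-prefix demo/hiconf
```

which logs, among other things:

```
INFO plantmeth: wrote 24 reads, 553 truth sites to demo
INFO plantmeth: wrote samples to demo/samples.tsv
INFO plantmeth: wrote 23 methylated sites to demo/hiconf.CpG.methylated.tsv
INFO plantmeth: wrote 61 unmethylated sites to demo/hiconf.CpG.unmethylated.tsv
```

24 simulated event-aligned reads cover 553 cytosine sites; of the CpG
sites, 23 are fully methylated and 61 fully unmethylated at high
confidence in the simulated bisulfite report, and `demo/samples.tsv` holds
one k×4 + k×16 feature-matrix row per (read, site) pair, ready for
`plantmeth train` / `call` / `freq` / `eval` (see `plantmeth --help`).
The same steps are available as library functions; `plantmeth.experiments`
wires them into complete runs.

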