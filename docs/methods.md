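# Methods

## Problem and model

A nanopore read is a time series of current measurements.  After
re-squiggling, each reference base of a mapped read carries a non-empty
group of raw current values.  5mC perturbs the current of the k-mers that
contain the modified cytosine, so the methylation state of one cytosine in
one read is in principle decodable from the signal in a window around it.
`plantmeth` frames this as binary classification of (read, cytosine-site)
pairs, with per-site methylation frequency obtained by counting methylated
calls over mapped reads.

### Signal normalization

Raw currents differ between pores and over time by roughly affine
transformations.  Each read's signals are therefore normalized as
x → (x − median) / MAD, with median and MAD computed over all signal
values of the whole read (not per base, not per run).  The raw MAD is used
without the 1.4826 Gaussian-consistency constant — training and calling
use the same convention, so the constant would cancel anyway.  No outlier
clipping is applied after scaling.  The transform is idempotent and
invariant to positive affine distortions, which is exactly the read-level
nuisance it exists to remove; a constant-signal read (MAD = 0) is an error
naming the read rather than a silent NaN.

### Features

For a cytosine site and a read covering its full k-window (k = 13,
strand-oriented so row order reads 5'→3' on the C-bearing strand, with
minus-strand k-mers reverse-complemented):

- sequence features, k×4: integer base code (A=0, C=1, G=2, T=3), mean,
  population standard deviation (divisor n, fixed once so training and
  calling match), and count of the base's normalized signals;
- signal features, k×m (m = 16): m signals per base.  A base with more
  than m signals is reduced at evenly spaced indices ⌊i·len/m⌋ — a
  deterministic choice that preserves the temporal span, preferred over
  random sampling for reproducibility; fewer than m signals are
  right-padded with zeros.

Sites whose k-mer or two-base context window overruns the contig, or whose
k-mer contains N, are skipped: there is no feature encoding for N and the
context is undefined at the 3' end.

### Network

Two branches: the embedded base code (dimension 4) concatenated with the
three numeric columns feeds a bidirectional LSTM, then a per-timestep
fully connected layer with ReLU; the signal matrix takes the same path in
a second branch.  The per-timestep branch outputs are concatenated and
passed through a stack of bidirectional LSTM layers (default 3 × 256).
The final representation concatenates the forward LSTM's last state and
the backward LSTM's first state, then two fully connected layers and a
softmax over {unmethylated, methylated} give (P_um, P_m) with
P_m + P_um = 1.  `mode` selects the full network or a single branch;
`signal_only` is the variant used inside denoising, where sequence
composition must not influence removal decisions.

The layers (dense, embedding, LSTM, bidirectional LSTM, inverted dropout,
fused softmax cross-entropy) and the Adam optimizer are implemented in
numpy with hand-written backward passes (`plantmeth._layers`), verified
against finite differences in the test suite.  Training is
single-threaded and bit-deterministic given the config seed.

Defaults and their provenance: merged stack depth 3, width 256 and
learning rate 0.001 are the method's stated choices; branch width (256),
branch fully connected width (128), head width (128), dropout 0.5, batch
size 512, embedding dimension 4 are this package's own defaults, all
config-exposed.  Validation metric for model selection and early stopping
is accuracy; training stops as soon as an epoch's validation accuracy
falls below the best seen, after restoring the best parameters.
Training/validation split defaults to 99:1, seed-reproducible.

### Training-set curation

High-confidence sites from bisulfite reports: positives need coverage ≥ 5
and frequency ≥ 0.9 in a replicate, combined across replicates by
intersection for CpG and union for CHG/CHH (positives are scarce outside
CpG); negatives need coverage ≥ 5 with zero frequency and must show zero
methylated reads in every replicate that covers them.

Negative balancing: for each k-mer present in both classes, at most as
many negatives as positives of that k-mer are kept (drawn at random); any
deficit relative to the positive count is filled from k-mers found only
among negatives.  Training subsampling caps each class at half of
`max_samples` (default 20 million); a class smaller than its cap is kept
whole and the other class is still capped, preserving balance rather than
volume.

Denoising: per iteration, R (default 3) rounds of a random two-fold split
(⌊n/2⌋ / ⌈n/2⌉ for odd n); a fresh signal-only model is trained on each
half for E epochs (fixed — no early stopping inside denoising, since the
folds have no validation set) and scores the other half; each positive's
scores are averaged arithmetically over rounds and positives below 0.5
are removed; negatives are rebalanced against the survivors from the
current negative pool (the iteration's own set, a documented reading of
the procedure's ambiguous pseudocode); the loop ends after I (default 10)
iterations or when an iteration retains ≥ 99% of its positives.

### Calling, aggregation, evaluation, repeats

A site in a read is called methylated iff P_m > P_um, i.e. a tie is
unmethylated (strict inequality).  Frequencies are reported per strand,
without CpG strand merging.  Binning (low ≤ 0.3 < intermediate < 0.7 ≤
high) applies after a coverage ≥ 5 filter.  Site-level evaluation joins
nanopore and bisulfite tables on (chrom, pos, strand) with the coverage
filter on both sides; Pearson/Spearman come from scipy, AUC from
scikit-learn's rank-based (midrank-tied) implementation, and all metrics
are cross-checked against closed-form oracles in the tests.  The
bisulfite coverage threshold is a parameter (default 5) because
low-coverage bisulfite datasets warrant 10.

Repeat pairs keep length ≥ 100 and identity ≥ 0.99 (the thresholds are
inclusive and config-exposed) and must contain a cytosine.  Cytosines are
matched by identical offset from each member's start, strand-flipped for
reverse-orientation pairs; matching is gap-free, which identity ≥ 0.99
makes a mild assumption, and a gapped matcher is out of scope.  Both
members need frequency records with coverage ≥ 5 (consistent with
evaluation; the procedure itself does not fix this).  A matched cytosine
is differential at |Δfrequency| ≥ 0.5; a pair is differential per class
(all cytosines, CpG, CHG, CHH independently) at ≥ 10% differential
cytosines of that class, with the flag undefined for empty classes.

## Synthetic data

The generator emulates the *structure* of re-squiggled plant data:

- reference: i.i.d. bases at GC = 0.36;
- truth: each cytosine's frequency drawn from a per-context mixture —
  point masses at 0 and 1 plus a Beta intermediate component — with
  defaults (w₀, w₁) of (0.55, 0.25) for CpG, (0.70, 0.10) for CHG,
  (0.85, 0.04) for CHH, echoing the ordering of methylation levels in
  plant genomes; a degenerate 50/50 mixture (`TRAINING_FREQ_MIX`) models
  the fully-methylated/fully-unmethylated composition of curated training
  sites;
- signal: per-base baseline currents depend on the local trinucleotide
  (one value per trinucleotide from a seeded table, σ = 0.8), so the
  sequence branch has something real to learn; methylation of a molecule
  shifts the mean by δ (default 3σ, σ = 1) within ±2 bases of the C,
  mimicking the k-mer-context footprint of a modification; signal counts
  are Poisson (mean 8, min 1); each read applies a random gain and offset
  that MAD normalization must undo;
- each molecule's state at a site is Bernoulli(frequency), independent
  across sites within a read;
- bisulfite reports: Poisson coverage (mean 30, zero-coverage rows
  emitted), Binomial methylated counts under a symmetric 0.5% conversion
  error;
- mislabel injection replaces a known fraction of the positive set with
  truly unmethylated samples relabelled positive and returns their
  identities for recovery scoring;
- `generate_training_samples` skips the read layer and draws balanced
  two-class per-base Gaussian feature matrices directly — the denoising
  simulation's data model.

What the generator does **not** model: basecalling errors, event
mis-segmentation, dwell-time/sequence coupling, long-range pore drift,
molecule-level co-methylation, realistic k-mer current tables.  Passing
tests therefore demonstrate that the algorithms recover what this signal
model encodes, not field performance on real flow-cell data.

## Experiment scales and numerical choices

The canned experiments (`plantmeth.experiments`) fix desk-scale problem
sizes chosen to run in minutes on one CPU:

- denoising recovery: 20,000 samples, mislabel ratios 10% and 20%,
  signal-only model with hidden width 32, one merged layer, learning rate
  0.003, batch 256, E = 1, R = 3 — one epoch over a ~10k-sample fold
  reaches ~99% fold accuracy on 3σ-separable data, so deeper fold
  training would add runtime, not removals;
- frequency recovery: 8 kb genome, 40× training reads, 20× test reads,
  full model with hidden width 48, two merged layers, up to 10 epochs;
- null control: δ = 0 on a 4 kb genome at 20×, **signal-only** model.
  With site-level labels the sequence branch can learn the k-mer
  composition of training sites — the very shortcut k-mer balancing
  exists to suppress — which would lift AUC above 0.5 for reasons
  unrelated to signal.  The control asks whether the *signal* carries
  methylation information, so it isolates that channel.

Numerical details: probabilities come from a max-shifted softmax; the
forget-gate bias initializes to 1; weights are Glorot-uniform from the
config seed; cross-entropy clips probabilities at 1e-12; ties in calling
go to unmethylated; an exactly balanced split of an odd-sized denoising
set is impossible, so the halves differ by one.

## Known limitations

- The per-read output schema (nine columns including `pos_in_strand`) is
  this package's contract; the original tool's schema is not public in
  the sources used.
- Event-aligned reads use a documented JSON-lines dialect rather than
  FAST5/HDF5; a FAST5 adapter is a non-goal, as are basecalling,
  re-squiggling and self-alignment themselves (their outputs are the
  pipeline's inputs).
- Gap-free repeat-pair matching slightly undercounts matched cytosines
  in pairs whose alignment contains indels.
- The numpy network trains small models quickly but is not suited to
  genome-scale training; the architecture, not throughput, is the point.
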