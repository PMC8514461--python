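"""Synthetic reference, event-aligned reads and bisulfite tables.

The generator emulates the structure of re-squiggled nanopore data well
enough to exercise the whole pipeline without any downloads:

- a random reference with plant-like GC content;
- per-site ground-truth methylation frequencies drawn from a per-context
  mixture (a point mass at 0, a point mass at 1, and a Beta-distributed
  intermediate component), with each sequenced molecule's state Bernoulli
  in the site's frequency;
- per-base current values that are Gaussian around a sequence-dependent
  baseline (one baseline per trinucleotide, drawn once from a seeded
  table), shifted by ``delta`` within ``neighborhood`` bases of a
  methylated cytosine — mimicking how a modified base perturbs pore
  current across the k-mers that contain it;
- per-base signal counts Poisson-distributed (minimum 1), read-level gain
  and offset jitter that the median/MAD normalization must undo;
- bisulfite reports with Poisson coverage and a symmetric conversion-error
  rate;
- mislabel injection for denoising experiments: a known fraction of the
  positive training set is replaced by truly unmethylated samples
  relabelled as methylated.

All outputs are pure functions of (config, seed).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .features import FeatureConfig, SiteSample, extract_all
from .io_formats import BisulfiteSiteRecord
from .motif import reverse_complement, scan_cytosines
from .preprocess import EventAlignedRead, normalize_read

# (weight of frequency 0, weight of frequency 1, Beta a, Beta b) per context;
# the remaining weight is the Beta-distributed intermediate component.
DEFAULT_FREQ_MIX: dict[str, tuple[float, float, float, float]] = {
    "CpG": (0.55, 0.25, 1.0, 1.0),
    "CHG": (0.70, 0.10, 1.0, 1.0),
    "CHH": (0.85, 0.04, 1.0, 2.0),
}

# degenerate mixture used to build training sets: every site fully
# methylated or fully unmethylated, as the high-confidence selection yields
TRAINING_FREQ_MIX: dict[str, tuple[float, float, float, float]] = {
    "CpG": (0.5, 0.5, 1.0, 1.0),
    "CHG": (0.5, 0.5, 1.0, 1.0),
    "CHH": (0.5, 0.5, 1.0, 1.0),
}


@dataclass
class SyntheticConfig:
    genome_length: int = 20_000
    n_contigs: int = 1
    gc_fraction: float = 0.36  # typical plant genome
    k: int = 13
    m: int = 16
    delta: float = 3.0  # methylation-induced mean current shift
    sigma: float = 1.0  # per-sample Gaussian noise, normalized units
    neighborhood: int = 2  # bases around a methylated C whose signal shifts
    signals_per_base_mean: float = 8.0
    read_length: int = 2_000
    coverage: float = 20.0  # total, both strands together
    freq_mix: Mapping[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_FREQ_MIX)
    )
    bisulfite_coverage: float = 30.0
    conversion_error: float = 0.005
    mislabel_ratio: float = 0.0
    raw_scale: float = 12.0  # normalized -> raw current units
    raw_offset: float = 90.0
    raw_scale_jitter: float = 0.5  # per-read gain/offset variation
    raw_offset_jitter: float = 5.0
    seed: int = 1

    def __post_init__(self) -> None:
        if self.delta < 0 or self.sigma <= 0:
            raise ValueError("need delta >= 0 and sigma > 0")
        if self.coverage < 1:
            raise ValueError("coverage must be >= 1")
        if not 0.0 <= self.mislabel_ratio < 1.0:
            raise ValueError("mislabel_ratio must be in [0, 1)")


@dataclass(frozen=True)
class TruthSite:
    frequency: float
    context: str


def generate_reference(cfg: SyntheticConfig, seed: int | None = None) -> dict[str, str]:
    """Random contigs with the configured GC fraction."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    gc = cfg.gc_fraction
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    contigs = {}
    for i in range(cfg.n_contigs):
        length = cfg.genome_length // cfg.n_contigs
        bases = rng.choice(np.array(list("ACGT")), size=length, p=probs)
        contigs[f"contig{i + 1}"] = "".join(bases)
    return contigs


def generate_truth(
    reference: Mapping[str, str], cfg: SyntheticConfig, seed: int | None = None
) -> dict[tuple[str, int, str], TruthSite]:
    """Assign a ground-truth methylation frequency to every cytosine site."""
    rng = np.random.default_rng((cfg.seed if seed is None else seed) + 1)
    truth: dict[tuple[str, int, str], TruthSite] = {}
    for site in scan_cytosines(reference, cfg.k):
        w0, w1, a, b = cfg.freq_mix[site.context]
        u = rng.random()
        if u < w0:
            freq = 0.0
        elif u < w0 + w1:
            freq = 1.0
        else:
            freq = float(rng.beta(a, b))
        truth[site.key] = TruthSite(frequency=freq, context=site.context)
    return truth


def _kmer_mean_table(seed: int) -> dict[str, float]:
    """Baseline current level per trinucleotide, drawn once from a seeded table."""
    rng = np.random.default_rng([seed, 0x3A5])
    table = {}
    for trio in itertools.product("ACGT", repeat=3):
        table["".join(trio)] = float(rng.normal(0.0, 0.8))
    return table


def generate_event_reads(
    reference: Mapping[str, str],
    truth: Mapping[tuple[str, int, str], TruthSite],
    cfg: SyntheticConfig,
    seed: int | None = None,
) -> tuple[list[EventAlignedRead], dict[tuple[str, str, int, str], int]]:
    """Simulate event-aligned reads tiling the genome on both strands.

    Returns the reads (raw, un-normalized current units) and the per-read
    molecule states: (read_id, chrom, pos, strand) -> 0/1 for every truth
    site on the read's strand that the read covers.
    """
    base_seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(base_seed + 2)
    means = _kmer_mean_table(base_seed)
    reads: list[EventAlignedRead] = []
    states: dict[tuple[str, str, int, str], int] = {}
    by_chrom_strand: dict[tuple[str, str], list[tuple[int, TruthSite]]] = {}
    for (chrom, pos, strand), site in truth.items():
        by_chrom_strand.setdefault((chrom, strand), []).append((pos, site))
    for group in by_chrom_strand.values():
        group.sort()

    read_no = 0
    for chrom, seq in reference.items():
        glen = len(seq)
        rlen = min(cfg.read_length, glen)
        n_per_strand = max(1, int(np.ceil(cfg.coverage * glen / (2 * rlen))))
        for strand in "+-":
            # evenly spaced starts with jitter, clipped to the contig
            starts = np.linspace(0, glen - rlen, n_per_strand)
            starts = starts + rng.integers(-rlen // 4, rlen // 4 + 1, size=n_per_strand)
            starts = np.clip(starts, 0, glen - rlen).astype(int)
            sites = by_chrom_strand.get((chrom, strand), [])
            positions = np.array([p for p, _ in sites], dtype=int)
            for start in starts:
                read_no += 1
                read_id = f"read{read_no:06d}"
                end = start + rlen
                shift = np.zeros(rlen)
                lo = np.searchsorted(positions, start)
                hi = np.searchsorted(positions, end)
                for pos, site in sites[lo:hi]:
                    state = int(rng.random() < site.frequency)
                    states[(read_id, chrom, pos, strand)] = state
                    if state:
                        a = max(start, pos - cfg.neighborhood)
                        b = min(end, pos + cfg.neighborhood + 1)
                        shift[a - start : b - start] += cfg.delta * cfg.sigma
                gain = max(0.1, rng.normal(cfg.raw_scale, cfg.raw_scale_jitter))
                offset = rng.normal(cfg.raw_offset, cfg.raw_offset_jitter)
                counts = np.maximum(1, rng.poisson(cfg.signals_per_base_mean, size=rlen))
                signals = []
                for i in range(rlen):
                    pos = start + i
                    if strand == "+":
                        trio = seq[max(0, pos - 1) : pos + 2]
                    else:
                        trio = reverse_complement(seq[max(0, pos - 1) : pos + 2])
                    mu = means.get(trio, 0.0) + shift[i]
                    vals = rng.normal(mu, cfg.sigma, size=counts[i])
                    signals.append((vals * gain + offset).tolist())
                reads.append(
                    EventAlignedRead(
                        read_id=read_id,
                        chrom=chrom,
                        strand=strand,
                        start=int(start),
                        bases=seq[start:end],
                        signals=signals,
                    )
                )
    return reads, states


def generate_bisulfite_table(
    truth: Mapping[tuple[str, int, str], TruthSite],
    reference: Mapping[str, str],
    cfg: SyntheticConfig,
    seed: int | None = None,
) -> list[BisulfiteSiteRecord]:
    """Simulate a bisulfite cytosine report from the ground truth.

    Coverage is Poisson (zero-coverage sites are emitted, not dropped); the
    methylated-read count is Binomial in the frequency distorted by the
    symmetric conversion-error rate.
    """
    rng = np.random.default_rng((cfg.seed if seed is None else seed) + 3)
    records = []
    e = cfg.conversion_error
    for (chrom, pos, strand), site in sorted(truth.items()):
        cov = int(rng.poisson(cfg.bisulfite_coverage))
        p = site.frequency * (1 - e) + (1 - site.frequency) * e
        n_meth = int(rng.binomial(cov, p)) if cov > 0 else 0
        seq = reference[chrom]
        if strand == "+":
            trinuc = seq[pos : pos + 3]
        else:
            trinuc = reverse_complement(seq[max(0, pos - 2) : pos + 1])
        records.append(
            BisulfiteSiteRecord(
                chrom=chrom,
                pos=pos,
                strand=strand,
                count_methylated=n_meth,
                count_unmethylated=cov - n_meth,
                context=site.context,
                trinucleotide=trinuc if len(trinuc) == 3 else "NNN",
            )
        )
    return records


def inject_mislabels(
    samples: Sequence[SiteSample], ratio: float, seed: int = 0
) -> tuple[list[SiteSample], set[tuple[str, str, int, str]]]:
    """Replace a fraction of the positives with relabelled negatives.

    ``ratio`` is the fraction of the returned positive set that is falsely
    labelled.  n = round(ratio * |positives|) genuine positives are removed
    and n randomly chosen negatives are relabelled as positive (and leave
    the negative set), keeping the positive count unchanged.  Returns the
    corrupted sample list and the injected samples' uids.
    """
    if not 0.0 <= ratio < 1.0:
        raise ValueError(f"ratio must be in [0, 1), got {ratio}")
    pos = [s for s in samples if s.label == 1]
    neg = [s for s in samples if s.label == 0]
    n_inject = int(round(ratio * len(pos)))
    if n_inject == 0:
        return list(samples), set()
    if n_inject > len(neg):
        raise ValueError(f"not enough negatives ({len(neg)}) to inject {n_inject} mislabels")
    rng = np.random.default_rng(seed)
    drop_pos = set(rng.choice(len(pos), size=n_inject, replace=False).tolist())
    flip_neg = set(rng.choice(len(neg), size=n_inject, replace=False).tolist())
    out: list[SiteSample] = [s for i, s in enumerate(pos) if i not in drop_pos]
    injected: set[tuple[str, str, int, str]] = set()
    for i, s in enumerate(neg):
        if i in flip_neg:
            flipped = SiteSample(
                chrom=s.chrom,
                pos=s.pos,
                strand=s.strand,
                read_id=s.read_id,
                kmer=s.kmer,
                seq_features=s.seq_features,
                signal_features=s.signal_features,
                label=1,
            )
            out.append(flipped)
            injected.add(flipped.uid)
        else:
            out.append(s)
    return out, injected


def generate_training_samples(
    cfg: SyntheticConfig, n_samples: int, seed: int | None = None
) -> list[SiteSample]:
    """Directly generate a balanced two-class labelled sample set.

    Each sample is a random k-mer with a central C; per base the signal
    count is Poisson (minimum 1) and the values are Gaussian around the
    base's trinucleotide baseline, with the central ``neighborhood`` rows of
    methylated samples shifted by ``delta * sigma``.  This is the per-base
    two-class Gaussian signal model used for denoising simulations; reads
    and genome coordinates are synthesized only as identifiers.
    """
    base_seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(base_seed + 4)
    means = _kmer_mean_table(base_seed)
    center = cfg.k // 2
    bases = np.array(list("ACGT"))
    samples: list[SiteSample] = []
    for i in range(n_samples):
        label = int(i % 2 == 0)
        kmer_arr = rng.choice(bases, size=cfg.k)
        kmer_arr[center] = "C"
        kmer = "".join(kmer_arr)
        seq_features = np.zeros((cfg.k, 4))
        signal_features = np.zeros((cfg.k, cfg.m))
        for row in range(cfg.k):
            trio = kmer[max(0, row - 1) : row + 2]
            mu = means.get(trio, 0.0)
            if label and abs(row - center) <= cfg.neighborhood:
                mu += cfg.delta * cfg.sigma
            count = max(1, int(rng.poisson(cfg.signals_per_base_mean)))
            vals = rng.normal(mu, cfg.sigma, size=count)
            from .features import BASE_CODES, sample_signals

            seq_features[row] = (BASE_CODES[kmer[row]], vals.mean(), vals.std(), count)
            signal_features[row] = sample_signals(vals, cfg.m)
        samples.append(
            SiteSample(
                chrom="simC",
                pos=i,
                strand="+",
                read_id=f"simread{i:07d}",
                kmer=kmer,
                seq_features=seq_features,
                signal_features=signal_features,
                label=label,
            )
        )
    return samples


def make_labelled_samples(
    cfg: SyntheticConfig, seed: int | None = None
) -> tuple[list[SiteSample], dict]:
    """End-to-end helper: simulate, normalize, extract labelled samples.

    Labels are the per-molecule truth states, i.e. exactly what a
    high-confidence training-site selection would yield when the frequency
    mixture is degenerate (every site fully methylated or unmethylated).
    Returns the samples plus the simulation artifacts (reference, truth,
    reads, states) for downstream checks.
    """
    base_seed = cfg.seed if seed is None else seed
    reference = generate_reference(cfg, base_seed)
    truth = generate_truth(reference, cfg, base_seed)
    reads, states = generate_event_reads(reference, truth, cfg, base_seed)
    normalized = [normalize_read(r) for r in reads]
    sites = list(scan_cytosines(reference, cfg.k))
    fcfg = FeatureConfig(k=cfg.k, m=cfg.m)
    samples = []
    for sample in extract_all(normalized, sites, fcfg):
        state = states.get(sample.uid)
        if state is not None:
            sample.label = state
            samples.append(sample)
    artifacts = {
        "reference": reference,
        "truth": truth,
        "reads": normalized,
        "raw_reads": reads,
        "states": states,
        "sites": sites,
    }
    return samples, artifacts
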