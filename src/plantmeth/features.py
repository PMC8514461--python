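"""Feature matrices for a cytosine site in one read.

For each targeted cytosine, the k-mer centered on it yields two matrices:

- sequence features, k x 4: per base the nucleotide code (A=0, C=1, G=2,
  T=3), the mean and standard deviation of its normalized signal values, and
  the signal count;
- signal features, k x m: m normalized signal values sampled per base, with
  zero padding on the right when a base has fewer than m signals.

Rows follow the 5'->3' order of the site's own strand, so minus-strand
samples present the reverse-complemented k-mer with base-reversed signal
rows and the model always sees the C-bearing strand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

from .motif import CytosineSite
from .preprocess import EventAlignedRead

logger = logging.getLogger(__name__)

BASE_CODES = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass(frozen=True)
class FeatureConfig:
    """k-mer length and signals-per-base for feature extraction."""

    k: int = 13
    m: int = 16

    def __post_init__(self) -> None:
        if self.k < 3 or self.k % 2 == 0:
            raise ValueError(f"k must be an odd integer >= 3, got {self.k}")
        if self.m < 1:
            raise ValueError(f"m must be >= 1, got {self.m}")


@dataclass
class SiteSample:
    """Feature matrices for one cytosine in one read, optionally labelled."""

    chrom: str
    pos: int
    strand: str
    read_id: str
    kmer: str
    seq_features: np.ndarray  # (k, 4): base code, mean, std, count
    signal_features: np.ndarray  # (k, m)
    label: int | None = None

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chrom, self.pos, self.strand)

    @property
    def uid(self) -> tuple[str, str, int, str]:
        """Identity of the (read, site) pair this sample was extracted from."""
        return (self.read_id, self.chrom, self.pos, self.strand)


def sample_signals(signals: Sequence[float], m: int) -> np.ndarray:
    """Reduce or pad a base's signal list to exactly m values.

    More than m signals: take values at the evenly spaced indices
    floor(i * len / m) for i = 0..m-1.  Fewer than m: right-pad with zeros.
    """
    n = len(signals)
    if n == 0:
        raise ValueError("cannot sample from an empty signal list")
    arr = np.asarray(signals, dtype=np.float64)
    if n == m:
        return arr.copy()
    if n > m:
        idx = (np.arange(m) * n) // m
        return arr[idx]
    out = np.zeros(m, dtype=np.float64)
    out[:n] = arr
    return out


def extract_site_sample(
    read: EventAlignedRead,
    site: CytosineSite,
    cfg: FeatureConfig = FeatureConfig(),
    label: int | None = None,
) -> SiteSample:
    """Build the k x 4 and k x m matrices for ``site`` from ``read``.

    The read must cover the full k-window of the site; signal statistics use
    the population standard deviation (divisor n).
    """
    flank = cfg.k // 2
    lo, hi = site.pos - flank, site.pos + flank + 1
    if read.chrom != site.chrom or lo < read.start or hi > read.end:
        raise ValueError(
            f"read {read.read_id} ({read.chrom}:{read.start}-{read.end}) does not cover "
            f"the k-window {site.chrom}:{lo}-{hi}"
        )
    # Forward-axis order first, then flip for minus-strand sites.
    offsets = range(lo - read.start, hi - read.start)
    per_base = [read.signals[i] for i in offsets]
    if site.strand == "-":
        per_base = per_base[::-1]

    seq_features = np.zeros((cfg.k, 4), dtype=np.float64)
    signal_features = np.zeros((cfg.k, cfg.m), dtype=np.float64)
    for row, (base, sigs) in enumerate(zip(site.kmer, per_base)):
        arr = np.asarray(sigs, dtype=np.float64)
        seq_features[row, 0] = BASE_CODES[base]
        seq_features[row, 1] = arr.mean()
        seq_features[row, 2] = arr.std()  # population std
        seq_features[row, 3] = arr.size
        signal_features[row] = sample_signals(arr, cfg.m)
    return SiteSample(
        chrom=site.chrom,
        pos=site.pos,
        strand=site.strand,
        read_id=read.read_id,
        kmer=site.kmer,
        seq_features=seq_features,
        signal_features=signal_features,
        label=label,
    )


def extract_all(
    reads: Iterable[EventAlignedRead],
    sites: Sequence[CytosineSite],
    cfg: FeatureConfig = FeatureConfig(),
    labels: Mapping[tuple[str, int, str], int] | None = None,
) -> Iterator[SiteSample]:
    """Emit one sample per (read, covered site) pair, in deterministic order.

    Sites are matched to reads of the same chromosome and strand.  Sites whose
    k-window is only partially covered by a read are skipped (and logged), not
    fatal.  When ``labels`` is given, only labelled sites are extracted and
    samples carry their label.
    """
    flank = cfg.k // 2
    by_chrom_strand: dict[tuple[str, str], list[CytosineSite]] = {}
    for site in sites:
        if labels is not None and site.key not in labels:
            continue
        by_chrom_strand.setdefault((site.chrom, site.strand), []).append(site)
    for group in by_chrom_strand.values():
        group.sort(key=lambda s: s.pos)

    n_skipped = 0
    for read in reads:
        group = by_chrom_strand.get((read.chrom, read.strand), ())
        for site in group:
            if site.pos < read.start or site.pos >= read.end:
                continue
            if site.pos - flank < read.start or site.pos + flank + 1 > read.end:
                n_skipped += 1
                continue
            label = labels[site.key] if labels is not None else None
            yield extract_site_sample(read, site, cfg, label=label)
    if n_skipped:
        logger.info("extract_all: skipped %d (read, site) pairs lacking full k-windows", n_skipped)


# ---------------------------------------------------------------------------
# Optional flat TSV dump of samples, for inspection and CLI hand-off.

SAMPLE_HEADER = "chrom\tpos\tstrand\tread_id\tkmer\tlabel\tseq_features\tsignal_features"


def write_samples(path, samples: Iterable[SiteSample]) -> None:
    """One row per sample; matrices flattened row-major, comma-separated."""
    with open(path, "w") as handle:
        handle.write(SAMPLE_HEADER + "\n")
        for s in samples:
            seq = ",".join(f"{v:.6g}" for v in s.seq_features.ravel())
            sig = ",".join(f"{v:.6g}" for v in s.signal_features.ravel())
            label = "." if s.label is None else str(s.label)
            handle.write(
                f"{s.chrom}\t{s.pos}\t{s.strand}\t{s.read_id}\t{s.kmer}\t{label}\t{seq}\t{sig}\n"
            )


def read_samples(path) -> list[SiteSample]:
    samples = []
    with open(path) as handle:
        header = handle.readline().rstrip("\n")
        if header != SAMPLE_HEADER:
            raise ValueError(f"{path}: unexpected sample-dump header")
        for line in handle:
            chrom, pos, strand, read_id, kmer, label, seq, sig = line.rstrip("\n").split("\t")
            k = len(kmer)
            seq_features = np.array(seq.split(","), dtype=np.float64).reshape(k, 4)
            signal_features = np.array(sig.split(","), dtype=np.float64).reshape(k, -1)
            samples.append(
                SiteSample(
                    chrom=chrom,
                    pos=int(pos),
                    strand=strand,
                    read_id=read_id,
                    kmer=kmer,
                    seq_features=seq_features,
                    signal_features=signal_features,
                    label=None if label == "." else int(label),
                )
            )
    return samples
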