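"""Per-read methylation calls, per-site frequency aggregation, and binning.

A site in a read is called methylated when P_m > P_um (strictly; a tie is
called unmethylated).  Site methylation frequency is the number of reads
called methylated divided by the number of reads mapped to the site.  For
comparison with bisulfite data, coverage-filtered sites are binned into
low (frequency <= 0.3), high (>= 0.7) and intermediate (strictly between)
classes.  Frequencies are reported per strand; no CpG strand merging.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .features import SiteSample
from .model import MethylationNet, predict
from .motif import classify_context

BINS = ("low", "intermediate", "high")


@dataclass(frozen=True)
class CallRecord:
    chrom: str
    pos: int
    strand: str
    read_id: str
    p_methylated: float
    p_unmethylated: float
    call: int
    kmer: str
    pos_in_strand: int = -1

    def __post_init__(self) -> None:
        expected = 1 if self.p_methylated > self.p_unmethylated else 0
        if self.call != expected:
            raise ValueError(
                f"call {self.call} inconsistent with P_m={self.p_methylated}, "
                f"P_um={self.p_unmethylated}"
            )


@dataclass(frozen=True)
class SiteFrequency:
    chrom: str
    pos: int
    strand: str
    context: str
    coverage: int
    n_methylated: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_methylated <= self.coverage:
            raise ValueError(f"n_methylated {self.n_methylated} outside [0, {self.coverage}]")

    @property
    def frequency(self) -> float:
        return self.n_methylated / self.coverage

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chrom, self.pos, self.strand)


def kmer_context(kmer: str) -> str:
    """Context of the central cytosine of a strand-oriented k-mer."""
    center = len(kmer) // 2
    ctx = classify_context(kmer[center + 1 : center + 3])
    return ctx if ctx is not None else "CHH"


def call_reads(
    model: MethylationNet,
    samples: Sequence[SiteSample],
    contig_lengths: Mapping[str, int] | None = None,
) -> list[CallRecord]:
    """One call per sample, in input order.

    ``pos_in_strand`` is the coordinate on the site's own strand when contig
    lengths are known (minus strand: L - 1 - pos), else -1.
    """
    predictions = predict(model, samples)
    records = []
    for s, p in zip(samples, predictions):
        if contig_lengths is not None and s.chrom in contig_lengths:
            pos_in_strand = s.pos if s.strand == "+" else contig_lengths[s.chrom] - 1 - s.pos
        else:
            pos_in_strand = -1
        records.append(
            CallRecord(
                chrom=s.chrom,
                pos=s.pos,
                strand=s.strand,
                read_id=s.read_id,
                p_methylated=p.p_methylated,
                p_unmethylated=p.p_unmethylated,
                call=1 if p.p_methylated > p.p_unmethylated else 0,
                kmer=s.kmer,
                pos_in_strand=pos_in_strand,
            )
        )
    return records


def aggregate_frequencies(
    records: Iterable[CallRecord], contexts: Sequence[str] | None = None
) -> list[SiteFrequency]:
    """Per-site coverage, methylated-read count and frequency.

    Sites are keyed by (chrom, pos, strand); the context is derived from the
    record's k-mer.  The output is sorted by site key; ``contexts`` limits
    the output to the given context classes.
    """
    grouped: dict[tuple[str, int, str], list[CallRecord]] = {}
    for rec in records:
        grouped.setdefault((rec.chrom, rec.pos, rec.strand), []).append(rec)
    freqs = []
    for (chrom, pos, strand), group in sorted(grouped.items()):
        context = kmer_context(group[0].kmer)
        if contexts is not None and context not in contexts:
            continue
        n_meth = sum(rec.call for rec in group)
        freqs.append(
            SiteFrequency(
                chrom=chrom,
                pos=pos,
                strand=strand,
                context=context,
                coverage=len(group),
                n_methylated=n_meth,
            )
        )
    return freqs


def bin_sites(
    freqs: Iterable[SiteFrequency], min_coverage: int = 5
) -> dict[str, list[SiteFrequency]]:
    """Partition coverage-filtered sites into low / intermediate / high bins.

    low: frequency <= 0.3; high: frequency >= 0.7; intermediate: strictly
    between.  Sites below ``min_coverage`` are excluded from every bin.
    """
    bins: dict[str, list[SiteFrequency]] = {name: [] for name in BINS}
    for f in freqs:
        if f.coverage < min_coverage:
            continue
        if f.frequency <= 0.3:
            bins["low"].append(f)
        elif f.frequency >= 0.7:
            bins["high"].append(f)
        else:
            bins["intermediate"].append(f)
    return bins
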