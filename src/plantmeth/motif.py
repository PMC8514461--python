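"""Enumeration of cytosine sites and their CpG/CHG/CHH context.

In plants cytosine methylation occurs in three sequence contexts defined by
the two bases 3' of the C on its own strand: CpG (CG), CHG, and CHH, where
H is A, C, or T.  Both strands of the reference are scanned; a G on the
forward strand hosts a C on the reverse strand.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Mapping

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass(frozen=True)
class CytosineSite:
    """A single cytosine on one strand of the reference.

    ``pos`` is the forward-axis coordinate of the C (for minus-strand sites
    this is the position of the G on the forward strand).  ``kmer`` is
    strand-oriented (5'->3' on the C's strand) with the C at its center.
    """

    chrom: str
    pos: int
    strand: str
    context: str
    kmer: str

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chrom, self.pos, self.strand)


def classify_context(downstream: str) -> str | None:
    """Context from the two strand-downstream bases; None if undefined (N)."""
    if len(downstream) != 2 or "N" in downstream:
        return None
    if downstream[0] == "G":
        return "CpG"
    if downstream[1] == "G":
        return "CHG"
    return "CHH"


def site_context(seq: str, pos: int, strand: str) -> str | None:
    """Context of the cytosine at forward-axis ``pos`` on ``strand``.

    Returns None when the position does not carry a C on that strand or the
    two downstream bases run off the contig or contain N.
    """
    if strand == "+":
        if pos < 0 or pos >= len(seq) or seq[pos] != "C":
            return None
        if pos + 2 >= len(seq):
            return None
        return classify_context(seq[pos + 1 : pos + 3])
    if pos < 0 or pos >= len(seq) or seq[pos] != "G":
        return None
    if pos - 2 < 0:
        return None
    return classify_context(reverse_complement(seq[pos - 2 : pos]))


def scan_cytosines(reference: Mapping[str, str], k: int) -> Iterator[CytosineSite]:
    """Emit every cytosine on either strand with full k-mer and context windows.

    ``k`` must be odd and >= 3.  Sites whose k-mer window or 2-base context
    window overruns the contig, or whose k-mer contains N, are skipped.
    Minus-strand k-mers are reverse-complemented so their center reads C.
    """
    if k % 2 == 0 or k < 3:
        raise ValueError(f"k must be an odd integer >= 3, got {k}")
    flank = k // 2
    for chrom in reference:
        seq = reference[chrom]
        n = len(seq)
        for pos in range(n):
            base = seq[pos]
            if base == "C":
                strand = "+"
            elif base == "G":
                strand = "-"
            else:
                continue
            context = site_context(seq, pos, strand)
            if context is None:
                continue
            lo, hi = pos - flank, pos + flank + 1
            if lo < 0 or hi > n:
                continue
            kmer = seq[lo:hi]
            if "N" in kmer:
                continue
            if strand == "-":
                kmer = reverse_complement(kmer)
            yield CytosineSite(chrom=chrom, pos=pos, strand=strand, context=context, kmer=kmer)
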