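"""Differential methylation between members of repeat pairs.

Repeat pairs are near-identical intervals from a self-alignment of the
reference (length >= 100 bp, identity >= 0.99 by default).  Cytosines are
matched between the two members by identical offset from each region's
start (strand-flipped for reverse-orientation pairs; offset matching is
gap-free, which the high identity threshold justifies).  A matched cytosine
is differentially methylated when the absolute frequency difference is at
least 0.5, and a pair is differentially methylated — for all cytosines or
per context class independently — when at least 10% of its matched
cytosines of that class are differential.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .calling import SiteFrequency
from .io_formats import RepeatPair
from .motif import site_context

CLASSES = ("allC", "CpG", "CHG", "CHH")


@dataclass
class MatchedCytosine:
    offset: int
    strand_a: str
    freq_a: float
    freq_b: float
    context: str


@dataclass
class PairMethylationProfile:
    pair: RepeatPair
    matched: list[MatchedCytosine] = field(default_factory=list)
    n_matched: dict[str, int] = field(default_factory=dict)
    n_differential: dict[str, int] = field(default_factory=dict)
    # True / False per class; None when the class has no matched cytosines
    differential: dict[str, bool | None] = field(default_factory=dict)


def _region_has_cytosine(region: tuple[str, int, int], reference: Mapping[str, str]) -> bool:
    chrom, start, end = region
    seq = reference.get(chrom)
    if seq is None:
        return False
    window = seq[start:end]
    return "C" in window or "G" in window


def filter_pairs(
    pairs: Sequence[RepeatPair],
    min_length: int = 100,
    min_identity: float = 0.99,
    reference: Mapping[str, str] | None = None,
) -> list[RepeatPair]:
    """Keep pairs meeting the length and identity thresholds (inclusive).

    When a reference is supplied, pairs without a single cytosine on either
    strand of either member are dropped as well.
    """
    kept = []
    for pair in pairs:
        if pair.length < min_length or pair.identity < min_identity:
            continue
        if reference is not None and not (
            _region_has_cytosine(pair.region_a, reference)
            or _region_has_cytosine(pair.region_b, reference)
        ):
            continue
        kept.append(pair)
    return kept


def match_cytosines(
    pair: RepeatPair,
    frequencies: Mapping[tuple[str, int, str], SiteFrequency],
    reference: Mapping[str, str],
    min_coverage: int = 5,
) -> PairMethylationProfile:
    """Pair cytosines of the two members by identical relative position.

    An offset is matched when both members carry a cytosine (same strand
    after orientation) there and both have a frequency with at least
    ``min_coverage`` mapped reads.  The reported context is member A's.
    """
    chrom_a, start_a, end_a = pair.region_a
    chrom_b, start_b, end_b = pair.region_b
    span = min(end_a - start_a, end_b - start_b)
    seq_a = reference[chrom_a]
    profile = PairMethylationProfile(pair=pair)
    for offset in range(span):
        pos_a = start_a + offset
        if pair.reverse:
            pos_b = end_b - 1 - offset
        else:
            pos_b = start_b + offset
        for strand_a in "+-":
            context = site_context(seq_a, pos_a, strand_a)
            if context is None:
                continue
            if pair.reverse:
                strand_b = "-" if strand_a == "+" else "+"
            else:
                strand_b = strand_a
            if site_context(reference[chrom_b], pos_b, strand_b) is None:
                continue
            fa = frequencies.get((chrom_a, pos_a, strand_a))
            fb = frequencies.get((chrom_b, pos_b, strand_b))
            if fa is None or fb is None:
                continue
            if fa.coverage < min_coverage or fb.coverage < min_coverage:
                continue
            profile.matched.append(
                MatchedCytosine(
                    offset=offset,
                    strand_a=strand_a,
                    freq_a=fa.frequency,
                    freq_b=fb.frequency,
                    context=context,
                )
            )
    return profile


def classify_pair(
    profile: PairMethylationProfile,
    diff_threshold: float = 0.5,
    fraction_threshold: float = 0.10,
) -> PairMethylationProfile:
    """Set per-class matched/differential counts and differential flags.

    A class with zero matched cytosines gets flag ``None`` (undefined).
    """
    for cls in CLASSES:
        members = (
            profile.matched
            if cls == "allC"
            else [m for m in profile.matched if m.context == cls]
        )
        n = len(members)
        n_diff = sum(1 for m in members if abs(m.freq_a - m.freq_b) >= diff_threshold)
        profile.n_matched[cls] = n
        profile.n_differential[cls] = n_diff
        profile.differential[cls] = None if n == 0 else (n_diff / n >= fraction_threshold)
    return profile


def write_pair_report(path, profiles: Sequence[PairMethylationProfile]) -> None:
    """TSV pair report: coordinates, per-class matched/differential counts, flags."""
    header = ["chrom_a", "start_a", "end_a", "chrom_b", "start_b", "end_b", "length", "identity", "reverse"]
    for cls in CLASSES:
        header += [f"n_{cls}", f"ndiff_{cls}", f"differential_{cls}"]
    with open(path, "w") as handle:
        handle.write("\t".join(header) + "\n")
        for p in profiles:
            ca, sa, ea = p.pair.region_a
            cb, sb, eb = p.pair.region_b
            row = [ca, sa, ea, cb, sb, eb, p.pair.length, f"{p.pair.identity:.4f}", int(p.pair.reverse)]
            for cls in CLASSES:
                flag = p.differential.get(cls)
                row += [
                    p.n_matched.get(cls, 0),
                    p.n_differential.get(cls, 0),
                    "NA" if flag is None else int(flag),
                ]
            handle.write("\t".join(str(v) for v in row) + "\n")
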