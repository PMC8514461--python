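"""Readers and writers for every external format the pipeline touches.

All coordinates are 0-based half-open internally.  Formats that are
conventionally 1-based (the bisulfite cytosine report, self-alignment
coordinate tables) are converted at the serialization boundary and nowhere
else.

Dialects
--------
- Reference genome: FASTA (via Biopython).
- Bisulfite cytosine report (one row per covered cytosine, 1-based)::

    chrom  pos  strand  count_meth  count_unmeth  context  trinucleotide

- Event-aligned reads: JSON lines, one read per line::

    {"read_id": ..., "chrom": ..., "strand": "+", "start": 100, "end": 120,
     "bases": "ACGT...", "signals": [[...], [...], ...]}

  where ``bases`` are the forward-reference bases of the covered interval and
  ``signals[i]`` is the non-empty list of current values assigned to base
  ``start + i``.
- Per-read methylation calls (0-based)::

    chrom  pos  strand  pos_in_strand  read_id  prob_unmeth  prob_meth  call  kmer

- Per-site methylation frequencies (0-based)::

    chrom  pos  strand  context  coverage  n_meth  frequency

- Repeat-pair coordinates (1-based inclusive, identity in percent)::

    start_a  end_a  start_b  end_b  len_a  len_b  identity  chrom_a  chrom_b
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .preprocess import EventAlignedRead

CONTEXTS = ("CpG", "CHG", "CHH")

_CONTEXT_ALIASES = {
    "CPG": "CpG",
    "CG": "CpG",
    "CHG": "CHG",
    "CHH": "CHH",
}


class FormatError(ValueError):
    """Raised when an input file violates its declared dialect."""


@dataclass(frozen=True)
class BisulfiteSiteRecord:
    """One cytosine from a bisulfite cytosine report.

    ``pos`` is the 0-based coordinate of the C on the forward reference axis;
    ``strand`` is the strand carrying the C.
    """

    chrom: str
    pos: int
    strand: str
    count_methylated: int
    count_unmethylated: int
    context: str
    trinucleotide: str = "NNN"

    @property
    def coverage(self) -> int:
        return self.count_methylated + self.count_unmethylated

    @property
    def frequency(self) -> float | None:
        """Methylated-read fraction; ``None`` when the site has no coverage."""
        if self.coverage == 0:
            return None
        return self.count_methylated / self.coverage


@dataclass(frozen=True)
class RepeatPair:
    """Two near-identical genomic intervals from a reference self-alignment.

    Regions are (chrom, start, end), 0-based half-open, start < end.
    ``reverse`` marks pairs whose members align in opposite orientation.
    """

    region_a: tuple[str, int, int]
    region_b: tuple[str, int, int]
    length: int
    identity: float
    reverse: bool = False

    def __post_init__(self) -> None:
        for chrom, start, end in (self.region_a, self.region_b):
            if end <= start:
                raise ValueError(f"empty region {chrom}:{start}-{end}")
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError(f"identity {self.identity} outside [0, 1]")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into a contig-name -> uppercase-sequence mapping."""
    path = Path(path)
    contigs: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        contigs[record.id] = str(record.seq).upper()
    if not contigs:
        raise FormatError(f"{path}: no FASTA records found")
    for name, seq in contigs.items():
        bad = set(seq) - set("ACGTN")
        if bad:
            raise FormatError(f"{path}: contig {name} contains non-ACGTN characters {sorted(bad)}")
    return contigs


def write_fasta(path: str | Path, contigs: dict[str, str], width: int = 70) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in contigs.items()]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# Bisulfite cytosine report


def read_bisulfite_report(path: str | Path) -> list[BisulfiteSiteRecord]:
    """Parse a bisulfite cytosine report into records with 0-based positions.

    Coverage-0 rows are retained: parsing does not filter.
    """
    records: list[BisulfiteSiteRecord] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 7:
                raise FormatError(f"{path}:{lineno}: expected 7 columns, got {len(fields)}")
            chrom, pos_s, strand, n_meth_s, n_unmeth_s, context_s, trinuc = fields
            if strand not in "+-":
                raise FormatError(f"{path}:{lineno}: unknown strand {strand!r}")
            try:
                pos = int(pos_s)
                n_meth = int(n_meth_s)
                n_unmeth = int(n_unmeth_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer field ({exc})") from None
            if pos < 1 or n_meth < 0 or n_unmeth < 0:
                raise FormatError(f"{path}:{lineno}: negative count or position")
            context = _CONTEXT_ALIASES.get(context_s.upper())
            if context is None:
                raise FormatError(f"{path}:{lineno}: unknown context {context_s!r}")
            records.append(
                BisulfiteSiteRecord(
                    chrom=chrom,
                    pos=pos - 1,
                    strand=strand,
                    count_methylated=n_meth,
                    count_unmethylated=n_unmeth,
                    context=context,
                    trinucleotide=trinuc.upper(),
                )
            )
    return records


def write_bisulfite_report(path: str | Path, records: Iterable[BisulfiteSiteRecord]) -> None:
    """Write records in the 1-based cytosine-report dialect."""
    with open(path, "w") as handle:
        for rec in records:
            handle.write(
                f"{rec.chrom}\t{rec.pos + 1}\t{rec.strand}\t{rec.count_methylated}\t"
                f"{rec.count_unmethylated}\t{rec.context}\t{rec.trinucleotide}\n"
            )


# ---------------------------------------------------------------------------
# Event-aligned reads (JSON lines)


def read_event_reads(path: str | Path) -> Iterator[EventAlignedRead]:
    """Stream event-aligned reads from a JSON-lines file."""
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise FormatError(f"{path}:{lineno}: invalid JSON ({exc})") from None
            try:
                read_id = obj["read_id"]
                chrom = obj["chrom"]
                strand = obj["strand"]
                start = int(obj["start"])
                end = int(obj["end"])
                bases = obj["bases"]
                signals = obj["signals"]
            except KeyError as exc:
                raise FormatError(f"{path}:{lineno}: missing field {exc}") from None
            if strand not in "+-":
                raise FormatError(f"{path}:{lineno}: unknown strand {strand!r}")
            if end - start != len(bases) or len(bases) != len(signals):
                raise FormatError(
                    f"{path}:{lineno}: read {read_id}: declared span {start}-{end} "
                    f"inconsistent with {len(bases)} bases / {len(signals)} signal groups"
                )
            for i, sig in enumerate(signals):
                if not sig:
                    raise FormatError(
                        f"{path}:{lineno}: read {read_id}: empty signal list at base {start + i}"
                    )
            yield EventAlignedRead(
                read_id=read_id,
                chrom=chrom,
                strand=strand,
                start=start,
                bases=bases.upper(),
                signals=[[float(v) for v in sig] for sig in signals],
            )


def write_event_reads(path: str | Path, reads: Iterable[EventAlignedRead]) -> None:
    with open(path, "w") as handle:
        for read in reads:
            obj = {
                "read_id": read.read_id,
                "chrom": read.chrom,
                "strand": read.strand,
                "start": read.start,
                "end": read.end,
                "bases": read.bases,
                "signals": [[float(v) for v in sig] for sig in read.signals],
            }
            handle.write(json.dumps(obj) + "\n")


# ---------------------------------------------------------------------------
# Per-read calls and per-site frequencies

CALL_HEADER = "chrom\tpos\tstrand\tpos_in_strand\tread_id\tprob_unmeth\tprob_meth\tcall\tkmer"
FREQ_HEADER = "chrom\tpos\tstrand\tcontext\tcoverage\tn_meth\tfrequency"


def write_call_records(path: str | Path, records: Iterable) -> None:
    """Write per-read calls; see :data:`CALL_HEADER` for the column order."""
    with open(path, "w") as handle:
        handle.write(CALL_HEADER + "\n")
        for rec in records:
            handle.write(
                f"{rec.chrom}\t{rec.pos}\t{rec.strand}\t{rec.pos_in_strand}\t{rec.read_id}\t"
                f"{rec.p_unmethylated:.6f}\t{rec.p_methylated:.6f}\t{rec.call}\t{rec.kmer}\n"
            )


def read_call_records(path: str | Path) -> list:
    from .calling import CallRecord

    records = []
    with open(path) as handle:
        header = handle.readline().rstrip("\n")
        if header != CALL_HEADER:
            raise FormatError(f"{path}: unexpected call-record header")
        for lineno, line in enumerate(handle, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 columns")
            records.append(
                CallRecord(
                    chrom=fields[0],
                    pos=int(fields[1]),
                    strand=fields[2],
                    pos_in_strand=int(fields[3]),
                    read_id=fields[4],
                    p_unmethylated=float(fields[5]),
                    p_methylated=float(fields[6]),
                    call=int(fields[7]),
                    kmer=fields[8],
                )
            )
    return records


def write_site_frequencies(path: str | Path, freqs: Iterable) -> None:
    with open(path, "w") as handle:
        handle.write(FREQ_HEADER + "\n")
        for f in freqs:
            handle.write(
                f"{f.chrom}\t{f.pos}\t{f.strand}\t{f.context}\t{f.coverage}\t"
                f"{f.n_methylated}\t{f.frequency:.6f}\n"
            )


def read_site_frequencies(path: str | Path) -> list:
    from .calling import SiteFrequency

    freqs = []
    with open(path) as handle:
        header = handle.readline().rstrip("\n")
        if header != FREQ_HEADER:
            raise FormatError(f"{path}: unexpected site-frequency header")
        for lineno, line in enumerate(handle, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 7:
                raise FormatError(f"{path}:{lineno}: expected 7 columns")
            freqs.append(
                SiteFrequency(
                    chrom=fields[0],
                    pos=int(fields[1]),
                    strand=fields[2],
                    context=fields[3],
                    coverage=int(fields[4]),
                    n_methylated=int(fields[5]),
                )
            )
    return freqs


# ---------------------------------------------------------------------------
# Repeat-pair coordinates


def read_repeat_coords(path: str | Path) -> list[RepeatPair]:
    """Parse a self-alignment coordinate table into :class:`RepeatPair` objects.

    Input coordinates are 1-based inclusive; ``end < start`` on the second
    member marks a reverse-orientation alignment.  Identity is given in
    percent and stored as a fraction.  Rows aligning an interval to itself
    are discarded.
    """
    pairs: list[RepeatPair] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 columns, got {len(fields)}")
            try:
                s_a, e_a, s_b, e_b = (int(v) for v in fields[:4])
                len_a, len_b = int(fields[4]), int(fields[5])
                identity_pct = float(fields[6])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: malformed number ({exc})") from None
            chrom_a, chrom_b = fields[7], fields[8]
            if not 0.0 <= identity_pct <= 100.0:
                raise FormatError(f"{path}:{lineno}: identity {identity_pct} outside [0, 100]")
            reverse = e_b < s_b
            if reverse:
                s_b, e_b = e_b, s_b
            region_a = (chrom_a, s_a - 1, e_a)
            region_b = (chrom_b, s_b - 1, e_b)
            if region_a == region_b:
                continue  # self-alignment of an interval to itself
            pairs.append(
                RepeatPair(
                    region_a=region_a,
                    region_b=region_b,
                    length=min(len_a, len_b),
                    identity=identity_pct / 100.0,
                    reverse=reverse,
                )
            )
    return pairs


def write_repeat_coords(path: str | Path, pairs: Iterable[RepeatPair]) -> None:
    with open(path, "w") as handle:
        for p in pairs:
            chrom_a, s_a, e_a = p.region_a
            chrom_b, s_b, e_b = p.region_b
            if p.reverse:
                s_b_out, e_b_out = e_b, s_b + 1
            else:
                s_b_out, e_b_out = s_b + 1, e_b
            handle.write(
                f"{s_a + 1}\t{e_a}\t{s_b_out}\t{e_b_out}\t{e_a - s_a}\t{e_b - s_b}\t"
                f"{p.identity * 100.0:.2f}\t{chrom_a}\t{chrom_b}\n"
            )
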