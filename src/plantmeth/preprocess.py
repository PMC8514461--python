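"""Event-aligned reads and per-read signal normalization.

An event-aligned read is a nanopore read whose raw current samples have been
assigned to contiguous reference bases (the product of re-squiggling).  Before
feature extraction each read's signals are centered by their median and scaled
by their median absolute deviation (MAD), computed over the whole read, so
that reads from different pores and runs live on a common scale.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterator, Sequence

import numpy as np


class DegenerateSignalError(ValueError):
    """Raised when a read's signal is constant (MAD = 0) and cannot be scaled."""


@dataclass(frozen=True)
class EventAlignedRead:
    """One read's contiguous reference mapping with signals per base.

    ``bases[i]`` is the forward-reference base at position ``start + i`` and
    ``signals[i]`` the non-empty list of current values assigned to it.
    ``strand`` is the strand the molecule was read from.
    """

    read_id: str
    chrom: str
    strand: str
    start: int
    bases: str
    signals: Sequence[Sequence[float]]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"read {self.read_id}: unknown strand {self.strand!r}")
        if len(self.bases) != len(self.signals):
            raise ValueError(
                f"read {self.read_id}: {len(self.bases)} bases but "
                f"{len(self.signals)} signal groups"
            )
        for i, sig in enumerate(self.signals):
            if len(sig) == 0:
                raise ValueError(f"read {self.read_id}: empty signal list at base {self.start + i}")

    @property
    def end(self) -> int:
        return self.start + len(self.bases)

    def iter_bases(self) -> Iterator[tuple[int, str, Sequence[float]]]:
        """Yield (ref_pos, forward base, signals) triples in reference order."""
        for i, (base, sig) in enumerate(zip(self.bases, self.signals)):
            yield self.start + i, base, sig


def normalize_read(read: EventAlignedRead) -> EventAlignedRead:
    """Median-shift / MAD-scale all signal values of one read.

    Every value x becomes (x - median) / MAD with both statistics computed
    over the concatenation of the read's signals; the per-base grouping is
    preserved.  The raw (unscaled) MAD is used, without the Gaussian
    consistency constant.  The operation is idempotent and invariant to
    positive affine transforms of the input.
    """
    flat = np.concatenate([np.asarray(sig, dtype=np.float64) for sig in read.signals])
    med = np.median(flat)
    mad = np.median(np.abs(flat - med))
    if mad == 0.0:
        raise DegenerateSignalError(
            f"read {read.read_id}: constant signal (MAD = 0), cannot normalize"
        )
    normalized = [((np.asarray(sig, dtype=np.float64) - med) / mad).tolist() for sig in read.signals]
    return replace(read, signals=normalized)
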