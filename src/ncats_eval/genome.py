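"""Genomic intervals, target regions and alignment records.

Coordinates are 0-based half-open internally; 1-based inclusive coordinates
(as printed in genome browsers and summary tables) are converted only at
construction / reporting boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "GenomicInterval",
    "Guide",
    "TargetRegion",
    "ReadAlignment",
    "read_bed",
    "write_bed",
]


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int
    name: str = ""

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start >= self.end:
            raise ValueError(
                f"interval {self.name or self.chrom}: start ({self.start}) "
                f"must be < end ({self.end})"
            )

    @classmethod
    def from_1based(cls, chrom: str, start: int, end: int, name: str = "") -> "GenomicInterval":
        """Build from a 1-based inclusive range as printed (e.g. 300325-440842)."""
        return cls(chrom, start - 1, end, name)

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, position: int) -> bool:
        return self.start <= position < self.end

    def overlap(self, other: "GenomicInterval") -> int:
        """Length of the overlap with ``other`` in bp (0 if disjoint)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class Guide:
    """A Cas9 guide: cut position (bp, 0-based) and the strand reads extend on.

    Reads initiate at the cut and run downstream on ``strand``: '+' extends to
    increasing coordinates, '-' to decreasing ones.
    """

    cut_position: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass(frozen=True)
class TargetRegion:
    """An enrichment target: an interval plus the guide cut sites inside it."""

    interval: GenomicInterval
    guides: tuple[Guide, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        for g in self.guides:
            if not self.interval.contains(g.cut_position):
                raise ValueError(
                    f"guide cut {g.cut_position} outside region "
                    f"{self.interval.name or self.interval.chrom}"
                )

    @property
    def name(self) -> str:
        return self.interval.name


@dataclass(frozen=True)
class ReadAlignment:
    """One aligned read: interval, strand, mapping quality and primary flag."""

    read_id: str
    interval: GenomicInterval
    strand: str
    mapq: int
    is_primary: bool = True
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.mapq < 0:
            raise ValueError("mapq must be >= 0")

    @property
    def length(self) -> int:
        return self.interval.length


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read a BED file (chrom, start, end[, name]) into intervals.

    BED is already 0-based half-open, so coordinates pass through unchanged.
    """
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{i}: BED line has fewer than 3 columns")
            name = parts[3] if len(parts) > 3 else ""
            out.append(GenomicInterval(parts[0], int(parts[1]), int(parts[2]), name))
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\n")
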