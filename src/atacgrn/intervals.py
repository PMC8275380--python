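"""Genomic interval primitives and BED-style I/O.

All coordinates follow the BED convention: 0-based, half-open ``[start, end)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A span on a named sequence, 0-based half-open.

    Ordering is lexicographic in (chrom, start, end), which is the sort
    order used for all peak/footprint sets in the package.
    """

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be nonempty")
        if not self.start < self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: start must be < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    @property
    def name(self) -> str:
        """Canonical identifier, e.g. ``chrS:100-400``."""
        return f"{self.chrom}:{self.start}-{self.end}"

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains_point(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start <= pos < self.end

    def jaccard(self, other: "GenomicInterval") -> float:
        inter = self.overlap_length(other)
        if inter == 0:
            return 0.0
        union = self.length + other.length - inter
        return inter / union


def interval_from_name(name: str) -> GenomicInterval:
    """Parse a ``chrom:start-end`` identifier back into an interval."""
    chrom, _, span = name.rpartition(":")
    start, _, end = span.partition("-")
    return GenomicInterval(chrom, int(start), int(end))


def sort_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    return sorted(intervals)


def merge_intervals(
    intervals: Iterable[GenomicInterval], max_gap: int = 0
) -> list[GenomicInterval]:
    """Merge intervals whose gap (end_i to start_j) is <= ``max_gap``.

    ``max_gap=0`` merges overlapping and bookended intervals only.
    """
    out: list[GenomicInterval] = []
    for iv in sort_intervals(intervals):
        if out and iv.chrom == out[-1].chrom and iv.start - out[-1].end <= max_gap:
            if iv.end > out[-1].end:
                out[-1] = GenomicInterval(iv.chrom, out[-1].start, iv.end)
        else:
            out.append(iv)
    return out


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read intervals from a BED file (first three columns; extra columns ignored)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"BED line has fewer than 3 columns: {line!r}")
            out.append(GenomicInterval(fields[0], int(fields[1]), int(fields[2])))
    return out


def write_bed(
    intervals: Sequence[GenomicInterval],
    path: str | Path,
    names: Sequence[str] | None = None,
    scores: Sequence[float] | None = None,
) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if names is not None:
                fields.append(str(names[i]))
            if scores is not None:
                if names is None:
                    fields.append(iv.name)
                fields.append(f"{scores[i]:g}")
            fh.write("\t".join(fields) + "\n")
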