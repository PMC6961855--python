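"""Genomic interval arithmetic.

Internally every coordinate is 0-based, half-open.  User-facing strings
(reports, CLI arguments) follow the 1-based inclusive convention used by
genome browsers, e.g. ``chr7:55,174,773-55,174,787``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

_REGION_RE = re.compile(r"^([\w.]+):([\d,]+)-([\d,]+)$")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open interval on a named sequence."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.start >= self.end:
            raise ValueError(f"empty or inverted interval: {self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def reciprocal_overlap(self, other: "GenomicInterval") -> float:
        """Smaller of the two overlap fractions (0 when disjoint)."""
        ov = self.overlap_length(other)
        if ov == 0:
            return 0.0
        return min(ov / len(self), ov / len(other))

    def distance_to(self, other: "GenomicInterval") -> int:
        """Nearest-edge separation in bp; 0 when the intervals overlap."""
        if self.chrom != other.chrom:
            raise ValueError(f"intervals on different sequences: {self.chrom} vs {other.chrom}")
        if self.overlaps(other):
            return 0
        if other.start >= self.end:
            return other.start - self.end
        return self.start - other.end

    def shifted(self, offset: int) -> "GenomicInterval":
        return GenomicInterval(self.chrom, self.start + offset, self.end + offset)

    @classmethod
    def from_1based(cls, chrom: str, start1: int, end1: int) -> "GenomicInterval":
        return cls(chrom, start1 - 1, end1)

    @classmethod
    def parse(cls, text: str) -> "GenomicInterval":
        """Parse a 1-based inclusive region string like ``chr7:55,174,773-55,174,787``."""
        m = _REGION_RE.match(text.strip())
        if m is None:
            raise ValueError(f"cannot parse region {text!r}; expected chrom:start-end")
        chrom, s, e = m.groups()
        return cls.from_1based(chrom, int(s.replace(",", "")), int(e.replace(",", "")))

    def to_1based_str(self) -> str:
        return f"{self.chrom}:{self.start + 1}-{self.end}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_1based_str()
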