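"""Haplotype landscape I/O.

A landscape is a named, megabase-scale sequence slice centred on a query
locus, carrying its reference coordinates, the phase/coverage block
structure recovered from long-read phasing, and a record of any intervals
whose sequence was filled in from a reference assembly.

File conventions
----------------
FASTA: one record per landscape; the record description carries the
reference origin as ``origin=chrom:start-end`` (1-based inclusive) so a
landscape round-trips through plain FASTA.  BED (6 columns, standard
0-based half-open): one row per *covered* block (sequencing depth >= 10x);
column 4 is a free-form block label and column 5 encodes the phased (1) vs
collapsed (0) state.  Gaps between covered blocks are the low-coverage
phase discontinuities.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import List, Optional, Tuple

import pyfaidx

from .regions import GenomicInterval

_ORIGIN_RE = re.compile(r"origin=([\w.]+:[\d,]+-[\d,]+)")


@dataclass(frozen=True)
class PhaseBlock:
    """A covered block of a landscape; ``phased`` distinguishes haplotype-resolved from collapsed."""

    interval: GenomicInterval
    phased: bool
    coverage_ok: bool = True


@dataclass
class HaplotypeLandscape:
    """A named sequence with reference origin, phase blocks and fill-in bookkeeping.

    ``origin`` gives the reference coordinates of the whole slice (base 0 of
    ``sequence`` sits at ``origin.start``); after a structural edit the
    origin span is nominal.  ``blocks`` lists covered blocks, sorted and
    non-overlapping; intervals between them are low-coverage discontinuities.
    """

    name: str
    sequence: str
    origin: GenomicInterval
    blocks: List[PhaseBlock] = field(default_factory=list)
    filled_intervals: List[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.origin):
            raise ValueError(
                f"sequence length {len(self.sequence)} != origin span {len(self.origin)}"
            )
        if not self.blocks:
            self.blocks = [PhaseBlock(self.origin, phased=True)]
        self._check_blocks()

    def _check_blocks(self) -> None:
        prev_end = None
        for b in self.blocks:
            if not self.origin.contains(b.interval):
                raise ValueError(f"block {b.interval} outside landscape span {self.origin}")
            if prev_end is not None and b.interval.start < prev_end:
                raise ValueError(f"blocks overlap or are unsorted at {b.interval}")
            prev_end = b.interval.end

    # -- coordinate helpers -------------------------------------------------
    def offset_of(self, ref_pos: int) -> int:
        return ref_pos - self.origin.start

    def subseq(self, interval: GenomicInterval) -> str:
        if not self.origin.contains(interval):
            raise ValueError(f"interval {interval} outside landscape {self.origin}")
        return self.sequence[self.offset_of(interval.start) : self.offset_of(interval.end)]

    def low_coverage_intervals(self) -> List[GenomicInterval]:
        """Gaps between covered blocks (the phase discontinuities)."""
        gaps = []
        cursor = self.origin.start
        for b in self.blocks:
            if b.interval.start > cursor:
                gaps.append(GenomicInterval(self.origin.chrom, cursor, b.interval.start))
            cursor = max(cursor, b.interval.end)
        if cursor < self.origin.end:
            gaps.append(GenomicInterval(self.origin.chrom, cursor, self.origin.end))
        return gaps


def coverage_summary(landscape: HaplotypeLandscape) -> Tuple[float, float]:
    """(covered bp / total bp, phased bp / total bp)."""
    total = len(landscape.origin)
    covered = sum(len(b.interval) for b in landscape.blocks)
    phased = sum(len(b.interval) for b in landscape.blocks if b.phased)
    return covered / total, phased / total


def fill_discontinuities(
    landscape: HaplotypeLandscape, reference: HaplotypeLandscape
) -> HaplotypeLandscape:
    """Substitute reference bases across every low-coverage discontinuity.

    The reference must span all gaps at homologous coordinates and contain
    no undetermined (N) bases there.  Covered blocks are never touched.
    Filled intervals are recorded so downstream hit reports can flag hits
    that exist only by virtue of the fill-in.
    """
    gaps = landscape.low_coverage_intervals()
    if not gaps:
        return landscape
    seq = list(landscape.sequence)
    filled = list(landscape.filled_intervals)
    for gap in gaps:
        if not reference.origin.contains(gap):
            raise ValueError(f"reference {reference.origin} does not cover gap {gap}")
        ref_seq = reference.subseq(gap)
        if "N" in ref_seq.upper():
            raise ValueError(f"reference has undetermined sequence within gap {gap}")
        off = landscape.offset_of(gap.start)
        seq[off : off + len(gap)] = ref_seq.upper()
        filled.append(gap)
    return replace(landscape, sequence="".join(seq), filled_intervals=sorted(filled))


# ---------------------------------------------------------------------------
# FASTA / BED plumbing
# ---------------------------------------------------------------------------


def read_blocks_bed(path: str | Path, span: GenomicInterval) -> List[PhaseBlock]:
    blocks: List[PhaseBlock] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise ValueError(f"{path}:{lineno}: expected >=5 BED columns, got {line!r}")
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                phased = bool(int(fields[4]))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed BED record {line!r}") from exc
            iv = GenomicInterval(chrom, start, end)
            if not span.contains(iv):
                raise ValueError(f"{path}:{lineno}: block {iv} outside landscape span {span}")
            blocks.append(PhaseBlock(iv, phased=phased))
    blocks.sort(key=lambda b: b.interval.start)
    return blocks


def write_blocks_bed(landscape: HaplotypeLandscape, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, b in enumerate(landscape.blocks):
            fh.write(
                f"{b.interval.chrom}\t{b.interval.start}\t{b.interval.end}\t"
                f"{landscape.name}_block{i}\t{int(b.phased)}\t.\n"
            )


def read_landscape(
    fasta_path: str | Path,
    region: Optional[GenomicInterval] = None,
    blocks_path: Optional[str | Path] = None,
    name: Optional[str] = None,
) -> HaplotypeLandscape:
    """Load a landscape slice from FASTA (+ optional phase-block BED).

    ``region`` is given in the coordinates of the FASTA contig.  When the
    record description carries an ``origin=`` tag (as written by
    :func:`write_landscape`), coordinates are reference coordinates and
    ``region`` may be omitted to take the whole record.
    """
    fa = pyfaidx.Fasta(str(fasta_path))
    rec_name = None
    try:
        if region is None:
            rec = fa[list(fa.keys())[0]]
            rec_name = rec.name
            m = _ORIGIN_RE.search(rec.long_name)
            if m:
                origin = GenomicInterval.parse(m.group(1))
            else:
                origin = GenomicInterval(rec.name, 0, len(rec))
            seq = str(rec[:]).upper()
        else:
            if region.chrom not in fa:
                raise KeyError(f"contig {region.chrom!r} not in {fasta_path}")
            rec = fa[region.chrom]
            rec_name = rec.name
            m = _ORIGIN_RE.search(rec.long_name)
            base = GenomicInterval.parse(m.group(1)).start if m else 0
            lo, hi = region.start - base, region.end - base
            if lo < 0 or hi > len(rec):
                raise ValueError(
                    f"region {region} out of bounds for contig {region.chrom} "
                    f"({len(rec)} bp, base {base})"
                )
            seq = str(rec[lo:hi]).upper()
            origin = region
    finally:
        fa.close()
    blocks = read_blocks_bed(blocks_path, origin) if blocks_path else []
    return HaplotypeLandscape(
        name=name or rec_name or origin.chrom, sequence=seq, origin=origin, blocks=blocks
    )


def write_landscape(
    landscape: HaplotypeLandscape,
    fasta_path: str | Path,
    bed_path: Optional[str | Path] = None,
    line_width: int = 60,
) -> None:
    with open(fasta_path, "w") as fh:
        fh.write(f">{landscape.name} origin={landscape.origin.to_1based_str()}\n")
        seq = landscape.sequence
        for i in range(0, len(seq), line_width):
            fh.write(seq[i : i + line_width] + "\n")
    if bed_path is not None:
        write_blocks_bed(landscape, bed_path)
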