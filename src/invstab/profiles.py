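"""Sliding-window instability profiles and in-silico structural variants.

Every k-bp window of an exon is treated in turn as the query motif: its
reverse complements are catalogued across the landscape and converted to a
raw stability score, giving a per-window instability profile.  Windows are
indexed 1-based from the exon 5' end, so the window covering exon bases
52-66 of a 99-bp exon has index 52 and a 99-bp exon yields exactly 85
fully-exonic 15-bp windows.

Structural-variant edits (1-kb deletion, tandem duplication, inversion)
are applied independently to the pristine landscape; hit distances are
recomputed on the edited coordinates, so a duplication pushes downstream
hits farther away.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .landscape import HaplotypeLandscape, PhaseBlock
from .model import InstabilityParams, raw_stability
from .regions import GenomicInterval
from .scanner import QueryMotif, ScanParams, scan_landscape
from .sequence import reverse_complement

SV_KINDS = ("deletion", "duplication", "inversion")


@dataclass(frozen=True)
class SVEdit:
    """One structural edit; duplications insert the copy in tandem after the original."""

    kind: str
    interval: GenomicInterval

    def __post_init__(self) -> None:
        if self.kind not in SV_KINDS:
            raise ValueError(f"unknown SV kind {self.kind!r}; choose from {SV_KINDS}")

    @property
    def label(self) -> str:
        return f"{self.kind}:{self.interval.to_1based_str()}"


@dataclass
class WindowProfile:
    """Per-window stability scores across an exon."""

    exon: GenomicInterval
    k: int
    window_indices: List[int]  # 1-based from the exon 5' end
    scores: List[float]  # raw stability S per window
    canonical_window: Optional[int] = None  # e.g. 52 for a deletion of exon bases 52-66

    @property
    def instabilities(self) -> List[float]:
        return [1.0 - s for s in self.scores]

    def to_frame(self) -> pd.DataFrame:
        inst = self.instabilities
        ranks = rankdata([-i for i in inst], method="average")
        return pd.DataFrame(
            {
                "window_index": self.window_indices,
                "raw_stability": self.scores,
                "instability": inst,
                "instability_rank": ranks,
            }
        )


def window_profile(
    landscape: HaplotypeLandscape,
    exon: GenomicInterval,
    k: int = 15,
    scan_params: ScanParams = ScanParams(),
    model_params: InstabilityParams = InstabilityParams(),
    exonic_only: bool = True,
    canonical_window: Optional[int] = None,
) -> WindowProfile:
    """Stability of every k-bp window across an exon.

    In ``exonic_only`` mode windows are restricted to those fully inside
    the exon (85 windows for k=15 on a 99-bp exon); otherwise every window
    overlapping at least one exon base is scored, extending into the
    flanking introns (used for the smoother k=20 profile).
    """
    if not landscape.origin.contains(exon):
        raise ValueError(f"exon {exon} outside landscape {landscape.origin}")
    if exonic_only:
        if len(exon) < k:
            raise ValueError(f"exon of {len(exon)} bp shorter than window k={k}")
        starts = range(exon.start, exon.end - k + 1)
    else:
        starts = range(exon.start - k + 1, exon.end)
    sp = replace(scan_params, k=k)
    indices: List[int] = []
    scores: List[float] = []
    for s in starts:
        iv = GenomicInterval(exon.chrom, s, s + k)
        if not landscape.origin.contains(iv):
            continue
        query = QueryMotif(seq=landscape.subseq(iv), interval=iv)
        hits = scan_landscape(landscape, query, sp)
        scores.append(raw_stability(hits, model_params).raw_stability)
        indices.append(s - exon.start + 1)
    return WindowProfile(
        exon=exon, k=k, window_indices=indices, scores=scores, canonical_window=canonical_window
    )


def rank_window(profile: WindowProfile, window_index: int) -> float:
    """Percentile rank of a window's instability (1 = the single most unstable window).

    Ties take the midrank, so an all-equal profile puts every window at the
    50th percentile.
    """
    if window_index not in profile.window_indices:
        raise KeyError(f"window {window_index} not in profile")
    inst = profile.instabilities
    ranks = rankdata([-i for i in inst], method="average")
    pos = profile.window_indices.index(window_index)
    return 100.0 * ranks[pos] / len(inst)


# ---------------------------------------------------------------------------
# structural edits
# ---------------------------------------------------------------------------


def _remap_point(pos: int, edit_start: int, edit_end: int, kind: str) -> int:
    span = edit_end - edit_start
    if kind == "deletion":
        if pos <= edit_start:
            return pos
        if pos >= edit_end:
            return pos - span
        return edit_start  # interior points collapse onto the breakpoint
    if kind == "duplication":
        return pos if pos <= edit_end else pos + span
    return pos  # inversion: length-preserving


def apply_sv_edit(landscape: HaplotypeLandscape, edit: SVEdit) -> HaplotypeLandscape:
    """Apply one structural edit, remapping phase blocks and filled intervals.

    Deletion removes the interval's bases; duplication inserts a tandem
    copy immediately after the original; inversion replaces the interval
    by its reverse complement in place.  A phase block spanning a
    duplication breakpoint stretches across the inserted copy.
    """
    iv = edit.interval
    if not landscape.origin.contains(iv):
        raise ValueError(f"edit {edit.label} outside landscape {landscape.origin}")
    s, e = landscape.offset_of(iv.start), landscape.offset_of(iv.end)
    seq = landscape.sequence
    if edit.kind == "deletion":
        new_seq = seq[:s] + seq[e:]
    elif edit.kind == "duplication":
        new_seq = seq[:e] + seq[s:e] + seq[e:]
    else:
        new_seq = seq[:s] + reverse_complement(seq[s:e]) + seq[e:]

    def remap(interval: GenomicInterval) -> Optional[GenomicInterval]:
        a = _remap_point(interval.start, iv.start, iv.end, edit.kind)
        b = _remap_point(interval.end, iv.start, iv.end, edit.kind)
        if b <= a:
            return None
        return GenomicInterval(interval.chrom, a, b)

    new_blocks = []
    for b in landscape.blocks:
        riv = remap(b.interval)
        if riv is not None:
            new_blocks.append(PhaseBlock(riv, b.phased, b.coverage_ok))
    new_filled = [riv for f in landscape.filled_intervals if (riv := remap(f)) is not None]
    new_origin = GenomicInterval(
        landscape.origin.chrom, landscape.origin.start, landscape.origin.start + len(new_seq)
    )
    # clip remapped annotation to the new span (a trailing deletion shortens it)
    new_blocks = [
        PhaseBlock(
            GenomicInterval(
                b.interval.chrom, b.interval.start, min(b.interval.end, new_origin.end)
            ),
            b.phased,
            b.coverage_ok,
        )
        for b in new_blocks
        if b.interval.start < new_origin.end
    ]
    return HaplotypeLandscape(
        name=f"{landscape.name}|{edit.kind}",
        sequence=new_seq,
        origin=new_origin,
        blocks=new_blocks,
        filled_intervals=new_filled,
    )


def perturbation_report(
    landscape: HaplotypeLandscape,
    exon: GenomicInterval,
    edits: Sequence[SVEdit],
    k: int = 15,
    scan_params: ScanParams = ScanParams(),
    model_params: InstabilityParams = InstabilityParams(),
    canonical_window: Optional[int] = None,
) -> Dict[str, WindowProfile]:
    """Baseline profile plus one profile per independently applied edit.

    Each edit is applied to the pristine landscape, never cumulatively.
    The exon's coordinates are remapped when an edit lies upstream of it;
    an edit overlapping the exon itself is allowed but flagged with a
    warning.
    """
    out = {
        "baseline": window_profile(
            landscape, exon, k, scan_params, model_params, canonical_window=canonical_window
        )
    }
    for edit in edits:
        if edit.interval.overlaps(exon):
            warnings.warn(f"edit {edit.label} overlaps the profiled exon", stacklevel=2)
        edited = apply_sv_edit(landscape, edit)
        a = _remap_point(exon.start, edit.interval.start, edit.interval.end, edit.kind)
        b = _remap_point(exon.end, edit.interval.start, edit.interval.end, edit.kind)
        exon_mapped = GenomicInterval(exon.chrom, a, b)
        out[edit.label] = window_profile(
            edited, exon_mapped, k, scan_params, model_params, canonical_window=canonical_window
        )
    return out
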