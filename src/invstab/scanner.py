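"""Deterministic reverse-complement motif scanning.

Finds every inverted approximate copy of a query motif within the reporting
window of a landscape: each candidate locus is scored against the reverse
complement of the query with :func:`invstab.sequence.align_revcomp`
(ungapped plus every single-1-bp-gap alignment, gap = 2 effective
mismatches), hits above 6 effective mismatches (below 60% homology) are
dropped, and overlapping candidate alignments are merged to the best one.

Two modes are exposed.  ``exhaustive`` reports every merged locus that
clears the homology floor.  ``seeded`` additionally requires the winning
alignment to contain a contiguous exact-match run of at least
``seed_word`` bases (default 8), emulating the word-seeded behaviour of a
BLAST-style search: on random sequence the exhaustive mode reports on the
order of 10^3 loci per +/-421 kb while the seeded mode reports on the
order of 10^2.  Seeded hits are by construction a subset of exhaustive
hits with identical scores.

Only the plus strand is scanned for the reverse complement of the query: a
minus-strand occurrence would be a direct repeat, which does not form the
fold-back geometry the instability model is about.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .landscape import HaplotypeLandscape
from .regions import GenomicInterval
from .sequence import (
    GAP_MISMATCH_PENALTY,
    AlignmentScore,
    align_revcomp,
    max_exact_run,
    reverse_complement,
)

_ENC = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENC[_b] = _i


def _encode(seq: str) -> np.ndarray:
    """A,C,G,T -> 0..3; anything else (ambiguity, N) -> 4."""
    return _ENC[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class QueryMotif:
    """The k-bp target sequence plus its landscape coordinates."""

    seq: str
    interval: GenomicInterval

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.interval):
            raise ValueError("query sequence length does not match its interval")

    @property
    def k(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class ScanParams:
    """Scan configuration; defaults are the study conditions.

    ``reactive_distance`` (421,000 bp) bounds the separation out to which
    inverted pairs are scored as reactive; ``reporting_distance``
    (500,000 bp) bounds the catalogued landscape.  ``self_exclusion`` is a
    bp radius around the query within which hits are suppressed (None =
    the query interval only).
    """

    k: int = 15
    max_mismatches: int = 6
    reactive_distance: int = 421_000
    reporting_distance: int = 500_000
    mode: str = "seeded"
    seed_word: int = 8
    self_exclusion: Optional[int] = None

    def __post_init__(self) -> None:
        if self.reactive_distance > self.reporting_distance:
            raise ValueError("reactive_distance must be <= reporting_distance")
        if not 1 <= self.seed_word <= self.k:
            raise ValueError("seed_word must be in [1, k]")
        if self.mode not in ("exhaustive", "seeded"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass(frozen=True)
class RevCompHit:
    """One inverted approximate copy of the query."""

    interval: GenomicInterval
    score: AlignmentScore
    distance: int
    within_reactive: bool
    haplotype: str = ""
    in_filled_region: bool = False

    @property
    def locus(self) -> str:
        return self.interval.to_1based_str()


# ---------------------------------------------------------------------------
# vectorised candidate generation
# ---------------------------------------------------------------------------


def _candidate_table(enc: np.ndarray, q: np.ndarray, max_mm: int):
    """All (start, target_len, effective_mm, matched, gapped, gap_index) candidates.

    ``enc`` is the encoded scan region, ``q`` the encoded reverse
    complement of the query.  Vectorised over every alignment start; gapped
    alignments are scored through prefix/suffix mismatch cumsums.
    """
    k = len(q)
    L = len(enc)
    out = []
    n0 = L - k + 1
    if n0 < 1:
        return out

    M0 = np.empty((k, n0), dtype=np.uint8)
    for j in range(k):
        col = enc[j : j + n0]
        M0[j] = (col != q[j]) | (col == 4) | (q[j] == 4)
    mm0 = M0.sum(axis=0, dtype=np.int16)

    # N-run mask: window [i, i+w) is skipped when it contains >= 2 consecutive Ns
    is_n = enc == 4
    r2 = (is_n[:-1] & is_n[1:]).astype(np.int32)
    c2 = np.concatenate([[0], np.cumsum(r2)])

    def has_nrun(i0: np.ndarray, w: int) -> np.ndarray:
        return (c2[i0 + w - 1] - c2[i0]) > 0

    idx = np.nonzero(mm0 <= max_mm)[0]
    if idx.size:
        keep = ~has_nrun(idx, k)
        for i in idx[keep]:
            mm = int(mm0[i])
            out.append((int(i), k, mm, k - mm, False, None))

    nc = L - k  # common width for both gapped classes
    if nc >= 1 and max_mm >= GAP_MISMATCH_PENALTY:
        M0c = M0[:, :nc]
        pre = np.zeros((k + 1, nc), dtype=np.int16)
        np.cumsum(M0c, axis=0, out=pre[1:])

        # deletion-type: query base g unaligned, target window length k-1
        Mm1 = np.zeros((k, nc), dtype=np.uint8)
        for j in range(1, k):
            col = enc[j - 1 : j - 1 + nc]
            Mm1[j] = (col != q[j]) | (col == 4) | (q[j] == 4)
        sufd = np.zeros((k, nc), dtype=np.int16)
        for g in range(k - 2, -1, -1):
            sufd[g] = sufd[g + 1] + Mm1[g + 1]
        subd = pre[:k] + sufd
        mmd = subd.min(axis=0)
        gd = subd.argmin(axis=0)
        idx = np.nonzero(mmd + GAP_MISMATCH_PENALTY <= max_mm)[0]
        if idx.size:
            keep = ~has_nrun(idx, k - 1)
            for i in idx[keep]:
                sub = int(mmd[i])
                out.append(
                    (int(i), k - 1, sub + GAP_MISMATCH_PENALTY, (k - 1) - sub, True, int(gd[i]))
                )

        # insertion-type: target base g unaligned, target window length k+1
        Mp1 = np.empty((k, nc), dtype=np.uint8)
        for j in range(k):
            col = enc[j + 1 : j + 1 + nc]
            Mp1[j] = (col != q[j]) | (col == 4) | (q[j] == 4)
        sufi = np.zeros((k + 1, nc), dtype=np.int16)
        for g in range(k - 1, -1, -1):
            sufi[g] = sufi[g + 1] + Mp1[g]
        subi = pre + sufi
        mmi = subi.min(axis=0)
        gi = subi.argmin(axis=0)
        idx = np.nonzero(mmi + GAP_MISMATCH_PENALTY <= max_mm)[0]
        if idx.size:
            keep = ~has_nrun(idx, k + 1)
            for i in idx[keep]:
                sub = int(mmi[i])
                out.append(
                    (int(i), k + 1, sub + GAP_MISMATCH_PENALTY, k - sub, True, int(gi[i]))
                )
    return out


def merge_hits(candidates: Sequence[RevCompHit]) -> List[RevCompHit]:
    """Collapse overlapping candidate alignments to the best one per locus.

    Overlap chains are clustered; within a cluster the hit with the fewest
    effective mismatches wins, ties preferring ungapped then smallest start.
    """
    if not candidates:
        return []
    ordered = sorted(candidates, key=lambda h: (h.interval.start, h.interval.end))
    clusters: List[List[RevCompHit]] = []
    cur = [ordered[0]]
    cur_end = ordered[0].interval.end
    for h in ordered[1:]:
        if h.interval.start < cur_end:
            cur.append(h)
            cur_end = max(cur_end, h.interval.end)
        else:
            clusters.append(cur)
            cur = [h]
            cur_end = h.interval.end
    clusters.append(cur)
    winners = [
        min(
            cl,
            key=lambda h: (
                h.score.effective_mismatches,
                h.score.gapped,
                h.interval.start,
            ),
        )
        for cl in clusters
    ]
    return sorted(winners, key=lambda h: h.interval.start)


def scan_landscape(
    landscape: HaplotypeLandscape, query: QueryMotif, params: ScanParams = ScanParams()
) -> List[RevCompHit]:
    """All inverted approximate copies of the query within the reporting window."""
    if not landscape.sequence:
        raise ValueError("empty landscape")
    if not landscape.origin.contains(query.interval):
        raise ValueError(f"query {query.interval} outside landscape {landscape.origin}")
    if len(query.seq) != params.k:
        raise ValueError(f"query length {len(query.seq)} != params.k {params.k}")

    observed = landscape.subseq(query.interval)
    if observed.upper() != query.seq.upper():
        warnings.warn(
            f"landscape {landscape.name} sequence at {query.interval} differs from the "
            "query motif (haplotype variant?)",
            stacklevel=2,
        )

    k = params.k
    q_rel_start = landscape.offset_of(query.interval.start)
    q_rel_end = landscape.offset_of(query.interval.end)
    lo = max(0, q_rel_start - params.reporting_distance - k - 1)
    hi = min(len(landscape.sequence), q_rel_end + params.reporting_distance + k + 1)
    region = landscape.sequence[lo:hi]

    enc = _encode(region)
    q = _encode(reverse_complement(query.seq))
    cands = _candidate_table(enc, q, params.max_mismatches)

    excl_radius = params.self_exclusion or 0
    excl = GenomicInterval(
        query.interval.chrom,
        max(0, query.interval.start - excl_radius),
        query.interval.end + excl_radius,
    )
    chrom = landscape.origin.chrom
    gap_runs = landscape.filled_intervals

    hits: List[RevCompHit] = []
    for start, tlen, eff, matched, gapped, gidx in cands:
        ref_start = landscape.origin.start + lo + start
        iv = GenomicInterval(chrom, ref_start, ref_start + tlen)
        if iv.overlaps(excl):
            continue
        dist = iv.distance_to(query.interval)
        if dist > params.reporting_distance:
            continue
        score = AlignmentScore(eff, matched, gapped, k, gidx)
        hits.append(
            RevCompHit(
                interval=iv,
                score=score,
                distance=dist,
                within_reactive=dist <= params.reactive_distance,
                haplotype=landscape.name,
                in_filled_region=any(iv.overlaps(f) for f in gap_runs),
            )
        )
    merged = merge_hits(hits)
    if params.mode == "seeded":
        merged = [
            h
            for h in merged
            if max_exact_run(query.seq, landscape.subseq(h.interval)) >= params.seed_word
        ]
    return merged


def classify_by_mismatch(hits: Sequence[RevCompHit]) -> Dict[object, int]:
    """Hit counts per effective-mismatch class (2..6 always reported, 0/1 when present).

    Only hits within the reactive distance are counted; the ``"total"`` key
    sums the classes.
    """
    reactive = [h for h in hits if h.within_reactive]
    counts: Dict[object, int] = {}
    for m in (0, 1):
        n = sum(h.score.effective_mismatches == m for h in reactive)
        if n:
            counts[m] = n
    for m in (2, 3, 4, 5, 6):
        counts[m] = sum(h.score.effective_mismatches == m for h in reactive)
    counts["total"] = len(reactive)
    return counts


def compare_hit_presence(
    hit_sets: Mapping[str, Sequence[RevCompHit]], min_reciprocal_overlap: float = 0.5
) -> Tuple[pd.DataFrame, int]:
    """Presence/absence matrix of hit loci across haplotypes.

    Loci are matched across haplotypes by reciprocal interval overlap
    (>= 50% by default) in the shared reference frame.  Returns the
    boolean matrix (rows = union loci, columns = haplotypes) and the
    number of loci absent from at least one haplotype.
    """
    if len(hit_sets) < 2:
        raise ValueError("need >= 2 haplotypes to compare")
    entries = []
    for hap, hits in hit_sets.items():
        for h in hits:
            entries.append((h.interval, hap))
    entries.sort(key=lambda e: (e[0].start, e[0].end))
    reps: List[GenomicInterval] = []
    assignment: List[List[str]] = []
    for iv, hap in entries:
        placed = False
        for j in range(len(reps) - 1, -1, -1):
            if reps[j].end <= iv.start:  # sorted by start: older reps cannot overlap
                break
            if reps[j].reciprocal_overlap(iv) >= min_reciprocal_overlap:
                assignment[j].append(hap)
                placed = True
                break
        if not placed:
            reps.append(iv)
            assignment.append([hap])
    haps = list(hit_sets)
    matrix = pd.DataFrame(
        [[hap in present for hap in haps] for present in assignment],
        index=[iv.to_1based_str() for iv in reps],
        columns=haps,
    )
    absent = int((~matrix.all(axis=1)).sum())
    return matrix, absent


# ---------------------------------------------------------------------------
# hit-table I/O
# ---------------------------------------------------------------------------

_TSV_COLUMNS = [
    "haplotype",
    "chrom",
    "start",
    "end",
    "mismatches",
    "matched_bases",
    "gapped",
    "homology_pct",
    "distance",
    "within_reactive",
    "in_filled_region",
    "k",
]


def hits_to_frame(hits: Sequence[RevCompHit]) -> pd.DataFrame:
    rows = []
    for h in hits:
        rows.append(
            {
                "haplotype": h.haplotype,
                "chrom": h.interval.chrom,
                "start": h.interval.start + 1,  # reported 1-based inclusive
                "end": h.interval.end,
                "mismatches": h.score.effective_mismatches,
                "matched_bases": h.score.matched_bases,
                "gapped": h.score.gapped,
                "homology_pct": round(100 * h.score.reported_homology, 1),
                "distance": h.distance,
                "within_reactive": h.within_reactive,
                "in_filled_region": h.in_filled_region,
                "k": h.score.k,
            }
        )
    return pd.DataFrame(rows, columns=_TSV_COLUMNS)


def write_hits_tsv(hits: Sequence[RevCompHit], path: str | Path) -> None:
    hits_to_frame(hits).to_csv(path, sep="\t", index=False)


def read_hits_tsv(path: str | Path) -> List[RevCompHit]:
    df = pd.read_csv(path, sep="\t")
    hits = []
    for row in df.itertuples(index=False):
        iv = GenomicInterval(str(row.chrom), int(row.start) - 1, int(row.end))
        score = AlignmentScore(
            int(row.mismatches), int(row.matched_bases), bool(row.gapped), int(row.k)
        )
        hits.append(
            RevCompHit(
                interval=iv,
                score=score,
                distance=int(row.distance),
                within_reactive=bool(row.within_reactive),
                haplotype=str(row.haplotype),
                in_filled_region=bool(row.in_filled_region),
            )
        )
    return hits


def write_hits_bed(hits: Sequence[RevCompHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.interval.chrom}\t{h.interval.start}\t{h.interval.end}\t"
                f"mm{h.score.effective_mismatches}{'g' if h.score.gapped else ''}\t"
                f"{h.score.effective_mismatches}\t.\n"
            )
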