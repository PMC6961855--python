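"""Ground-truth synthetic landscapes.

Generates megabase-scale haplotype landscapes with a known inverted-repeat
architecture so every stage of the analysis can be tested without any
sequence download.  The default recipe emulates the study conditions for
a single landscape: an i.i.d. 50%-GC background of 1,000,001 bp with the
query motif at its centre, 90 planted inverted approximate copies with
mismatch-class counts (1, 3, 11, 20, 55) at 2..6 effective mismatches,
the single 2-mismatch copy being a gapped 14-of-15 match 1,366 bp
downstream of the query, plus per-haplotype phase-block structure with on
average 26 low-coverage discontinuities (range 18-30, drawn as
18 + Binomial(12, 2/3)) and a 97.6% covered fraction.

Because a random megabase necessarily contains spurious approximate
reverse complements (about 10^2 seeded-mode and 10^3 exhaustive-mode loci
are expected by chance), the generator *scrubs* the background after
planting: it repeatedly rescans and makes single-base edits that break
every spurious seeded-mode locus landscape-wide and every spurious
exhaustive-mode locus within 2 kb of a plant, so truth labels are
unambiguous - a seeded scan returns exactly the planted hits, and an
exhaustive scan recovers every plant with exactly its intended score.

All randomness flows from one top-level seed through named substreams
(background, planting, scrubbing, absences, per-haplotype phase), so any
component is reproducible in isolation and identical spec + seed gives
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .landscape import HaplotypeLandscape, PhaseBlock
from .regions import GenomicInterval
from .scanner import (
    QueryMotif,
    RevCompHit,
    ScanParams,
    merge_hits,
    scan_landscape,
    _candidate_table,
    _encode,
)
from .sequence import (
    AlignmentScore,
    align_revcomp,
    alignment_matches,
    max_exact_run,
    reverse_complement,
    _mismatch,
)

# Fixed default query motif: an arbitrary non-palindromic 15-mer with no two
# adjacent equal bases (which keeps shifted self-alignments uninformative).
# Real-genome runs read the query from FASTA at user-supplied coordinates.
DEFAULT_QUERY = "ACTGAGTCATCAGCT"

# Reference coordinates mirroring the canonical query locus (0-based start).
DEFAULT_QUERY_REF_START = 55_174_772
DEFAULT_CHROM = "chr7"

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class SimulationError(RuntimeError):
    """A planting or scrubbing constraint could not be satisfied."""


@dataclass(frozen=True)
class PlantSpec:
    """One planted inverted (or direct) approximate copy.

    ``distance`` is the signed nearest-edge separation from the query
    (positive = downstream); None means "sample uniformly".  ``anchor``
    plants are never dropped when haplotype-specific absences are drawn.
    """

    distance: Optional[int]
    m: int
    gapped: bool = False
    orientation: str = "inverted"
    anchor: bool = False


@dataclass(frozen=True)
class PhaseSpec:
    """Phase-block recipe; ``n_discontinuities`` None draws 18 + Binomial(12, 2/3)."""

    n_discontinuities: Optional[int] = None
    covered_fraction: float = 0.976
    phased_probability: float = 0.85


def default_plants() -> List[PlantSpec]:
    """The Table-1-like landscape: classes (1, 3, 11, 20, 55) at 2..6 mismatches."""
    plants = [PlantSpec(distance=1_366, m=2, gapped=True, anchor=True)]
    for m, n in ((3, 3), (4, 11), (5, 20), (6, 55)):
        plants += [PlantSpec(distance=None, m=m) for _ in range(n)]
    return plants


@dataclass
class SyntheticLandscapeSpec:
    """Full recipe for a ground-truth landscape set."""

    seed: int
    length: int = 1_000_001
    gc: float = 0.5
    query: str = DEFAULT_QUERY
    chrom: str = DEFAULT_CHROM
    query_ref_start: int = DEFAULT_QUERY_REF_START
    plants: List[PlantSpec] = field(default_factory=default_plants)
    phase: PhaseSpec = field(default_factory=PhaseSpec)
    min_distance: int = 5_000
    seed_word: Optional[int] = 8  # plants keep an exact run >= this; None disables
    scan_params: ScanParams = field(default_factory=ScanParams)

    @property
    def k(self) -> int:
        return len(self.query)

    @property
    def query_rel_start(self) -> int:
        return self.length // 2 - self.k // 2

    @property
    def origin(self) -> GenomicInterval:
        start = self.query_ref_start - self.query_rel_start
        return GenomicInterval(self.chrom, start, start + self.length)

    @property
    def query_interval(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.query_ref_start, self.query_ref_start + self.k
        )


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one plant, written alongside the generated FASTA."""

    interval: GenomicInterval
    m: int
    gapped: bool
    orientation: str
    distance: int
    anchor: bool = False
    haplotype: str = ""


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([stream, seed])


def generate_background(length: int, gc: float, seed) -> str:
    """i.i.d. background with P(G) = P(C) = gc/2; deterministic given the seed."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if not 0 <= gc <= 1:
        raise ValueError("gc must be in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    at, gcp = (1 - gc) / 2, gc / 2
    codes = rng.choice(4, size=length, p=[at, gcp, gcp, at])
    return _BASES[codes].tobytes().decode("ascii")


# ---------------------------------------------------------------------------
# planting
# ---------------------------------------------------------------------------


def _mutate_base(base: str, rng: np.random.Generator) -> str:
    others = [b for b in "ACGT" if b != base]
    return others[rng.integers(0, 3)]


def _build_segment(
    query: str,
    m: int,
    gapped: bool,
    rng: np.random.Generator,
    seed_word: Optional[int],
) -> str:
    """A target segment whose best alignment to reverse_complement(query) has
    exactly m effective mismatches, keeping an exact run >= seed_word."""
    k = len(query)
    rc = reverse_complement(query)
    if not gapped:
        w = seed_word or 1
        run_start = int(rng.integers(0, k - w + 1))
        mutable = [j for j in range(k) if not run_start <= j < run_start + w]
        if m > len(mutable):
            raise SimulationError(
                f"cannot place {m} substitutions outside a {w}-bp exact run in a {k}-mer"
            )
        seg = list(rc)
        for j in rng.choice(len(mutable), size=m, replace=False):
            pos = mutable[int(j)]
            seg[pos] = _mutate_base(seg[pos], rng)
        return "".join(seg)
    # gapped: deletion-type segment of length k-1 (one query base unaligned)
    if m < 2:
        raise SimulationError("a gapped plant has >= 2 effective mismatches")
    subs = m - 2
    w = seed_word or 1
    # keep the gap >= 2 columns away from both motif ends: a near-boundary
    # gap admits an ungapped reinterpretation of the same locus with as few
    # substitutions as the gapped score, which would win the merge tie-break
    valid_g = [g for g in range(2, k - 2) if max(g, k - 1 - g) >= w]
    if not valid_g:
        raise SimulationError(f"no gap position leaves an exact run >= {w} in a {k}-mer")
    g = int(valid_g[rng.integers(0, len(valid_g))])
    seg = list(rc[:g] + rc[g + 1 :])  # perfect 14-of-15 gapped match
    if g >= w:
        run_lo, run_hi = 0, w  # run in the prefix
    else:
        run_lo, run_hi = g, g + w  # run in the suffix (segment coordinates)
    mutable = [j for j in range(len(seg)) if not run_lo <= j < run_hi]
    if subs > len(mutable):
        raise SimulationError(
            f"cannot place {subs} substitutions outside the exact run of a gapped plant"
        )
    for j in rng.choice(len(mutable), size=subs, replace=False):
        pos = mutable[int(j)]
        seg[pos] = _mutate_base(seg[pos], rng)
    return "".join(seg)


def _local_merged_hits(
    seq: str, query: str, lo: int, hi: int, max_mm: int = 6
) -> List[RevCompHit]:
    """Merged hit list for a slice of a raw sequence (coordinates are slice-absolute)."""
    lo, hi = max(0, lo), min(len(seq), hi)
    enc = _encode(seq[lo:hi])
    q = _encode(reverse_complement(query))
    hits = []
    for start, tlen, eff, matched, gapped, gidx in _candidate_table(enc, q, max_mm):
        iv = GenomicInterval("rel", lo + start, lo + start + tlen)
        score = AlignmentScore(eff, matched, gapped, len(query), gidx)
        hits.append(RevCompHit(iv, score, 0, True))
    return merge_hits(hits)


def plant_inverted_repeat(
    seq: str,
    query: str,
    position: int,
    m: int,
    gapped: bool = False,
    rng: Optional[np.random.Generator] = None,
    orientation: str = "inverted",
    seed_word: Optional[int] = 8,
    max_tries: int = 40,
) -> Tuple[str, TruthRecord]:
    """Write one approximate copy into ``seq`` at ``position`` and verify it.

    For inverted plants the realised best local alignment is re-scored
    after writing; if background context produces a better-scoring
    alternative alignment, the mutation layout is re-drawn (up to
    ``max_tries``) so that the truth label is exact.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    k = len(query)
    if orientation == "direct":
        seg = list(query)
        for j in rng.choice(k, size=m, replace=False):
            seg[int(j)] = _mutate_base(seg[int(j)], rng)
        segment = "".join(seg)
        new_seq = seq[:position] + segment + seq[position + len(segment) :]
        iv = GenomicInterval("rel", position, position + len(segment))
        return new_seq, TruthRecord(iv, m, gapped, "direct", 0)
    if orientation != "inverted":
        raise ValueError(f"unknown orientation {orientation!r}")

    rc = reverse_complement(query)
    for attempt in range(max_tries):
        segment = _build_segment(query, m, gapped, rng, seed_word)
        cand = seq[:position] + segment + seq[position + len(segment) :]
        if gapped or attempt > 0:
            # pin the flanking background bases away from the motif ends so
            # that no shifted window frames the plant with an equal score
            chars = list(cand)
            if position > 0 and chars[position - 1] == rc[0]:
                chars[position - 1] = _mutate_base(rc[0], rng)
            right = position + len(segment)
            if right < len(chars) and chars[right] == rc[-1]:
                chars[right] = _mutate_base(rc[-1], rng)
            cand = "".join(chars)
        iv = GenomicInterval("rel", position, position + len(segment))
        pad = 2 * k
        local = _local_merged_hits(cand, query, position - pad, position + len(segment) + pad)
        own = [h for h in local if h.interval.overlaps(iv)]
        if (
            len(own) == 1
            and own[0].score.effective_mismatches == m
            and own[0].score.gapped == gapped
            and own[0].interval.start == position
            and own[0].interval.end == position + len(segment)
        ):
            if seed_word is None or max_exact_run(query, segment) >= seed_word:
                return cand, TruthRecord(iv, m, gapped, "inverted", 0)
    raise SimulationError(
        f"could not realise a clean {'gapped ' if gapped else ''}{m}-mismatch plant "
        f"at position {position} after {max_tries} attempts"
    )


# ---------------------------------------------------------------------------
# scrubbing
# ---------------------------------------------------------------------------


def _matched_target_positions(query: str, target: str) -> List[int]:
    """Target indices that are exact matches in the best alignment."""
    sc = align_revcomp(query, target)
    rc = reverse_complement(query)
    t = target.upper()
    k = len(query)
    pos: List[int] = []
    if not sc.gapped:
        pos = [j for j in range(k) if not _mismatch(rc[j], t[j])]
    elif len(t) == k - 1:
        g = sc.gap_index
        pos = [j for j in range(g) if not _mismatch(rc[j], t[j])]
        pos += [j - 1 for j in range(g + 1, k) if not _mismatch(rc[j], t[j - 1])]
    else:
        g = sc.gap_index
        pos = [j for j in range(g) if not _mismatch(rc[j], t[j])]
        pos += [j + 1 for j in range(g, k) if not _mismatch(rc[j], t[j + 1])]
    return pos


def _truth_overlap(hit: RevCompHit, truths: Sequence[TruthRecord]) -> bool:
    return any(hit.interval.overlaps(t.interval) for t in truths)


def _near_truth(hit: RevCompHit, truths: Sequence[TruthRecord], radius: int) -> bool:
    return any(
        hit.interval.chrom == t.interval.chrom
        and hit.interval.start < t.interval.end + radius
        and t.interval.start - radius < hit.interval.end
        for t in truths
    )


def _scrub(
    seq: str,
    spec: SyntheticLandscapeSpec,
    truths: Sequence[TruthRecord],
    rng: np.random.Generator,
    clean_radius: int = 2_000,
    max_iter: int = 60,
) -> str:
    """Break spurious hits: all seeded-mode loci, and exhaustive loci near plants.

    Each pass rescans the landscape and makes one base edit per offending
    locus (a matched alignment position near the hit centre, changed to a
    different base), never touching a planted segment or the query.
    """
    protected: List[Tuple[int, int]] = [
        (t.interval.start, t.interval.end) for t in truths
    ]
    q_rel = spec.query_rel_start
    protected.append((q_rel, q_rel + spec.k))
    seed_word = spec.scan_params.seed_word
    chars = list(seq)
    for _ in range(max_iter):
        s = "".join(chars)
        landscape = HaplotypeLandscape(
            name="scrub",
            sequence=s,
            origin=GenomicInterval("rel", 0, len(s)),
            blocks=[],
        )
        query = QueryMotif(
            spec.query, GenomicInterval("rel", q_rel, q_rel + spec.k)
        )
        params = replace(spec.scan_params, mode="exhaustive")
        rel_truths = [
            replace(t, interval=GenomicInterval("rel", t.interval.start, t.interval.end))
            for t in truths
        ]
        offenders = []
        for h in scan_landscape(landscape, query, params):
            if _truth_overlap(h, rel_truths):
                continue
            target = s[h.interval.start : h.interval.end]
            is_seeded = max_exact_run(spec.query, target) >= seed_word
            if is_seeded or _near_truth(h, rel_truths, clean_radius):
                offenders.append(h)
        if not offenders:
            return "".join(chars)
        for h in offenders:
            target = s[h.interval.start : h.interval.end]
            matched = _matched_target_positions(spec.query, target)
            centre = len(target) // 2
            matched.sort(key=lambda p: abs(p - centre))
            for p in matched:
                pos = h.interval.start + p
                if any(a <= pos < b for a, b in protected):
                    continue
                chars[pos] = _mutate_base(chars[pos], rng)
                break
    raise SimulationError("background scrubbing did not converge")


# ---------------------------------------------------------------------------
# landscape assembly
# ---------------------------------------------------------------------------


def _sample_one_position(
    spec: SyntheticLandscapeSpec,
    plant: PlantSpec,
    occupied: List[Tuple[int, int]],
    rng: np.random.Generator,
) -> int:
    """A non-overlapping start offset for one plant (fixed or sampled distance)."""
    k = spec.k
    q_lo, q_hi = spec.query_rel_start, spec.query_rel_start + k
    max_d = min(
        spec.scan_params.reactive_distance - 1_000,
        q_lo - k - 100,
        spec.length - q_hi - k - 100,
    )
    if max_d <= spec.min_distance:
        raise SimulationError("landscape too short for the requested plant distances")
    seglen = k - 1 if plant.gapped else k
    for _ in range(2_000):
        if plant.distance is not None:
            d = plant.distance
        else:
            d = int(rng.integers(spec.min_distance, max_d + 1))
            if rng.random() < 0.5:
                d = -d
        start = q_hi + d if d >= 0 else q_lo - abs(d) - seglen
        bad = (
            start < 0
            or start + seglen > spec.length
            or any(start - 60 < b and a < start + seglen + 60 for a, b in occupied)
        )
        if bad:
            if plant.distance is not None:
                raise SimulationError(f"plant at fixed distance {d} cannot be placed")
            continue
        return start
    raise SimulationError("could not place a plant without overlap")


def generate_master(
    spec: SyntheticLandscapeSpec,
) -> Tuple[HaplotypeLandscape, List[TruthRecord]]:
    """The scrubbed master landscape containing every plant, plus its truth records."""
    rng_bg = _rng(spec.seed, 1)
    rng_plant = _rng(spec.seed, 2)
    rng_scrub = _rng(spec.seed, 3)
    seq = generate_background(spec.length, spec.gc, rng_bg)
    q_rel = spec.query_rel_start
    seq = seq[:q_rel] + spec.query.upper() + seq[q_rel + spec.k :]

    q_lo, q_hi = q_rel, q_rel + spec.k
    occupied: List[Tuple[int, int]] = [(q_lo - 60, q_hi + 60)]
    truths: List[TruthRecord] = []
    for plant in spec.plants:
        # a position whose local background frustrates an exact-score plant
        # (a chance overlapping alignment near the homology floor) is
        # abandoned and resampled rather than fought
        for _ in range(25):
            start = _sample_one_position(spec, plant, occupied, rng_plant)
            try:
                seq, rec = plant_inverted_repeat(
                    seq,
                    spec.query,
                    start,
                    plant.m,
                    plant.gapped,
                    rng_plant,
                    plant.orientation,
                    spec.seed_word,
                    max_tries=12 if plant.distance is None else 60,
                )
            except SimulationError:
                if plant.distance is not None:
                    raise
                continue
            break
        else:
            raise SimulationError(f"could not realise plant {plant} at any sampled position")
        seglen = len(rec.interval)
        occupied.append((start, start + seglen))
        dist = start - q_hi if start >= q_rel else q_lo - (start + seglen)
        truths.append(replace(rec, distance=dist, anchor=plant.anchor))

    inverted = [t for t in truths if t.orientation == "inverted"]
    seq = _scrub(seq, spec, inverted, rng_scrub)

    origin = spec.origin
    abs_truths = [
        replace(
            t,
            interval=GenomicInterval(
                origin.chrom, origin.start + t.interval.start, origin.start + t.interval.end
            ),
        )
        for t in truths
    ]
    landscape = HaplotypeLandscape(
        name="master", sequence=seq, origin=origin, blocks=[]
    )
    return landscape, abs_truths


def plant_phase_blocks(
    landscape: HaplotypeLandscape,
    n_discontinuities: int,
    covered_target: float,
    seed,
    phased_probability: float = 0.85,
    protect: Optional[GenomicInterval] = None,
) -> HaplotypeLandscape:
    """Insert low-coverage discontinuities totalling (1 - covered_target) of the span.

    The block containing ``protect`` (by default the landscape centre,
    standing for the query locus) is kept covered and phased.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if not 0 < covered_target <= 1:
        raise ValueError("covered_target must be in (0, 1]")
    L = len(landscape.origin)
    origin = landscape.origin
    if protect is None:
        mid = origin.start + L // 2
        protect = GenomicInterval(origin.chrom, max(origin.start, mid - 2_500), min(origin.end, mid + 2_500))
    if n_discontinuities == 0:
        return replace(
            landscape, blocks=[PhaseBlock(origin, phased=True)]
        )
    total_gap = int(round((1 - covered_target) * L))
    min_gap = 30
    if total_gap < n_discontinuities * min_gap:
        raise SimulationError(
            f"{n_discontinuities} gaps of >= {min_gap} bp do not fit in {total_gap} bp"
        )
    extra = rng.multinomial(
        total_gap - n_discontinuities * min_gap,
        [1 / n_discontinuities] * n_discontinuities,
    )
    lengths = [min_gap + int(e) for e in extra]
    for _ in range(500):
        starts = sorted(
            int(rng.integers(0, L - max(lengths))) for _ in range(n_discontinuities)
        )
        gaps = []
        ok = True
        for st, ln in zip(starts, lengths):
            iv = GenomicInterval(origin.chrom, origin.start + st, origin.start + st + ln)
            if iv.end > origin.end or iv.overlaps(protect):
                ok = False
                break
            if gaps and iv.start < gaps[-1].end + 200:
                ok = False
                break
            gaps.append(iv)
        if ok:
            break
    else:
        raise SimulationError("could not place phase discontinuities without overlap")
    blocks: List[PhaseBlock] = []
    cursor = origin.start
    for gap in gaps + [GenomicInterval(origin.chrom, origin.end, origin.end + 1)]:
        if gap.start > cursor:
            iv = GenomicInterval(origin.chrom, cursor, gap.start)
            phased = bool(rng.random() < phased_probability) or iv.overlaps(protect)
            blocks.append(PhaseBlock(iv, phased=phased))
        cursor = max(cursor, min(gap.end, origin.end))
    return replace(landscape, blocks=blocks)


def draw_discontinuity_count(rng: np.random.Generator) -> int:
    """18 + Binomial(12, 2/3): mean 26, range 18-30."""
    return 18 + int(rng.binomial(12, 2 / 3))


def generate_haplotype_set(
    spec: SyntheticLandscapeSpec,
    n_haplotypes: int = 5,
    absence_count: int = 21,
    seed: Optional[int] = None,
) -> Tuple[Dict[str, HaplotypeLandscape], pd.DataFrame]:
    """n haplotypes sharing the master plant set minus haplotype-specific absences.

    ``absence_count`` distinct non-anchor plant loci are each dropped from
    at least one (and at most n-1) randomly chosen haplotypes, so every
    union locus survives somewhere.  Returns the landscapes plus a truth
    table with one row per (haplotype, plant) and a ``present`` flag.
    """
    if seed is not None:
        spec = replace(spec, seed=seed)
    master, truths = generate_master(spec)
    droppable = [i for i, t in enumerate(truths) if not t.anchor and t.orientation == "inverted"]
    if absence_count > len(droppable):
        raise ValueError(
            f"absence_count {absence_count} exceeds the {len(droppable)} droppable plants"
        )
    rng_abs = _rng(spec.seed, 4)
    absent_loci = sorted(
        int(i) for i in rng_abs.choice(len(droppable), size=absence_count, replace=False)
    )
    missing: Dict[int, List[int]] = {}
    for j in absent_loci:
        n_missing = int(rng_abs.integers(1, max(2, n_haplotypes)))
        haps = sorted(int(h) for h in rng_abs.choice(n_haplotypes, size=n_missing, replace=False))
        missing[droppable[j]] = haps

    landscapes: Dict[str, HaplotypeLandscape] = {}
    rows = []
    for h in range(n_haplotypes):
        name = f"hap{h + 1}"
        rng_h = _rng(spec.seed, 100 + h)
        chars = list(master.sequence)
        for ti, haps in missing.items():
            if h not in haps:
                continue
            t = truths[ti]
            lo = master.offset_of(t.interval.start)
            hi = master.offset_of(t.interval.end)
            for _ in range(60):
                repl = generate_background(hi - lo, spec.gc, rng_h)
                trial = chars[:lo] + list(repl) + chars[hi:]
                s = "".join(trial)
                local = _local_merged_hits(s, spec.query, lo - 2 * spec.k, hi + 2 * spec.k)
                if not any(
                    hit.interval.overlaps(GenomicInterval("rel", lo, hi)) for hit in local
                ):
                    chars = trial
                    break
            else:
                raise SimulationError(f"could not erase plant {t.interval} from {name}")
        seq_h = "".join(chars)
        land = HaplotypeLandscape(
            name=name, sequence=seq_h, origin=master.origin, blocks=[]
        )
        n_disc = spec.phase.n_discontinuities
        if n_disc is None:
            n_disc = draw_discontinuity_count(rng_h)
        land = plant_phase_blocks(
            land,
            n_disc,
            spec.phase.covered_fraction,
            rng_h,
            spec.phase.phased_probability,
            protect=GenomicInterval(
                spec.chrom, spec.query_ref_start - 2_500, spec.query_ref_start + spec.k + 2_500
            ),
        )
        landscapes[name] = land
        for ti, t in enumerate(truths):
            present = not (ti in missing and h in missing[ti])
            rows.append(
                {
                    "haplotype": name,
                    "chrom": t.interval.chrom,
                    "start": t.interval.start + 1,
                    "end": t.interval.end,
                    "m": t.m,
                    "gapped": t.gapped,
                    "orientation": t.orientation,
                    "distance": t.distance,
                    "anchor": t.anchor,
                    "present": present,
                }
            )
    truth_table = pd.DataFrame(rows)
    return landscapes, truth_table
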