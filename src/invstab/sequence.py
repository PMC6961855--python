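"""Nucleotide-string primitives.

Reverse complementation, sliding-window bookkeeping, and the gap-penalised
reverse-complement alignment score that the instability model is built on.

Scoring conventions
-------------------
A candidate locus is compared against the reverse complement of the query
motif.  Besides the ungapped alignment, every alignment carrying a single
1-bp gap (one unaligned query base, or one unaligned target base) is
evaluated.  A gapped alignment pays a fixed penalty of two effective
mismatches on top of its substitution mismatches — the strained geometry of
the folded-back intermediate is assumed to make a bulged alignment roughly
as destabilising as two substitutions.  Reported homology counts matched
bases only, over the motif length k (a 14-of-15 gapped match is 93%
homologous but carries 2 effective mismatches).

Any non-ACGT character (ambiguity codes, N fill-in) always scores as a
substitution mismatch, on both sides of the comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

from Bio.Data.IUPACData import ambiguous_dna_letters
from Bio.Seq import reverse_complement as _bio_revcomp

GAP_MISMATCH_PENALTY = 2
_IUPAC = set(ambiguous_dna_letters.upper())  # ACGT + ambiguity codes, incl. N
_ACGT = frozenset("ACGT")


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement; ambiguity codes map to their IUPAC complements."""
    if not seq:
        raise ValueError("empty sequence")
    s = seq.upper()
    bad = set(s) - _IUPAC
    if bad:
        raise ValueError(f"non-IUPAC characters in sequence: {sorted(bad)}")
    return str(_bio_revcomp(s))


def sliding_windows(seq_length: int, k: int, step: int = 1) -> List[int]:
    """Start offsets of every k-bp window fitting in a sequence of the given length.

    A 99-bp exon admits exactly 85 fully-exonic 15-bp windows at step 1.
    """
    if k < 1 or step < 1:
        raise ValueError("k and step must be >= 1")
    if seq_length < k:
        return []
    return list(range(0, seq_length - k + 1, step))


@dataclass(frozen=True)
class AlignmentScore:
    """Score of one reverse-complement alignment.

    ``effective_mismatches`` is the substitution count plus 2 for a single
    1-bp gap; ``matched_bases`` counts exact matches only; ``gap_index`` is
    the 0-based alignment column of the gap (None when ungapped).
    """

    effective_mismatches: int
    matched_bases: int
    gapped: bool
    k: int
    gap_index: Optional[int] = None

    @property
    def reported_homology(self) -> float:
        """Matched bases as a fraction of the motif length k."""
        return self.matched_bases / self.k


def _mismatch(a: str, b: str) -> bool:
    # non-ACGT on either side always mismatches, even N vs N
    return a != b or a not in _ACGT or b not in _ACGT


def align_revcomp(query: str, target: str) -> AlignmentScore:
    """Best single-gap-or-ungapped alignment of reverse_complement(query) to target.

    The target window must have length k (ungapped comparison), k-1 (one
    query base unaligned across a 1-bp gap) or k+1 (one target base
    unaligned).  Among equal-scoring alignments the ungapped one wins, then
    the leftmost gap position.
    """
    k = len(query)
    rc = reverse_complement(query)
    t = target.upper()
    n = len(t)
    if n == k:
        mm = sum(_mismatch(a, b) for a, b in zip(rc, t))
        return AlignmentScore(mm, k - mm, False, k)
    if n == k - 1:
        # one query base (alignment column g) is unaligned
        best = None
        for g in range(k):
            sub = sum(_mismatch(rc[j], t[j]) for j in range(g)) + sum(
                _mismatch(rc[j], t[j - 1]) for j in range(g + 1, k)
            )
            if best is None or sub < best[0]:
                best = (sub, g)
        sub, g = best
        return AlignmentScore(sub + GAP_MISMATCH_PENALTY, (k - 1) - sub, True, k, g)
    if n == k + 1:
        # one target base (offset g) is unaligned
        best = None
        for g in range(k + 1):
            sub = sum(_mismatch(rc[j], t[j]) for j in range(g)) + sum(
                _mismatch(rc[j], t[j + 1]) for j in range(g, k)
            )
            if best is None or sub < best[0]:
                best = (sub, g)
        sub, g = best
        return AlignmentScore(sub + GAP_MISMATCH_PENALTY, k - sub, True, k, g)
    raise ValueError(f"target length {n} outside {{k-1, k, k+1}} for k={k}")


def alignment_matches(query: str, target: str) -> List[bool]:
    """Per-column exact-match flags of the best alignment, with a break at the gap.

    The gap column is reported as ``False`` so that an exact run can never
    span the gap; used by the seeded-scan filter.
    """
    score = align_revcomp(query, target)
    rc = reverse_complement(query)
    t = target.upper()
    k = len(query)
    if not score.gapped:
        return [not _mismatch(a, b) for a, b in zip(rc, t)]
    g = score.gap_index
    if len(t) == k - 1:
        cols = [not _mismatch(rc[j], t[j]) for j in range(g)]
        cols.append(False)
        cols += [not _mismatch(rc[j], t[j - 1]) for j in range(g + 1, k)]
    else:
        cols = [not _mismatch(rc[j], t[j]) for j in range(g)]
        cols.append(False)
        cols += [not _mismatch(rc[j], t[j + 1]) for j in range(g, k)]
    return cols


def max_exact_run(query: str, target: str) -> int:
    """Length of the longest contiguous exact-match run in the best alignment."""
    best = run = 0
    for m in alignment_matches(query, target):
        run = run + 1 if m else 0
        best = max(best, run)
    return best


def homology_floor_check(score: AlignmentScore, max_mismatches: int = 6) -> bool:
    """True iff the hit clears the reactivity floor (<= 6 effective mismatches = >= 60% homology)."""
    return score.effective_mismatches <= max_mismatches
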