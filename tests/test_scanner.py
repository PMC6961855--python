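"""Reverse-complement scanning: plants, orientation, merging, modes, density."""

import numpy as np
import pytest
from helpers import mk_hit

from invstab.landscape import HaplotypeLandscape
from invstab.regions import GenomicInterval
from invstab.scanner import (
    QueryMotif,
    RevCompHit,
    ScanParams,
    classify_by_mismatch,
    compare_hit_presence,
    merge_hits,
    scan_landscape,
)
from invstab.sequence import AlignmentScore, reverse_complement
from invstab.simulate import generate_background

QUERY = "ACTGAGTCATCAGCT"


def ac_landscape(length=12_001, inserts=None, name="tiny"):
    """Deterministic homology-free background ('AC' repeats) with the query at
    the centre and optional planted segments; returns (landscape, query)."""
    seq = list("AC" * (length // 2 + 1))[:length]
    q_rel = length // 2
    seq[q_rel : q_rel + 15] = QUERY
    for pos, segment in (inserts or {}).items():
        seq[pos : pos + len(segment)] = segment
    land = HaplotypeLandscape(
        name=name, sequence="".join(seq), origin=GenomicInterval("chrT", 0, length)
    )
    query = QueryMotif(QUERY, GenomicInterval("chrT", q_rel, q_rel + 15))
    return land, query


class TestScanExamples:
    def test_exact_planted_copy(self):
        rc = reverse_complement(QUERY)
        land, query = ac_landscape(inserts={6_000 + 15 + 1_000: rc})
        for mode in ("exhaustive", "seeded"):
            hits = scan_landscape(land, query, ScanParams(mode=mode))
            assert len(hits) == 1
            assert hits[0].score.effective_mismatches == 0
            assert hits[0].distance == 1_000
            assert hits[0].within_reactive

    def test_seven_substitutions_below_floor(self):
        seg = list(reverse_complement(QUERY))
        for j in (0, 2, 4, 6, 8, 10, 12, 13, 14):  # 9 substitutions
            seg[j] = "A" if seg[j] != "A" else "G"
        land, query = ac_landscape(inserts={7_500: "".join(seg)})
        assert scan_landscape(land, query, ScanParams(mode="exhaustive")) == []

    def test_direct_copy_not_reported(self):
        land, query = ac_landscape(inserts={7_500: QUERY})
        assert scan_landscape(land, query, ScanParams(mode="exhaustive")) == []

    def test_hit_beyond_reporting_dropped_between_reactive_and_reporting_flagged(self):
        rc = reverse_complement(QUERY)
        q_end = 6_000 + 15
        land, query = ac_landscape(
            inserts={q_end + 1_000: rc, q_end + 3_000: rc, q_end + 4_500: rc}
        )
        params = ScanParams(reactive_distance=2_000, reporting_distance=4_000)
        hits = scan_landscape(land, query, params)
        assert [h.distance for h in hits] == [1_000, 3_000]
        assert [h.within_reactive for h in hits] == [True, False]

    def test_self_exclusion_radius(self):
        rc = reverse_complement(QUERY)
        land, query = ac_landscape(inserts={6_000 + 15 + 100: rc})
        assert len(scan_landscape(land, query, ScanParams())) == 1
        assert scan_landscape(land, query, ScanParams(self_exclusion=200)) == []

    def test_window_with_n_run_skipped(self):
        rc = reverse_complement(QUERY)
        broken = rc[:5] + "NN" + rc[7:]
        land, query = ac_landscape(inserts={7_000: broken, 8_000: rc})
        hits = scan_landscape(land, query, ScanParams(mode="exhaustive"))
        assert len(hits) == 1
        assert hits[0].interval.start == 8_000

    def test_single_n_counts_as_one_mismatch(self):
        rc = reverse_complement(QUERY)
        land, query = ac_landscape(inserts={7_000: rc[:5] + "N" + rc[6:]})
        hits = scan_landscape(land, query, ScanParams(mode="exhaustive"))
        assert len(hits) == 1
        assert hits[0].score.effective_mismatches == 1

    def test_variant_query_warns(self):
        land, query = ac_landscape()
        other = QueryMotif(
            reverse_complement(QUERY), query.interval
        )  # sequence disagrees with the landscape
        with pytest.warns(UserWarning, match="differs"):
            scan_landscape(land, other, ScanParams())

    def test_empty_landscape_rejected(self):
        land, query = ac_landscape()
        land.sequence = ""
        with pytest.raises(ValueError):
            scan_landscape(land, query, ScanParams())


class TestMergeHits:
    def test_overlapping_candidates_collapse_to_fewest_mismatches(self):
        cands = [
            mk_hit(100, 115, 0),
            mk_hit(100, 114, 2, gapped=True),
            mk_hit(99, 115, 2, gapped=True),
        ]
        merged = merge_hits(cands)
        assert len(merged) == 1
        assert merged[0].score.effective_mismatches == 0
        assert not merged[0].score.gapped

    def test_tie_prefers_ungapped_then_smallest_start(self):
        cands = [mk_hit(101, 115, 3, gapped=True), mk_hit(100, 115, 3)]
        assert merge_hits(cands)[0].interval.start == 100
        cands = [mk_hit(101, 116, 3), mk_hit(100, 115, 3)]
        assert merge_hits(cands)[0].interval.start == 100

    def test_disjoint_hits_kept(self):
        cands = [mk_hit(100, 115, 2), mk_hit(215, 230, 4)]
        assert len(merge_hits(cands)) == 2

    def test_empty(self):
        assert merge_hits([]) == []


class TestClassify:
    def test_empty(self):
        counts = classify_by_mismatch([])
        assert counts == {2: 0, 3: 0, 4: 0, 5: 0, 6: 0, "total": 0}

    def test_single_two_mismatch_hit(self):
        counts = classify_by_mismatch([mk_hit(0, 15, 2)])
        assert counts[2] == 1 and counts["total"] == 1

    def test_class_zero_reported_separately(self):
        counts = classify_by_mismatch([mk_hit(0, 15, 0), mk_hit(100, 115, 6)])
        assert counts[0] == 1 and counts[6] == 1 and counts["total"] == 2

    def test_beyond_reactive_excluded(self):
        far = mk_hit(0, 15, 3)
        far = RevCompHit(far.interval, far.score, 500_000, within_reactive=False)
        assert classify_by_mismatch([far])["total"] == 0


class TestPresence:
    def test_identical_haplotypes_no_absences(self):
        hits = [mk_hit(100, 115, 2), mk_hit(300, 315, 5)]
        matrix, absent = compare_hit_presence({"a": hits, "b": hits})
        assert absent == 0
        assert matrix.shape == (2, 2)
        assert matrix.all().all()

    def test_single_haplotype_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            compare_hit_presence({"a": []})

    def test_constructed_absences_counted(self):
        shared = [mk_hit(100 + 50 * i, 115 + 50 * i, 4) for i in range(5)]
        a = shared
        b = shared[:3]  # two loci absent from b
        matrix, absent = compare_hit_presence({"a": a, "b": b})
        assert absent == 2
        assert len(matrix) == 5


class TestModes:
    def test_seeded_subset_of_exhaustive_with_identical_scores(self, small_master, small_query):
        land, _ = small_master
        ex = scan_landscape(land, small_query, ScanParams(mode="exhaustive"))
        se = scan_landscape(land, small_query, ScanParams(mode="seeded"))
        ex_keys = {
            (h.interval.start, h.interval.end, h.score.effective_mismatches, h.score.gapped)
            for h in ex
        }
        se_keys = {
            (h.interval.start, h.interval.end, h.score.effective_mismatches, h.score.gapped)
            for h in se
        }
        assert se_keys <= ex_keys
        assert len(se) < len(ex)

    def test_coordinate_equivariance_under_landscape_revcomp(self, small_master, small_spec):
        land, _ = small_master
        L = len(land.sequence)
        flipped = HaplotypeLandscape(
            name="flip", sequence=reverse_complement(land.sequence), origin=land.origin
        )
        q_rel = small_spec.query_rel_start
        f_start = land.origin.start + (L - (q_rel + 15))
        f_iv = GenomicInterval(land.origin.chrom, f_start, f_start + 15)
        f_query = QueryMotif(flipped.subseq(f_iv), f_iv)
        params = ScanParams(mode="exhaustive")
        orig = scan_landscape(land, QueryMotif(small_spec.query, small_spec.query_interval), params)
        flip = scan_landscape(flipped, f_query, params)
        assert len(orig) == len(flip)
        base = land.origin.start
        flip_by_pos = sorted(flip, key=lambda h: h.interval.start)
        for h in orig:
            rel_lo, rel_hi = h.interval.start - base, h.interval.end - base
            mapped = GenomicInterval(h.interval.chrom, base + L - rel_hi, base + L - rel_lo)
            partners = [
                f
                for f in flip_by_pos
                if f.interval.overlaps(mapped)
                and f.score.effective_mismatches == h.score.effective_mismatches
            ]
            assert partners, f"no flipped partner for {h.interval}"

    def test_background_density_matches_binomial_seed_expectation(self):
        """Seeded-mode hit count on random sequence agrees with the exact
        enumeration of match/mismatch patterns (mm <= 6 and an exact run >= 8)
        to within a factor of ~2, i.e. order 10^2 per +/-421 kb."""
        k, w, p = 15, 8, 0.25
        pats = np.arange(2**k, dtype=np.uint32)
        bits = ((pats[:, None] >> np.arange(k)) & 1).astype(bool)
        nmatch = bits.sum(axis=1)
        run = np.zeros(len(pats), dtype=int)
        cur = np.zeros(len(pats), dtype=int)
        for j in range(k):
            cur = np.where(bits[:, j], cur + 1, 0)
            run = np.maximum(run, cur)
        prob = p**nmatch * (1 - p) ** (k - nmatch)
        p_seed = prob[(nmatch >= k - 6) & (run >= w)].sum()

        reach = 100_000
        observed = 0
        for rep in range(10):
            L = 2 * reach + 1
            seq = generate_background(L, 0.5, 1_000 + rep)
            q_rel = L // 2
            seq = seq[:q_rel] + QUERY + seq[q_rel + 15 :]
            land = HaplotypeLandscape("bg", seq, GenomicInterval("chrT", 0, L))
            query = QueryMotif(QUERY, GenomicInterval("chrT", q_rel, q_rel + 15))
            hits = scan_landscape(
                land, query, ScanParams(reactive_distance=reach, reporting_distance=reach)
            )
            observed += len(hits)
        expected = 10 * 2 * reach * p_seed
        assert 0.5 <= observed / expected <= 2.0
        # per +/-421 kb this expectation is order 10^2
        assert 10 <= 2 * 421_000 * p_seed <= 1_000
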