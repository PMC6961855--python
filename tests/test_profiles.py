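"""Sliding-window exon profiles and in-silico structural variants."""

import numpy as np
import pytest

from invstab.landscape import HaplotypeLandscape
from invstab.model import InstabilityParams, hit_weight, raw_stability
from invstab.profiles import (
    SVEdit,
    WindowProfile,
    apply_sv_edit,
    perturbation_report,
    rank_window,
    window_profile,
)
from invstab.regions import GenomicInterval
from invstab.scanner import QueryMotif, ScanParams, scan_landscape
from invstab.sequence import reverse_complement

UNIFORM = InstabilityParams(kernel="uniform")


@pytest.fixture(scope="module")
def exon_landscape():
    """An 'AC'-repeat background (no chance homology) carrying a random
    A/C-only 99-bp exon and one planted inverted copy of the window that
    starts at exon base 52."""
    L = 30_001
    rng = np.random.default_rng(5)
    seq = list("AC" * (L // 2 + 1))[:L]
    exon_start = 10_000
    exon_seq = "".join("AC"[i] for i in rng.integers(0, 2, size=99))
    seq[exon_start : exon_start + 99] = exon_seq
    win52 = exon_seq[51:66]  # exon bases 52-66, 1-based
    plant_pos = 12_500
    seq[plant_pos : plant_pos + 15] = reverse_complement(win52)
    land = HaplotypeLandscape(
        name="exonland", sequence="".join(seq), origin=GenomicInterval("chrE", 0, L)
    )
    exon = GenomicInterval("chrE", exon_start, exon_start + 99)
    return land, exon


class TestWindowProfile:
    def test_99bp_exon_yields_85_windows(self, exon_landscape):
        land, exon = exon_landscape
        prof = window_profile(land, exon, k=15)
        assert len(prof.scores) == 85
        assert prof.window_indices == list(range(1, 86))

    def test_minimum_at_the_complementary_window(self, exon_landscape):
        land, exon = exon_landscape
        prof = window_profile(land, exon, k=15)
        scores = dict(zip(prof.window_indices, prof.scores))
        assert min(scores, key=scores.get) == 52
        assert scores[52] < 1.0
        # windows sharing no 9-of-15 overlap with the planted copy are untouched
        for w, s in scores.items():
            if abs(w - 52) > 6:
                assert s == 1.0

    def test_k20_profile_smoother_with_minimum_at_overlapping_windows(self, exon_landscape):
        land, exon = exon_landscape
        prof15 = window_profile(land, exon, k=15)
        prof20 = window_profile(land, exon, k=20, exonic_only=False)
        assert len(prof20.scores) == 99 + 20 - 1
        scores20 = dict(zip(prof20.window_indices, prof20.scores))
        best = min(scores20, key=scores20.get)
        assert 47 <= best <= 52  # windows containing the full planted 15-mer
        assert min(prof20.scores) > min(prof15.scores)  # dampened instability

    def test_exon_shorter_than_window_rejected(self, exon_landscape):
        land, _ = exon_landscape
        with pytest.raises(ValueError, match="shorter"):
            window_profile(land, GenomicInterval("chrE", 100, 110), k=15)


class TestRankWindow:
    def test_unique_maximum_is_top_window(self, exon_landscape):
        land, exon = exon_landscape
        prof = window_profile(land, exon, k=15)
        assert rank_window(prof, 52) == pytest.approx(100.0 / 85, abs=0.01)

    def test_all_equal_profile_uses_midrank(self):
        prof = WindowProfile(
            exon=GenomicInterval("chrE", 0, 99),
            k=15,
            window_indices=list(range(1, 86)),
            scores=[0.999] * 85,
        )
        for w in (1, 40, 85):
            assert rank_window(prof, w) == pytest.approx(50.0, abs=1.0)

    def test_seventeenth_most_unstable_of_85_is_top_twenty_percent(self):
        scores = [1.0 - 1e-6 * i for i in range(1, 86)]  # window 85 most unstable
        prof = WindowProfile(
            exon=GenomicInterval("chrE", 0, 99),
            k=15,
            window_indices=list(range(1, 86)),
            scores=scores,
        )
        # the window with the 17th largest instability
        assert rank_window(prof, 85 - 16) == pytest.approx(100 * 17 / 85)
        assert rank_window(prof, 85 - 16) <= 20.0

    def test_unknown_window_rejected(self, exon_landscape):
        land, exon = exon_landscape
        prof = window_profile(land, exon, k=15)
        with pytest.raises(KeyError):
            rank_window(prof, 99)


SV_IV = GenomicInterval.from_1based("chr7", 55_175_821, 55_176_820)


class TestSVEdits:
    def test_length_bookkeeping(self, small_master):
        land, _ = small_master
        L = len(land.sequence)
        assert len(apply_sv_edit(land, SVEdit("deletion", SV_IV)).sequence) == L - 1_000
        assert len(apply_sv_edit(land, SVEdit("duplication", SV_IV)).sequence) == L + 1_000
        assert len(apply_sv_edit(land, SVEdit("inversion", SV_IV)).sequence) == L

    def test_inversion_is_an_involution(self, small_master):
        land, _ = small_master
        twice = apply_sv_edit(apply_sv_edit(land, SVEdit("inversion", SV_IV)), SVEdit("inversion", SV_IV))
        assert twice.sequence == land.sequence

    def test_duplication_is_tandem(self, small_master):
        land, _ = small_master
        dup = apply_sv_edit(land, SVEdit("duplication", SV_IV))
        s, e = land.offset_of(SV_IV.start), land.offset_of(SV_IV.end)
        assert dup.sequence[e : e + 1_000] == land.sequence[s:e]

    def test_edit_outside_landscape_rejected(self, small_master):
        land, _ = small_master
        far = GenomicInterval("chr7", land.origin.end + 10, land.origin.end + 1_010)
        with pytest.raises(ValueError):
            apply_sv_edit(land, SVEdit("deletion", far))

    def _instability(self, land, query, params=UNIFORM):
        hits = scan_landscape(land, query, ScanParams())
        return raw_stability(hits, params)

    def test_deletion_and_inversion_remove_exactly_the_contained_contribution(
        self, small_master, small_query
    ):
        """Under the additive model with a distance-free kernel, deleting or
        inverting the block holding the top hit subtracts exactly its weight."""
        land, truths = small_master
        base = self._instability(land, small_query)
        anchor_hit = base.contributions[0][0]
        assert SV_IV.contains(anchor_hit.interval)
        w_anchor = hit_weight(anchor_hit, UNIFORM)
        for kind in ("deletion", "inversion"):
            edited = apply_sv_edit(land, SVEdit(kind, SV_IV))
            after = self._instability(edited, small_query)
            assert after.instability == pytest.approx(base.instability - w_anchor, rel=1e-9)

    def test_duplication_doubles_the_contained_contribution(self, small_master, small_query):
        land, _ = small_master
        base = self._instability(land, small_query)
        w_anchor = hit_weight(base.contributions[0][0], UNIFORM)
        edited = apply_sv_edit(land, SVEdit("duplication", SV_IV))
        after = self._instability(edited, small_query)
        assert after.instability == pytest.approx(base.instability + w_anchor, rel=1e-9)

    def test_inverted_copy_becomes_direct_and_vanishes(self, small_master, small_query):
        land, _ = small_master
        edited = apply_sv_edit(land, SVEdit("inversion", SV_IV))
        hits = scan_landscape(edited, small_query, ScanParams())
        assert not any(SV_IV.overlaps(h.interval) for h in hits)


class TestPerturbationReport:
    def test_empty_edit_list_gives_baseline_only(self, small_master, small_spec):
        land, _ = small_master
        report = perturbation_report(land, small_spec.query_interval, [], k=15)
        assert list(report) == ["baseline"]

    def test_edit_in_hit_free_region_leaves_profile_unchanged(self, small_master, small_spec):
        land, truths = small_master
        lo = land.origin.start + 1_000
        free = GenomicInterval("chr7", lo, lo + 1_000)
        assert not any(free.overlaps(t.interval) for t in truths)
        report = perturbation_report(
            land,
            small_spec.query_interval,
            [SVEdit("deletion", free)],
            k=15,
            model_params=UNIFORM,
        )
        assert report["baseline"].scores == report[f"deletion:{free.to_1based_str()}"].scores

    def test_edit_overlapping_exon_warns(self, small_master, small_spec):
        land, _ = small_master
        qiv = small_spec.query_interval
        overlap = GenomicInterval("chr7", qiv.start - 100, qiv.start + 5)
        with pytest.warns(UserWarning, match="overlaps"):
            perturbation_report(land, qiv, [SVEdit("inversion", overlap)], k=15)

    def test_sv_ordering_at_the_query_window(self, small_master, small_spec):
        """Deletion and inversion of the top-hit block collapse the query
        window's instability; a tandem duplication nearly doubles it."""
        land, _ = small_master
        edits = [SVEdit(kind, SV_IV) for kind in ("deletion", "inversion", "duplication")]
        report = perturbation_report(land, small_spec.query_interval, edits, k=15)
        inst = {name: prof.instabilities[0] for name, prof in report.items()}
        base = inst["baseline"]
        dele = inst[f"deletion:{SV_IV.to_1based_str()}"]
        inv = inst[f"inversion:{SV_IV.to_1based_str()}"]
        dup = inst[f"duplication:{SV_IV.to_1based_str()}"]
        assert dele < base < dup
        assert inv == pytest.approx(dele, rel=0.1)
        assert dup > 1.5 * base
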