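"""Scar annotator rules: threshold inclusivity, smoothing, and invariants."""

import numpy as np
import pytest

from hrdbench.genome_segments import GRCH37, MB, ASCNVCallset, Segment
from hrdbench.scar_scores import (
    DEFAULT_CONFIG,
    annotate_loh,
    annotate_lst,
    annotate_tai,
    compute_scores,
    scar_region_catalog,
)
from hrdbench.simulate import simulate_truth

from conftest import make_callset


def random_profile(seed: int, n: int = 40) -> ASCNVCallset:
    """Random non-overlapping integer-CN segments across the autosomes."""
    rng = np.random.default_rng(seed)
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    segs: list[Segment] = []
    for _ in range(n):
        chrom = str(rng.integers(1, 23))
        length = int(rng.integers(1 * MB, 30 * MB))
        start = int(rng.integers(0, GRCH37.length(chrom) - length))
        taken = by_chrom.setdefault(chrom, [])
        if any(start < e and s < start + length for s, e in taken):
            continue
        taken.append((start, start + length))
        a = int(rng.integers(0, 4))
        b = int(rng.integers(0, a + 1)) if a else 0
        if a == b == 0:
            a = 1
        segs.append(Segment(chrom, start, start + length, None, a, b))
    return ASCNVCallset("random", segs)


class TestLOH:
    def test_qualifying_interior_segment(self):
        cs = make_callset([("1", 20 * MB, 40 * MB, 1, 0), ("1", 40 * MB, 60 * MB, 1, 1)])
        regions, count = annotate_loh(cs, GRCH37)
        assert count == 1
        assert regions == [("1", 20 * MB, 40 * MB)]

    def test_exactly_15mb_does_not_count(self):
        cs = make_callset([("1", 20 * MB, 35 * MB, 1, 0)])
        assert annotate_loh(cs, GRCH37)[1] == 0

    def test_whole_chromosome_excluded(self):
        cs = make_callset([("21", 0, GRCH37.length("21"), 1, 0)])
        assert annotate_loh(cs, GRCH37)[1] == 0

    def test_abutting_loh_segments_form_one_fragment(self):
        # two 9 Mb minor-allele-absent pieces that abut: one 18 Mb fragment
        cs = make_callset([("1", 20 * MB, 29 * MB, 1, 0), ("1", 29 * MB, 38 * MB, 2, 0)])
        regions, count = annotate_loh(cs, GRCH37)
        assert count == 1 and regions == [("1", 20 * MB, 38 * MB)]

    def test_balanced_profile_has_none(self):
        cs = make_callset([("1", 0, 100 * MB, 1, 1)])
        assert annotate_loh(cs, GRCH37)[1] == 0


class TestTAI:
    def test_telomeric_imbalance_before_centromere(self):
        cs = make_callset([("2", 0, 12 * MB, 2, 1), ("2", 12 * MB, 40 * MB, 1, 1)])
        regions, count = annotate_tai(cs, GRCH37)
        assert count == 1 and regions == [("2", 0, 12 * MB)]

    def test_interior_imbalance_does_not_count(self):
        cs = make_callset([("2", 0, 30 * MB, 1, 1), ("2", 30 * MB, 42 * MB, 2, 1)])
        assert annotate_tai(cs, GRCH37)[1] == 0

    def test_10mb_telomeric_segment_too_short(self):
        cs = make_callset([("2", 0, 10 * MB, 2, 1), ("2", 10 * MB, 40 * MB, 1, 1)])
        assert annotate_tai(cs, GRCH37)[1] == 0

    def test_exactly_11mb_counts(self):
        cs = make_callset([("2", 0, 11 * MB, 2, 1), ("2", 11 * MB, 40 * MB, 1, 1)])
        assert annotate_tai(cs, GRCH37)[1] == 1

    def test_segment_crossing_centromere_excluded(self):
        # chr2 centromere is at ~92-95 Mb; this imbalance runs past it
        cs = make_callset([("2", 0, 100 * MB, 2, 1), ("2", 100 * MB, 140 * MB, 1, 1)])
        assert annotate_tai(cs, GRCH37)[1] == 0

    def test_q_terminal_anchoring(self):
        end = GRCH37.length("2")
        cs = make_callset([("2", 100 * MB, end - 12 * MB, 1, 1), ("2", end - 12 * MB, end, 2, 1)])
        assert annotate_tai(cs, GRCH37)[1] == 1

    def test_anchoring_uses_covered_extent_not_chromosome_end(self):
        # profile starts at 5 Mb (assay does not reach the telomere);
        # the first covered segment still anchors
        cs = make_callset([("2", 5 * MB, 17 * MB, 2, 1), ("2", 17 * MB, 40 * MB, 1, 1)])
        assert annotate_tai(cs, GRCH37)[1] == 1


class TestLST:
    def test_adjacent_long_segments_different_state(self):
        cs = make_callset([("3", 0, 20 * MB, 1, 1), ("3", 20 * MB, 40 * MB, 2, 1)])
        regions, count = annotate_lst(cs, GRCH37)
        assert count == 1 and regions == [("3", 0, 40 * MB)]

    def test_gap_over_3mb_does_not_count(self):
        cs = make_callset([("3", 0, 20 * MB, 1, 1), ("3", 25 * MB, 45 * MB, 2, 1)])
        assert annotate_lst(cs, GRCH37)[1] == 0

    def test_gap_of_exactly_3mb_counts(self):
        cs = make_callset([("3", 0, 20 * MB, 1, 1), ("3", 23 * MB, 43 * MB, 2, 1)])
        assert annotate_lst(cs, GRCH37)[1] == 1

    def test_uniform_single_segment_arm(self):
        cs = make_callset([("3", 0, 80 * MB, 2, 1)])
        assert annotate_lst(cs, GRCH37)[1] == 0

    def test_short_flank_does_not_count(self):
        cs = make_callset([("3", 0, 9 * MB, 1, 1), ("3", 9 * MB, 40 * MB, 2, 1)])
        assert annotate_lst(cs, GRCH37)[1] == 0

    def test_small_segment_smoothed_between_equal_neighbors(self):
        cs = make_callset(
            [("3", 0, 20 * MB, 1, 1), ("3", 20 * MB, 22 * MB, 3, 1), ("3", 22 * MB, 42 * MB, 1, 1)]
        )
        assert annotate_lst(cs, GRCH37)[1] == 0

    def test_small_segment_smoothed_between_different_neighbors(self):
        cs = make_callset(
            [("3", 0, 20 * MB, 1, 1), ("3", 20 * MB, 22 * MB, 3, 1), ("3", 22 * MB, 42 * MB, 2, 2)]
        )
        assert annotate_lst(cs, GRCH37)[1] == 1

    def test_breakpoints_not_counted_across_centromere(self):
        cs, ce = GRCH37.centromere("3")
        rows = [("3", cs - 20 * MB, cs, 1, 1), ("3", ce, ce + 20 * MB, 2, 2)]
        assert annotate_lst(make_callset(rows), GRCH37)[1] == 0


class TestScoreInvariants:
    def test_gis_is_component_sum_and_region_counts_match(self):
        for seed in range(100):
            scores = compute_scores(random_profile(seed), GRCH37)
            assert scores.gis == scores.loh + scores.lst + scores.tai
            assert scores.loh == len(scores.loh_regions)
            assert scores.tai == len(scores.tai_regions)
            assert scores.lst == len(scores.lst_regions)

    @pytest.mark.parametrize("seed", range(5))
    def test_split_invariance(self, seed):
        """Splitting any segment into equal-CN halves never changes scores."""
        truth = simulate_truth(target_counts=(4, 3, 5), seed=seed)
        base = truth.as_callset()
        rng = np.random.default_rng(seed)
        split: list[Segment] = []
        for seg in base.segments:
            if seg.length > 2 and rng.random() < 0.5:
                mid = seg.start + int(rng.integers(1, seg.length))
                split.append(Segment(seg.chrom, seg.start, mid, None, seg.a_cn, seg.b_cn))
                split.append(Segment(seg.chrom, mid, seg.end, None, seg.a_cn, seg.b_cn))
            else:
                split.append(seg)
        before = compute_scores(base, GRCH37)
        after = compute_scores(ASCNVCallset("split", split), GRCH37)
        assert before.as_dict() == after.as_dict()

    def test_added_interior_loh_increments_loh_only(self):
        rows = [("8", 0, 12 * MB, 1, 1), ("8", 40 * MB, 43 * MB, 1, 1)]
        extra = ("8", 16 * MB, 36 * MB, 1, 0)
        before = compute_scores(make_callset(rows), GRCH37)
        after = compute_scores(make_callset(rows + [extra]), GRCH37)
        assert after.loh == before.loh + 1
        assert after.tai == before.tai
        assert after.lst == before.lst

    def test_empty_profile(self):
        scores = compute_scores(ASCNVCallset("empty", []), GRCH37)
        assert scores.as_dict() == {"LOH": 0, "TAI": 0, "LST": 0, "GIS": 0}


class TestBruteForceOracle:
    """Independent, unoptimized re-derivation of LOH/TAI rules per segment."""

    @staticmethod
    def brute_loh(cs: ASCNVCallset) -> int:
        cfg = DEFAULT_CONFIG
        count = 0
        for chrom in GRCH37.autosomes:
            spans = []
            for s in cs.segments:
                if s.chrom == chrom and s.b_cn <= cfg.loh_minor_max and s.a_cn >= cfg.loh_major_min:
                    if spans and spans[-1][1] == s.start:
                        spans[-1][1] = s.end
                    else:
                        spans.append([s.start, s.end])
            for st, en in spans:
                whole = st <= cfg.whole_chrom_window and en >= GRCH37.length(chrom) - cfg.whole_chrom_window
                if en - st > cfg.loh_min_len and not whole:
                    count += 1
        return count

    @staticmethod
    def brute_tai(cs: ASCNVCallset) -> int:
        cfg = DEFAULT_CONFIG
        count = 0
        for chrom in GRCH37.autosomes:
            segs = [s for s in cs.segments if s.chrom == chrom]
            if not segs:
                continue
            lo = min(s.start for s in segs)
            hi = max(s.end for s in segs)
            cen_s, cen_e = GRCH37.centromere(chrom)
            for s in segs:
                if abs(s.a_cn - s.b_cn) <= cfg.imbalance_tol or s.length < cfg.tai_min_len:
                    continue
                if s.start <= lo and s.end <= cen_e:
                    count += 1
                elif s.end >= hi and s.start >= cen_s:
                    count += 1
        return count

    @pytest.mark.parametrize("seed", range(30))
    def test_annotators_match_brute_force(self, seed):
        cs = random_profile(seed, n=50)
        assert annotate_loh(cs, GRCH37)[1] == self.brute_loh(cs)
        assert annotate_tai(cs, GRCH37)[1] == self.brute_tai(cs)


class TestCatalog:
    def test_planted_truth_catalog_matches_plant_list(self):
        truth = simulate_truth(target_counts=(5, 4, 6), seed=3)
        catalog = scar_region_catalog(truth.as_callset(), GRCH37)
        labels = [row[3] for row in catalog]
        assert labels.count("LOH") == 5
        assert labels.count("TAI") == 4
        assert labels.count("LST") == 6

    def test_overlapping_classifications_emit_separate_rows(self):
        # a telomeric >=15 Mb minor-allele-absent segment is both LOH and TAI
        cs = make_callset([("2", 0, 20 * MB, 1, 0), ("2", 20 * MB, 50 * MB, 1, 1)])
        catalog = scar_region_catalog(cs, GRCH37)
        spans = {(row[1], row[2], row[3]) for row in catalog}
        assert (0, 20 * MB, "LOH") in spans
        assert (0, 20 * MB, "TAI") in spans

    def test_no_scars_empty_catalog(self):
        cs = make_callset([("1", 0, 100 * MB, 1, 1)])
        assert scar_region_catalog(cs, GRCH37) == []
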