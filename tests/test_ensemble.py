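"""Fusion rules: agreement unions, takeover, pickup, sorting, full run."""

import itertools
import logging

import numpy as np
import pytest

from spinefuse import (
    CorruptionSpec,
    EnsembleConfig,
    EnsembleFailure,
    SpineSpec,
    agreement,
    extract_instances,
    iou,
    make_case,
    pickup_missed,
    run_ensemble,
    select_agreement_pairs,
    separate_overlapping,
    sort_masks,
)

from conftest import rect_mask


def partition_masks(n=6, shape=(120, 40)):
    """n disjoint stacked rectangles, top to bottom."""
    return [rect_mask(shape, 4 + 18 * i, 16 + 18 * i, 5, 35) for i in range(n)]


class TestSelectAgreementPairs:
    def test_identical_partitions_all_union(self):
        sem = partition_masks()
        inst = [rect_mask((120, 40), m.bbox[0], m.bbox[1] + 1, m.bbox[2],
                          m.bbox[3] + 1, source="instance")
                for m in sem]
        kept, sr, ir = select_agreement_pairs(sem, inst, EnsembleConfig())
        assert len(kept) == 6 and sr == [] and ir == []
        assert all(m.provenance == "agreement_union" for m in kept)

    def test_disjoint_lists_nothing_kept(self):
        sem = [rect_mask((40, 40), 0, 5, 0, 5)]
        inst = [rect_mask((40, 40), 20, 25, 20, 25, source="instance")]
        kept, sr, ir = select_agreement_pairs(sem, inst, EnsembleConfig())
        assert kept == [] and len(sr) == 1 and len(ir) == 1

    def test_greedy_matches_exhaustive_on_3x3(self):
        """Greedy descending-δ matching picks a maximal valid 3x3 assignment.

        The overlaps are arranged so naive row-order matching would pair
        sem0 with inst0 (δ=0.6) and strand the better sem1-inst0 pair; the
        greedy order must instead realise the assignment that exhaustive
        permutation search proves optimal.
        """
        shape = (30, 90)
        sem = [
            rect_mask(shape, 0, 10, 0, 10),
            rect_mask(shape, 0, 10, 20, 30),
            rect_mask(shape, 0, 10, 40, 50),
        ]
        inst = [
            rect_mask(shape, 0, 10, 24, 34, source="instance"),  # sem1 d=0.6
            rect_mask(shape, 0, 10, 2, 12, source="instance"),   # sem0 d=0.8
            rect_mask(shape, 0, 10, 41, 51, source="instance"),  # sem2 d=0.9
        ]
        cfg = EnsembleConfig(eta=0.55)
        dmat = [[agreement(s, m) for m in inst] for s in sem]
        best, best_val = None, -1.0
        for perm in itertools.permutations(range(3)):
            pairs = [(i, perm[i]) for i in range(3) if dmat[i][perm[i]] > cfg.eta]
            val = sum(dmat[i][j] for i, j in pairs)
            if val > best_val:
                best_val, best = val, set(pairs)
        kept, sr, ir = select_agreement_pairs(sem, inst, cfg)
        assert len(kept) == len(best) == 3
        # reconstruct greedy's assignment from which rests are empty
        assert sr == [] and ir == []

    def test_union_covering_other_candidate_is_vetoed(self):
        """A blob-union that would swallow a separable instance mask is refused.

        The semantic blob spans two instance masks; even at a low η where
        its δ against one of them passes the agreement test, forming that
        union would re-merge the pair, so it must be rejected and all
        three masks must fall through to the later rules.
        """
        shape = (60, 30)
        blob = rect_mask(shape, 5, 45, 5, 25)  # covers both instances
        i1 = rect_mask(shape, 5, 24, 5, 25, source="instance")
        i2 = rect_mask(shape, 26, 45, 5, 25, source="instance")
        cfg = EnsembleConfig(eta=0.3)
        assert agreement(blob, i1) > cfg.eta  # would pass the agreement test
        kept, sr, ir = select_agreement_pairs([blob], [i1, i2], cfg)
        assert kept == []
        assert len(sr) == 1 and len(ir) == 2


class TestSeparateOverlapping:
    def test_merged_blob_yields_two_takeovers(self):
        # one semantic blob = pixel union of two 300-px instance masks
        shape = (60, 30)
        blob = rect_mask(shape, 10, 50, 10, 25)  # 40x15 = 600 px
        i1 = rect_mask(shape, 10, 30, 10, 25, source="instance")  # 300 px
        i2 = rect_mask(shape, 30, 50, 10, 25, source="instance")  # 300 px
        cfg = EnsembleConfig(eta=0.6)
        assert agreement(blob, i1) == pytest.approx(0.5)
        kept, sr, ir = separate_overlapping([blob], [i1, i2], cfg)
        assert len(kept) == 2 and ir == []
        assert all(m.provenance == "instance_takeover" for m in kept)
        assert len(sr) == 1  # blob stays for the pickup screen

    def test_disjoint_instance_not_taken(self):
        sem = [rect_mask((40, 40), 0, 10, 0, 10)]
        inst = [rect_mask((40, 40), 20, 30, 20, 30, source="instance")]
        kept, _, ir = separate_overlapping(sem, inst, EnsembleConfig())
        assert kept == [] and len(ir) == 1

    def test_threshold_boundary_not_taken(self):
        # delta_m = 0.5 under eta = 0.6 -> no takeover
        shape = (40, 40)
        sem = [rect_mask(shape, 0, 10, 0, 5)]
        inst = [rect_mask(shape, 0, 10, 0, 10, source="instance")]
        cfg = EnsembleConfig(eta=0.6)
        kept, _, ir = separate_overlapping(sem, inst, cfg)
        assert kept == [] and len(ir) == 1


class TestPickupMissed:
    def test_zero_variance_exact_match_promoted(self):
        shape = (80, 80)
        kept = [rect_mask(shape, 10 * i, 10 * i + 5, 0, 20) for i in range(3)]
        cand = rect_mask(shape, 50, 55, 0, 20)  # same 100-px area, disjoint
        out, unused, mu, sigma = pickup_missed(kept, [cand], EnsembleConfig())
        assert sigma == 0.0 and len(out) == 4 and unused == []
        assert out[-1].provenance == "pickup"

    def test_area_window_rejects_double_blob(self):
        # kept areas {90, 100, 110}, lam=2: window approx [83.7, 116.3]
        shape = (100, 100)
        kept = [
            rect_mask(shape, 0, 9, 0, 10),    # 90
            rect_mask(shape, 20, 30, 0, 10),  # 100
            rect_mask(shape, 40, 51, 0, 10),  # 110
        ]
        blob = rect_mask(shape, 60, 80, 0, 10)  # 200 px merged double
        out, unused, mu, sigma = pickup_missed(kept, [blob], EnsembleConfig(lam=2.0))
        assert mu == pytest.approx(100.0)
        assert sigma == pytest.approx(np.std([90, 100, 110]))
        assert len(out) == 3 and len(unused) == 1

    def test_duplicate_rejected_by_iou(self):
        shape = (60, 60)
        kept = [rect_mask(shape, 0, 10, 0, 10), rect_mask(shape, 20, 30, 0, 10),
                rect_mask(shape, 40, 50, 0, 11)]
        dup = rect_mask(shape, 0, 10, 0, 11)  # IoU 10/11 with kept[0], area 110
        out, unused, *_ = pickup_missed(kept, [dup], EnsembleConfig(lam=3.0))
        assert len(out) == 3 and len(unused) == 1

    def test_empty_kept_raises(self):
        with pytest.raises(EnsembleFailure):
            pickup_missed([], [rect_mask((10, 10), 0, 5, 0, 5)], EnsembleConfig())


class TestSortMasks:
    def test_orders_by_centroid_row(self):
        shape = (60, 60)
        masks = [rect_mask(shape, r, r + 5, 0, 5) for r in (30, 10, 20)]
        assert [m.bbox[0] for m in sort_masks(masks)] == [10, 20, 30]

    def test_ties_broken_by_column(self):
        shape = (20, 60)
        left = rect_mask(shape, 5, 10, 3, 8)
        right = rect_mask(shape, 5, 10, 38, 43)
        assert sort_masks([right, left])[0] is left

    def test_stable_under_permutation(self, rng):
        spec = SpineSpec(region="cervical", n_vertebrae=7, seed=42)
        case = make_case(spec, CorruptionSpec(0, 0, 0, seed=42))
        expect = [m.centroid for m in case.gt_masks]
        for _ in range(5):
            perm = list(rng.permutation(len(case.gt_masks)))
            got = [m.centroid for m in sort_masks([case.gt_masks[i] for i in perm])]
            assert got == expect


class TestRunEnsemble:
    def test_fixed_point_on_identical_sources(self):
        """Both sources equal the truth -> output is the truth, all unions."""
        case = make_case(SpineSpec(seed=3), CorruptionSpec(0, 0, 0, seed=3))
        sem = np.zeros(case.gt_masks[0].shape, dtype=bool)
        for m in case.gt_masks:
            sem |= m.pixels
        inst = [m for m in case.instances]
        for eta in (0.1, 0.3, 0.6, 0.9):
            res = run_ensemble(sem, inst, EnsembleConfig(eta=eta))
            assert res.counts == {"agreement_union": len(case.gt_masks),
                                  "instance_takeover": 0, "pickup": 0}
            for kept, gt in zip(res.kept, case.gt_masks):
                assert np.array_equal(kept.pixels, gt.pixels)

    def test_merge_and_drop_repair(self):
        """Semantic merges a pair, instance drops a body: all recovered.

        Every ground-truth vertebra must reappear in the kept list at
        IoU >= 0.5, with the merged pair arriving via instance takeover
        and the dropped body via pickup of its semantic component.
        """
        spec = SpineSpec(region="cervical", n_vertebrae=6, seed=9)
        case = make_case(spec, CorruptionSpec(0, 0, 0, seed=9))
        sem = np.zeros(case.gt_masks[0].shape, dtype=bool)
        for m in case.gt_masks:
            sem |= m.pixels
        # bridge vertebrae 2 and 3 in the semantic raster
        u, l = case.gt_masks[2], case.gt_masks[3]
        r0, r1 = u.bbox[1], l.bbox[0]
        c0 = max(u.bbox[2], l.bbox[2]) + 10
        c1 = min(u.bbox[3], l.bbox[3]) - 10
        sem[r0:r1 + 1, c0:c1 + 1] = True
        inst = [m for i, m in enumerate(case.instances) if i != 5]  # drop last
        res = run_ensemble(sem, inst, EnsembleConfig())
        assert len(res.kept) == 6
        assert res.counts["instance_takeover"] == 2
        assert res.counts["pickup"] == 1
        assert res.counts["agreement_union"] == 3
        for gt in case.gt_masks:
            assert max(iou(gt, k) for k in res.kept) >= 0.5

    def test_empty_instance_list_falls_back(self, caplog):
        case = make_case(SpineSpec(seed=4), CorruptionSpec(0, 0, 0, seed=4))
        sem = np.zeros(case.gt_masks[0].shape, dtype=bool)
        for m in case.gt_masks:
            sem |= m.pixels
        with caplog.at_level(logging.WARNING, logger="spinefuse"):
            res = run_ensemble(sem, [], EnsembleConfig())
        assert len(res.kept) == len(case.gt_masks)
        assert all(m.provenance == "pickup" for m in res.kept)
        assert any("single-source" in r.message for r in caplog.records)

    def test_both_empty_raises(self):
        with pytest.raises(EnsembleFailure):
            run_ensemble(np.zeros((50, 50), dtype=bool), [], EnsembleConfig())

    def test_counts_sum_and_separation(self):
        """Provenance counts total |kept|; kept masks stay separated."""
        rng = np.random.default_rng(123)
        cfg = EnsembleConfig()
        for k in range(10):
            spec = SpineSpec(region="lumbar" if k % 2 else "cervical",
                             n_vertebrae=5 + k % 5,
                             seed=int(rng.integers(2**31)))
            corr = CorruptionSpec(0.3, 0.3, 1.0, seed=int(rng.integers(2**31)))
            case = make_case(spec, corr)
            if not case.instances:
                continue
            res = run_ensemble(case.semantic, case.instances, cfg)
            assert sum(res.counts.values()) == len(res.kept)
            for i, a in enumerate(res.kept):
                for b in res.kept[i + 1:]:
                    assert iou(a, b) <= cfg.pickup_dedup_iou
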