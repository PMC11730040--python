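import itertools

import numpy as np
import pytest

import cmbchar as c
from cmbchar.errors import ValidationError

from conftest import mask_from_voxels


def components(voxel_groups, shape=(20, 20, 20)):
    all_vox = [v for g in voxel_groups for v in g]
    return c.label_components(mask_from_voxels(all_vox, shape=shape))


class TestMatching:
    def test_identical_maps_all_true_positive(self):
        groups = [[(1, 1, 1), (2, 1, 1)], [(8, 8, 8)]]
        comps = components(groups)
        matches = c.match_lesions(comps, comps)
        assert all(m.status == "true_positive" for m in matches)
        assert len(matches) == 2

    def test_empty_prediction_all_false_negative(self):
        ref = components([[(1, 1, 1)], [(5, 5, 5)], [(9, 9, 9)]])
        matches = c.match_lesions([], ref)
        assert sum(m.status == "false_negative" for m in matches) == 3
        assert not any(m.status == "true_positive" for m in matches)

    def test_greedy_prefers_larger_overlap(self):
        # one prediction (a z-column) overlapping two reference lesions by
        # 2 voxels and by 4 voxels; the larger overlap wins the match
        pred = components([[(3, 3, z) for z in range(0, 7)]])
        ref = c.label_components(
            mask_from_voxels([(3, 3, 0), (3, 3, 1)] + [(3, 3, z) for z in range(3, 8)])
        )
        assert len(ref) == 2
        matches = c.match_lesions(pred, ref)
        tp = [m for m in matches if m.status == "true_positive"]
        assert len(tp) == 1
        big_ref = max(ref, key=lambda r: r.n_voxels)
        assert tp[0].ref_id == big_ref.component_id
        assert tp[0].overlap_voxels == 4
        assert sum(m.status == "false_negative" for m in matches) == 1

    def test_one_to_one_constraint(self):
        rng = np.random.default_rng(6)
        data = (rng.random((15, 15, 15)) < 0.15).astype(np.uint8)
        comps = c.label_components(mask_from_voxels(np.argwhere(data), shape=(15, 15, 15)))
        matches = c.match_lesions(comps, comps)
        pids = [m.pred_id for m in matches if m.pred_id is not None]
        rids = [m.ref_id for m in matches if m.ref_id is not None]
        assert len(pids) == len(set(pids)) and len(rids) == len(set(rids))

    def test_greedy_agrees_with_exhaustive_optimum(self):
        """On random small instances, greedy overlap matching attains the
        exhaustive-best total overlap with the same number of pairs."""
        rng = np.random.default_rng(11)
        for _ in range(30):
            n_ref = rng.integers(1, 7)
            shape = (56, 56, 56)
            centres = rng.integers(4, 52, size=(n_ref, 3))
            ref_vox, pred_vox = [], []
            for ctr in centres:
                offs = np.argwhere(np.ones((3, 3, 3))) - 1
                ref_vox.append([tuple(np.clip(ctr + o, 0, 55)) for o in offs])
                jitter = rng.integers(-2, 3, size=3)
                pred_vox.append([tuple(np.clip(ctr + jitter + o, 0, 55)) for o in offs])
            ref = components(ref_vox, shape=shape)
            pred = components(pred_vox, shape=shape)
            if len(ref) > 6 or len(pred) > 6:
                continue  # clipping can merge blobs; keep instances brute-forceable
            matches = c.match_lesions(pred, ref)
            greedy_total = sum(m.overlap_voxels for m in matches if m.status == "true_positive")
            greedy_pairs = sum(m.status == "true_positive" for m in matches)
            # brute force over injective assignments pred -> ref
            ov = {(p.component_id, r.component_id): len(p.voxel_set() & r.voxel_set())
                  for p in pred for r in ref}
            best_total, best_pairs = 0, 0
            rids = [r.component_id for r in ref]
            for k in range(min(len(pred), len(ref)), -1, -1):
                for p_sub in itertools.combinations([p.component_id for p in pred], k):
                    for perm in itertools.permutations(rids, k):
                        tot = sum(ov[p, r] for p, r in zip(p_sub, perm) if ov[p, r] >= 1)
                        npairs = sum(ov[p, r] >= 1 for p, r in zip(p_sub, perm))
                        if (tot, npairs) > (best_total, best_pairs):
                            best_total, best_pairs = tot, npairs
            assert greedy_total == best_total
            assert greedy_pairs == best_pairs


class TestSizeError:
    def test_identical_sizes_zero_error(self):
        comps = components([[(1, 1, 1)], [(8, 8, 8)]])
        matches = c.match_lesions(comps, comps)
        sizes = {cc.component_id: cc.diameter_mm for cc in comps}
        errors, mae = c.size_error(matches, sizes, sizes)
        assert errors == [0.0, 0.0] and mae == 0.0

    def test_hand_arithmetic(self):
        matches = [c.LesionMatch(1, 1, 3, "true_positive"),
                   c.LesionMatch(2, 2, 3, "true_positive")]
        errors, mae = c.size_error(matches, {1: 5.4, 2: 3.6}, {1: 4.5, 2: 3.6})
        assert errors == pytest.approx([0.9, 0.0])
        assert mae == pytest.approx(0.45)

    def test_empty_matches_mae_none(self):
        errors, mae = c.size_error([], {}, {})
        assert errors == [] and mae is None

    def test_missing_size_rejected(self):
        matches = [c.LesionMatch(1, 1, 3, "true_positive")]
        with pytest.raises(ValidationError):
            c.size_error(matches, {}, {1: 4.5})

    def test_error_summary_rounded_percentages(self):
        # 185 matched lesions: 11 with error > 6 mm -> 6%; 65 below 1 mm -> 35%
        errors = [7.0] * 11 + [0.5] * 65 + [2.0] * 109
        summary = c.error_summary(errors)
        assert summary["n"] == 185
        assert summary["pct_above_large"] == 6
        assert summary["pct_below_small"] == 35


class TestRegionMetrics:
    @pytest.mark.parametrize("sens,prec,f1", [(0.64, 1.00, 0.78), (0.79, 0.85, 0.82), (0.96, 0.91, 0.93)])
    def test_f1_harmonic_mean_printed_pairs(self, sens, prec, f1):
        assert round(c.f1_score(sens, prec), 2) == f1

    def test_perfect_agreement(self):
        pairs = [("deep", "deep"), ("lobar", "lobar"), ("infratentorial", "infratentorial")]
        per_region, acc = c.region_metrics(pairs)
        assert acc == 1.0
        for r in c.REGIONS:
            assert per_region[r]["f1"] == 1.0

    def test_accuracy_direct_count(self):
        pairs = [("lobar", "lobar")] * 9 + [("deep", "lobar")]
        _, acc = c.region_metrics(pairs)
        assert acc == pytest.approx(0.9)

    def test_unmatched_lesions_enter_one_side_only(self):
        pairs = [("lobar", "lobar"), (None, "deep"), ("deep", None)]
        per_region, acc = c.region_metrics(pairs)
        assert per_region["deep"]["sensitivity"] == 0.0  # the FN
        assert per_region["deep"]["precision"] == 0.0  # the FP
        assert per_region["lobar"]["sensitivity"] == 1.0
        assert acc == 1.0  # only one matched lesion, and it agrees

    def test_invalid_label_rejected(self):
        with pytest.raises(ValidationError):
            c.region_metrics([("cortex", "deep")])

    def test_count_level_mode(self):
        metrics = c.count_level_region_metrics(
            {"lobar": 5, "deep": 2, "infratentorial": 0},
            {"lobar": 4, "deep": 3, "infratentorial": 1},
        )
        assert metrics["lobar"]["sensitivity"] == 1.0
        assert metrics["lobar"]["precision"] == pytest.approx(0.8)
        assert metrics["deep"]["sensitivity"] == pytest.approx(2 / 3)
        assert metrics["infratentorial"]["f1"] == 0.0


class TestConfusion:
    def _assign(self, mapping):
        return {i: (s, c.STRUCTURE_REGION.get(s, c.UNCLASSIFIED)) for i, s in mapping.items()}

    def test_perfect_agreement_diagonal(self):
        matches = [c.LesionMatch(i, i, 1, "true_positive") for i in (1, 2, 3)]
        a = self._assign({1: "thalamus", 2: "frontal", 3: "cerebellum"})
        cs, cr = c.confusion_matrices(a, a, matches)
        assert int(np.trace(cs.values)) == 3 and int(cs.values.sum()) == 3
        assert int(np.trace(cr.values)) == 3

    def test_single_off_diagonal_cell(self):
        matches = [c.LesionMatch(1, 1, 1, "true_positive")]
        pred = self._assign({1: "basal_ganglia"})
        ref = self._assign({1: "thalamus"})
        cs, cr = c.confusion_matrices(pred, ref, matches)
        assert cs.loc["thalamus", "basal_ganglia"] == 1
        assert int(cs.values.sum()) == 1
        assert cr.loc["deep", "deep"] == 1  # same region despite structure error

    def test_total_equals_matched_count(self):
        matches = [c.LesionMatch(1, 2, 1, "true_positive"),
                   c.LesionMatch(2, 1, 1, "true_positive"),
                   c.LesionMatch(3, None, 0, "false_positive")]
        a = self._assign({1: "frontal", 2: "parietal", 3: "insula"})
        cs, cr = c.confusion_matrices(a, a, matches)
        assert int(cs.values.sum()) == 2 == int(cr.values.sum())

    def test_metrics_recomputable_from_region_matrix(self):
        """Internal consistency: sensitivity/precision/F1 derived from the
        region confusion matrix match region_metrics on the same pairs."""
        rng = np.random.default_rng(8)
        regions = list(c.REGIONS)
        pairs = [(regions[rng.integers(3)], regions[rng.integers(3)]) for _ in range(40)]
        matches = [c.LesionMatch(i, i, 1, "true_positive") for i in range(40)]
        pred = {i: ("frontal", p) for i, (p, _) in enumerate(pairs)}
        ref = {i: ("frontal", r) for i, (_, r) in enumerate(pairs)}
        # structure slot is irrelevant here; region slot drives the matrix
        _, cr = c.confusion_matrices(pred, ref, matches)
        from_matrix = c.metrics_from_region_confusion(cr)
        direct, _ = c.region_metrics(pairs)
        for r in regions:
            for k in ("sensitivity", "precision", "f1"):
                assert from_matrix[r][k] == pytest.approx(direct[r][k])


class TestFnHistogram:
    def test_no_false_negatives(self):
        matches = [c.LesionMatch(1, 1, 1, "true_positive")]
        assert c.fn_histogram(matches, {1: "frontal"}) == {}

    def test_counts_by_structure(self):
        matches = [c.LesionMatch(None, 1, 0, "false_negative"),
                   c.LesionMatch(None, 2, 0, "false_negative"),
                   c.LesionMatch(None, 3, 0, "false_negative"),
                   c.LesionMatch(1, 4, 2, "true_positive")]
        hist = c.fn_histogram(matches, {1: "frontal", 2: "frontal", 3: "parietal", 4: "thalamus"})
        assert hist == {"frontal": 2, "parietal": 1}
        assert sum(hist.values()) == sum(m.status == "false_negative" for m in matches)


class TestMarginalConsistency:
    def test_region_marginals_match_ratings(self, phantom_atlas, phantom_lesions):
        """Reference-side TP+FN per region equals the manual region count;
        prediction-side TP+FP equals the automated region count."""
        _, atlas = phantom_atlas
        mask, _ = phantom_lesions
        degraded = c.perturb_mask(mask, c.Perturbation("drop", p=0.4), seed=3)
        ref_rating = c.rate_subject(mask, atlas, "ref")
        pred_rating = c.rate_subject(degraded, atlas, "pred")
        pred_comps = c.label_components(degraded)
        ref_comps = c.label_components(mask)
        pa = {a.component_id: (a.structure, a.region) for a in pred_rating.per_lesion}
        ra = {a.component_id: (a.structure, a.region) for a in ref_rating.per_lesion}
        ev = c.evaluate_subject(pred_comps, ref_comps, pa, ra)
        for region in c.REGIONS:
            tp = sum(1 for m in ev.matches if m.status == "true_positive"
                     and pa[m.pred_id][1] == region and ra[m.ref_id][1] == region)
            fn = sum(1 for m in ev.matches
                     if (m.status == "false_negative" and ra[m.ref_id][1] == region)
                     or (m.status == "true_positive" and ra[m.ref_id][1] == region
                         and pa[m.pred_id][1] != region))
            fp = sum(1 for m in ev.matches
                     if (m.status == "false_positive" and pa[m.pred_id][1] == region)
                     or (m.status == "true_positive" and pa[m.pred_id][1] == region
                         and ra[m.ref_id][1] != region))
            assert tp + fn == ref_rating.region_counts[region]
            assert tp + fp == pred_rating.region_counts[region]
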