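import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from osteoseg import phantom
from osteoseg.core import (BinaryMask, GeometryError, LesionStats,
                           ParameterError, UndefinedResultError, Units,
                           VolumeImage)
from osteoseg.validation import (SweepResult, concordance_r, dice,
                                 evaluate_case, match_lesions, patient_report,
                                 select_optimum_threshold, sweep_thresholds,
                                 unmatched_report, voxel_confusion)
from tests.conftest import run_pipeline


def _lesion(label, suv_max, coord_mm, volume_ml=1.0, suv_mean=None):
    return LesionStats(label=label, volume_ml=volume_ml,
                       suv_mean=suv_mean or suv_max * 0.8, suv_max=suv_max,
                       max_coord=(0, 0, 0), max_coord_mm=coord_mm,
                       voxel_count=1)


def _mask(data, spacing=(1.0, 1.0, 1.0)):
    return BinaryMask(np.asarray(data), spacing, (0, 0, 0))


class TestMatchLesions:
    def test_identical_lists_pair_perfectly(self):
        lesions = [_lesion(1, 4.0, (0, 0, 0)), _lesion(2, 6.0, (30, 0, 0))]
        pairs, un_a, un_r = match_lesions(lesions, lesions)
        assert [(p.auto_label, p.ref_label) for p in pairs] == [(1, 1), (2, 2)]
        assert all(p.cost == 0 for p in pairs)
        assert un_a == [] and un_r == []

    def test_cost_tie_goes_to_lower_ref_label(self):
        auto = [_lesion(1, 4.0, (0, 0, 0))]
        ref = [_lesion(1, 4.0, (5, 0, 0)), _lesion(2, 4.0, (0, 5, 0))]
        pairs, _, un_r = match_lesions(auto, ref)
        assert pairs[0].ref_label == 1
        assert [r.label for r in un_r] == [2]

    def test_distance_gate_rejects_far_pairs(self):
        auto = [_lesion(1, 4.0, (0, 0, 0))]
        ref = [_lesion(1, 4.0, (100, 0, 0))]
        pairs, un_a, un_r = match_lesions(auto, ref, max_distance_mm=20.0)
        assert pairs == []
        assert len(un_a) == 1 and len(un_r) == 1

    def test_order_independent(self):
        rng = np.random.default_rng(6)
        auto = [_lesion(i + 1, rng.uniform(3, 8),
                        tuple(rng.uniform(0, 100, 3))) for i in range(5)]
        ref = [_lesion(i + 1, rng.uniform(3, 8),
                       tuple(rng.uniform(0, 100, 3))) for i in range(5)]
        pairs_fwd, _, _ = match_lesions(auto, ref)
        pairs_rev, _, _ = match_lesions(auto[::-1], ref[::-1])
        key = lambda p: (p.auto_label, p.ref_label)
        assert sorted(map(key, pairs_fwd)) == sorted(map(key, pairs_rev))

    def test_empty_inputs(self):
        assert match_lesions([], []) == ([], [], [])

    def test_one_to_one(self):
        auto = [_lesion(1, 4.0, (0, 0, 0)), _lesion(2, 4.0, (1, 0, 0))]
        ref = [_lesion(1, 4.0, (0.5, 0, 0))]
        pairs, un_a, _ = match_lesions(auto, ref)
        assert len(pairs) == 1
        assert len(un_a) == 1


class TestVoxelConfusion:
    def test_perfect_agreement(self):
        mask = _mask(np.ones((4, 4, 2)))
        cm = voxel_confusion(mask, mask, mask)
        assert cm.fp == cm.fn == 0
        assert cm.sensitivity == cm.specificity == 1.0

    def test_empty_auto(self):
        ref = _mask(np.ones((4, 4, 2)))
        auto = _mask(np.zeros((4, 4, 2)))
        domain = _mask(np.ones((4, 4, 2)))
        cm = voxel_confusion(auto, ref, domain)
        assert cm.tp == 0
        assert cm.sensitivity == 0.0
        assert cm.specificity == 1.0  # no negatives exist -> convention

    def test_counts_match_brute_force(self):
        rng = np.random.default_rng(12)
        shape = (6, 7, 5)
        domain = _mask(rng.uniform(size=shape) > 0.2)
        auto = _mask(rng.uniform(size=shape) > 0.7)
        ref = _mask(rng.uniform(size=shape) > 0.7)
        cm = voxel_confusion(auto, ref, domain)
        tp = tn = fp = fn = 0
        for idx in np.ndindex(shape):
            if not domain.data[idx]:
                continue
            a, r = auto.data[idx], ref.data[idx]
            tp += a and r
            fp += a and not r
            fn += r and not a
            tn += not a and not r
        assert (cm.tp, cm.tn, cm.fp, cm.fn) == (tp, tn, fp, fn)
        assert cm.total == int(domain.data.sum())

    def test_grid_mismatch_rejected(self):
        with pytest.raises(GeometryError):
            voxel_confusion(_mask(np.ones((2, 2, 2))),
                            _mask(np.ones((3, 3, 3))),
                            _mask(np.ones((2, 2, 2))))


class TestDice:
    def test_identical_masks(self):
        mask = _mask(np.ones((3, 3, 3)))
        assert dice(mask, mask) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((4, 4, 2), dtype=bool)
        b = np.zeros((4, 4, 2), dtype=bool)
        a[0, 0, 0] = True
        b[3, 3, 1] = True
        assert dice(_mask(a), _mask(b)) == 0.0

    def test_hand_counted_overlap(self):
        # |A| = |B| = 8, |A∩B| = 6 -> DSC = 12/16 = 0.75
        a = np.zeros((4, 4, 2), dtype=bool)
        b = np.zeros((4, 4, 2), dtype=bool)
        a.ravel()[:8] = True
        b.ravel()[2:10] = True
        assert dice(_mask(a), _mask(b)) == 0.75

    def test_both_empty_is_one(self):
        empty = _mask(np.zeros((3, 3, 3)))
        assert dice(empty, empty) == 1.0

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_jaccard_identity(self, seed):
        rng = np.random.default_rng(seed)
        a = _mask(rng.uniform(size=(5, 5, 4)) > 0.5)
        b = _mask(rng.uniform(size=(5, 5, 4)) > 0.5)
        d = dice(a, b)
        inter = int((a.data & b.data).sum())
        union = int((a.data | b.data).sum())
        j = inter / union if union else 1.0
        assert d == pytest.approx(2 * j / (1 + j))
        assert 0.0 <= d <= 1.0


class TestConcordance:
    def test_perfect_positive(self):
        x = [1.0, 2.0, 5.0]
        assert concordance_r(x, [2 * v + 1 for v in x]) == pytest.approx(1.0)

    def test_perfect_negative(self):
        x = [1.0, 2.0, 5.0]
        assert concordance_r(x, [-v for v in x]) == pytest.approx(-1.0)

    def test_five_point_hand_computation(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        y = [2.0, 1.0, 4.0, 3.0, 5.0]
        # textbook formula evaluated by hand:
        # sum (x-3)(y-3) = 2+2+0+0+4 = 8; sum (x-3)^2 = sum (y-3)^2 = 10
        # r = 8 / sqrt(10*10) = 0.8
        n = len(x)
        mx, my = sum(x) / n, sum(y) / n
        num = sum((a - mx) * (b - my) for a, b in zip(x, y))
        den = (sum((a - mx) ** 2 for a in x)
               * sum((b - my) ** 2 for b in y)) ** 0.5
        assert concordance_r(x, y) == pytest.approx(num / den)
        assert concordance_r(x, y) == pytest.approx(0.8)

    def test_degenerate_variance_raises(self):
        with pytest.raises(UndefinedResultError):
            concordance_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_too_few_points_raises(self):
        with pytest.raises(UndefinedResultError):
            concordance_r([1.0], [2.0])


class TestSweep:
    def _single_case(self, phantom_result):
        products = run_pipeline(phantom_result)
        return (products["suv"], products["bone"],
                phantom_result.truth_labels)

    def test_thresholds_below_all_plateaus_are_inert(self, oligo_phantom):
        # lowest lesion plateau in the oligo preset is 3.8; thresholds 2
        # and 3 cut the same uniform-plateau lesions identically apart from
        # the soft background, which sits at SUV 1
        case = self._single_case(oligo_phantom)
        sweep = sweep_thresholds([case], [2.0, 3.0])
        assert sweep.sensitivity[0] == sweep.sensitivity[1]
        assert sweep.dsc[0] == sweep.dsc[1]

    def test_sensitivity_non_increasing(self, widespread_phantom):
        case = self._single_case(widespread_phantom)
        sweep = sweep_thresholds([case], [2.0, 2.5, 3.0, 3.5, 4.0, 6.0])
        sens = sweep.sensitivity
        assert all(a >= b - 1e-12 for a, b in zip(sens, sens[1:]))

    def test_rates_bounded(self, widespread_phantom):
        case = self._single_case(widespread_phantom)
        sweep = sweep_thresholds([case], [2.5, 3.5, 6.0])
        for i in range(3):
            assert 0.0 <= sweep.sensitivity[i] <= 1.0
            assert 0.0 <= sweep.specificity[i] <= 1.0
            assert all(0.0 <= d <= 1.0 for d in sweep.dsc[i])

    def test_empty_threshold_list_rejected(self, oligo_phantom):
        case = self._single_case(oligo_phantom)
        with pytest.raises(ParameterError):
            sweep_thresholds([case], [])

    def test_no_cases_rejected(self):
        with pytest.raises(ParameterError):
            sweep_thresholds([], [3.0])

    def test_frame_output(self, oligo_phantom):
        case = self._single_case(oligo_phantom)
        frame = sweep_thresholds([case], [3.0]).to_frame()
        assert list(frame["suv_threshold"]) == [3.0]
        assert {"sensitivity", "specificity", "median_dsc",
                "volume_r"} <= set(frame.columns)


class TestSelectOptimum:
    def _sweep(self, sens, spec, dsc=None):
        n = len(sens)
        return SweepResult(
            thresholds=[2.0 + i for i in range(n)],
            sensitivity=sens, specificity=spec,
            dsc=dsc or [[0.5]] * n,
            volume_r=[1.0] * n, suvmean_r=[1.0] * n)

    def test_strict_peak_returned(self):
        sweep = self._sweep([0.9, 0.95, 0.7], [0.9, 0.99, 0.99])
        th, report = select_optimum_threshold(sweep)
        assert th == 3.0
        assert report["optimum_threshold"] == 3.0
        assert len(report["roc_points"]) == 3

    def test_tie_broken_by_median_dsc(self):
        sweep = self._sweep([0.8, 0.8], [0.9, 0.9],
                            dsc=[[0.4], [0.7]])
        th, _ = select_optimum_threshold(sweep)
        assert th == 3.0

    def test_full_tie_prefers_lower_threshold(self):
        sweep = self._sweep([0.8, 0.8], [0.9, 0.9], dsc=[[0.5], [0.5]])
        th, _ = select_optimum_threshold(sweep)
        assert th == 2.0

    def test_phantom_plateau_bounds_optimum(self):
        # every lesion plateau is 3.2: thresholds above lose all sensitivity
        spec = phantom.PhantomSpec(seed=3)
        spec.skeleton = phantom._default_skeleton(spec.fov_mm)
        spec.organs = []
        spec.lesions = [
            phantom.Lesion(centre=(87.0, 60.0, 40.0), radius_mm=6.0, suv=3.2),
            phantom.Lesion(centre=(45.0, 120.0, 100.0), radius_mm=6.0,
                           suv=3.2),
        ]
        result = phantom.generate_phantom(spec)
        products = run_pipeline(result)
        sweep = sweep_thresholds(
            [(products["suv"], products["bone"], result.truth_labels)],
            [2.0, 2.5, 3.0, 3.5, 4.0, 6.0])
        th, _ = select_optimum_threshold(sweep)
        assert th <= 3.2


class TestPatientReport:
    def test_perfect_segmentation_row(self, oligo_phantom):
        products = run_pipeline(oligo_phantom)
        result = evaluate_case(products["suv"], products["bone"],
                               oligo_phantom.truth_labels, 3.0)
        table, _ = patient_report([result])
        row = table.iloc[0]
        assert row["sensitivity_pct"] == pytest.approx(100.0)
        assert row["specificity_pct"] == pytest.approx(100.0)
        assert row["n_ref_lesions"] == row["n_auto_lesions"] == 3
        assert row["volume_r"] == pytest.approx(1.0)
        assert row["dsc"] == pytest.approx(1.0)

    def test_single_lesion_concordance_undefined(self):
        spec = phantom.PhantomSpec(seed=5)
        spec.skeleton = phantom._default_skeleton(spec.fov_mm)
        spec.lesions = [phantom.Lesion(centre=(87.0, 60.0, 60.0),
                                       radius_mm=6.0, suv=5.0)]
        result = phantom.generate_phantom(spec)
        products = run_pipeline(result)
        case = evaluate_case(products["suv"], products["bone"],
                             result.truth_labels, 3.0)
        table, _ = patient_report([case])
        assert np.isnan(table.iloc[0]["volume_r"])

    def test_cohort_row_count_and_count_r(self):
        cohort = phantom.random_cohort(5, seed=21)
        results = []
        for spec in cohort:
            ph = phantom.generate_phantom(spec)
            products = run_pipeline(ph)
            results.append(evaluate_case(products["suv"], products["bone"],
                                         ph.truth_labels, 3.0))
        table, count_r = patient_report(results)
        assert len(table) == 5
        assert count_r == pytest.approx(1.0)  # perfect count recovery


class TestUnmatchedAudit:
    def test_sub_threshold_lesion_lands_in_ref_only(self):
        spec = phantom.PhantomSpec(seed=13)
        spec.skeleton = phantom._default_skeleton(spec.fov_mm)
        spec.lesions = [
            phantom.Lesion(centre=(87.0, 60.0, 40.0), radius_mm=6.0, suv=5.0),
            phantom.Lesion(centre=(45.0, 120.0, 100.0), radius_mm=6.0,
                           suv=2.5),  # below SUV-Th 3.0 -> must be missed
        ]
        result = phantom.generate_phantom(spec)
        products = run_pipeline(result)
        case = evaluate_case(products["suv"], products["bone"],
                             result.truth_labels, 3.0)
        assert len(case.unmatched_ref) == 1
        assert case.unmatched_ref[0].suv_max == pytest.approx(2.5)
        audit = unmatched_report([case])
        assert list(audit["side"]) == ["ref_only"]
        assert set(audit.columns) >= {"volume_ml", "suv_mean", "suv_max"}
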