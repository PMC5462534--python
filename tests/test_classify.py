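"""Innervation/degeneration decision rules and myonuclear counting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nmjquant import (
    ClassificationThresholds,
    CoverageProfile,
    NMJGeometry,
    bin_myonuclear_counts,
    classify_postsynaptic,
    classify_presynaptic,
    count_myonuclei,
    generate_nmj_stack,
    sample_phantom_params,
    score_stack,
)
from nmjquant.morphometry import (
    compute_coverage,
    nucleus_overlap_fractions,
    quantify_geometry,
)


def _cov(devoid, runs):
    return CoverageProfile(
        per_branch_uncovered=list(enumerate(runs)),
        devoid_fraction=devoid,
        total_skeleton_length_um=60.0,
        reach_radius_um=1.0,
    )


class TestPresynapticRules:
    @pytest.mark.parametrize(
        "devoid,runs,expected",
        [
            (0.95, [0.0], "completely_denervated"),       # >90% devoid
            (0.0, [0.0, 0.0], "innervated"),
            (0.2, [6.0, 0.0], "partially_innervated"),    # >5 μm uncovered run
            (0.95, [20.0], "completely_denervated"),      # denervation tested first
            (0.5, [4.9], "innervated"),                   # below the 5 μm gap rule
        ],
    )
    def test_rule_table(self, devoid, runs, expected):
        assert classify_presynaptic(_cov(devoid, runs)) == expected

    def test_exhaustive_and_exclusive(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            devoid = rng.uniform(0, 1)
            runs = list(rng.uniform(0, 12, size=rng.integers(1, 6)))
            label = classify_presynaptic(_cov(devoid, runs))
            assert label in ("innervated", "partially_innervated", "completely_denervated")
            if label == "completely_denervated":
                assert devoid > 0.90


class TestPostsynapticRules:
    def test_many_elaborate_branches_intact(self):
        geom = NMJGeometry(100.0, 1e4, n_branches_ge_5um=6)
        assert classify_postsynaptic(geom) == "intact"

    def test_patch_without_branches_degenerated(self):
        geom = NMJGeometry(30.0, 1e3, n_branches_ge_5um=0)
        assert classify_postsynaptic(geom) == "degenerated"

    def test_single_branch_degenerated_under_default(self):
        geom = NMJGeometry(50.0, 1e3, n_branches_ge_5um=1)
        assert classify_postsynaptic(geom) == "degenerated"
        loose = ClassificationThresholds(min_elaborate_branches=1)
        assert classify_postsynaptic(geom, loose) == "intact"


class TestMyonuclearCount:
    def test_all_below_threshold(self):
        assert count_myonuclei([0.0, 0.1, 0.24]) == 0

    def test_all_above_threshold(self):
        assert count_myonuclei([0.26, 0.9, 1.0]) == 3

    def test_boundary_is_strict(self):
        assert count_myonuclei([0.25]) == 0
        assert count_myonuclei([0.25 + 1e-9]) == 1

    def test_accepts_id_fraction_pairs(self):
        assert count_myonuclei([(1, 0.5), (2, 0.1)]) == 1

    def test_out_of_range_fraction_rejected(self):
        with pytest.raises(ValueError):
            count_myonuclei([1.2])


class TestBinning:
    def test_direct_binning(self):
        bins = bin_myonuclear_counts([0, 1, 2, 3, 4, 5, 6])
        assert bins["0-2"] == pytest.approx(3 / 7)
        assert bins["3-4"] == pytest.approx(2 / 7)
        assert bins[">4"] == pytest.approx(2 / 7)

    def test_all_large_clusters(self):
        assert bin_myonuclear_counts([5, 5, 5])[">4"] == 1.0

    def test_empty_flagged(self):
        bins = bin_myonuclear_counts([])
        assert bins["defined"] is False

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            bin_myonuclear_counts([-1])

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.integers(min_value=0, max_value=12), min_size=1, max_size=40))
    def test_proportions_sum_to_one(self, counts):
        bins = bin_myonuclear_counts(counts)
        assert bins["0-2"] + bins["3-4"] + bins[">4"] == pytest.approx(1.0)


class TestThresholdValidation:
    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError):
            ClassificationThresholds(denervated_devoid_fraction=1.5)
        with pytest.raises(ValueError):
            ClassificationThresholds(branch_gap_um=-1)
        with pytest.raises(ValueError):
            ClassificationThresholds.from_config({"nonsense_key": 1})


class TestGroundTruthRecovery:
    def test_rules_on_truth_masks_reproduce_truth_labels(self):
        """Classifying the noiseless ground-truth masks (no segmentation)
        reproduces the generator's class labels and myonuclear counts."""
        from test_morphometry import _seg_from_masks

        rng = np.random.default_rng(77)
        for _ in range(40):
            params = sample_phantom_params(rng)
            _, gt = generate_nmj_stack(params)
            seg = _seg_from_masks(gt.post_mask, gt.pre_mask, gt.nucleus_labels,
                                  params.voxel_size)
            cov = compute_coverage(seg, reach_radius=1.0)
            overlaps = nucleus_overlap_fractions(seg)
            n_elab = sum(1 for b in seg.branches if b.length_um > 5.0)
            geom = NMJGeometry(0.0, 0.0, n_branches_ge_5um=n_elab)
            assert classify_presynaptic(cov) == gt.true_class_pre
            assert classify_postsynaptic(geom) == gt.true_class_post
            assert count_myonuclei(overlaps) == gt.true_myonuclear_count

    def test_coverage_monotone_in_coverage_fraction(self):
        """Raising pre-synaptic coverage never moves an NMJ toward
        denervation (class ordered innervated < partial < denervated)."""
        order = {"innervated": 0, "partially_innervated": 1, "completely_denervated": 2}
        from nmjquant import NMJPhantomParams

        base = dict(n_branches=3, seed=31, n_postsynaptic_nuclei=1,
                    n_nonsynaptic_nuclei=1)
        labels = []
        for cf in (0.0, 0.5, 1.0):
            stack, _ = generate_nmj_stack(NMJPhantomParams(coverage_fraction=cf, **base))
            labels.append(order[score_stack(stack).pre_class])
        assert labels[0] >= labels[1] >= labels[2]
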