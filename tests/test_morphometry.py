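"""Segmentation, skeleton coverage, geometry and nucleus-overlap measurement."""

import numpy as np
import pytest
from scipy import ndimage

from _oracle import brute_force_coverage
from nmjquant import (
    ConfocalStack,
    MorphometryConfig,
    NMJPhantomParams,
    compute_coverage,
    generate_nmj_stack,
    nucleus_overlap_fractions,
    quantify_geometry,
    segment_channels,
)
from nmjquant.morphometry import NMJSegmentation
from nmjquant._skeleton import skeleton_branches


def _seg_from_masks(post, pre, nuclei, voxel_size):
    from skimage.morphology import skeletonize

    skel = skeletonize(post)
    if post.any() and not skel.any():
        skel = np.zeros_like(post)
        d = ndimage.distance_transform_edt(post, sampling=voxel_size)
        skel[np.unravel_index(int(d.argmax()), post.shape)] = True
    return NMJSegmentation(
        post_mask=post, pre_mask=pre, nucleus_labels=nuclei,
        branches=skeleton_branches(skel, voxel_size), voxel_size=voxel_size,
    )


def _tube_stack(vs=(0.44, 0.25, 0.25), shape=(20, 48, 48)):
    """A straight horizontal tube with a matching pre tube above it."""
    post = np.zeros(shape, dtype=bool)
    zc, yc = 10, 24
    zz, yy, xx = np.indices(shape)
    phys = np.stack([(zz - zc) * vs[0], (yy - yc) * vs[1]], axis=0)
    r = np.sqrt((phys ** 2).sum(axis=0))
    post[(r <= 1.2) & (xx >= 6) & (xx <= 42)] = True
    return post, vs


class TestSegmentChannels:
    def test_noiseless_post_mask_close_to_truth(self):
        stack, gt = generate_nmj_stack(NMJPhantomParams(seed=4))
        seg = segment_channels(stack)
        inter = (seg.post_mask & gt.post_mask).sum()
        union = (seg.post_mask | gt.post_mask).sum()
        assert inter / union >= 0.95

    def test_all_zero_achr_flags_no_nmj(self):
        vox = np.zeros((3, 8, 32, 32), dtype=np.float32)
        vox[2, 4, 10:14, 10:14] = 50.0  # some DAPI, no AChR
        stack = ConfocalStack(vox, ["AChR", "nerve", "DAPI"], (0.44, 0.25, 0.25))
        seg = segment_channels(stack)
        assert not seg.nmj_found
        assert not seg.post_mask.any()
        assert seg.branches == []

    def test_all_zero_nerve_channel_gives_empty_pre_mask(self):
        stack, _ = generate_nmj_stack(NMJPhantomParams(coverage_fraction=0.0, seed=2))
        seg = segment_channels(stack)
        assert not seg.pre_mask.any()

    def test_two_separated_nuclei_get_two_labels(self):
        vs = (0.44, 0.25, 0.25)
        vox = np.zeros((3, 24, 64, 64), dtype=np.float32)
        vox[0, 10:13, 28:36, 28:36] = 100.0  # an AChR blob so nmj_found
        zz, yy, xx = np.indices((24, 64, 64)).astype(float)
        for cz, cy, cx in ((8, 12, 12), (8, 44, 44)):
            r = (((zz - cz) * vs[0] / 1.8) ** 2 + ((yy - cy) * vs[1] / 2.4) ** 2
                 + ((xx - cx) * vs[2] / 2.4) ** 2)
            vox[2][r <= 1.0] = 100.0
        stack = ConfocalStack(vox, ["AChR", "nerve", "DAPI"], vs)
        seg = segment_channels(stack)
        n_labels = len(np.unique(seg.nucleus_labels)) - 1
        # oracle: plain connected components on the noiseless truth
        cc, n_cc = ndimage.label(vox[2] > 50)
        assert n_cc == 2
        assert n_labels == 2


class TestCoverage:
    def test_full_apposition_zero_devoid(self):
        post, vs = _tube_stack()
        pre = ndimage.binary_dilation(post, iterations=2)
        seg = _seg_from_masks(post, pre, np.zeros_like(post, np.int32), vs)
        cov = compute_coverage(seg, reach_radius=1.0)
        assert cov.devoid_fraction == 0.0
        assert cov.max_uncovered_um == 0.0

    def test_empty_pre_mask_fully_devoid(self):
        post, vs = _tube_stack()
        seg = _seg_from_masks(post, np.zeros_like(post), np.zeros_like(post, np.int32), vs)
        cov = compute_coverage(seg, reach_radius=1.0)
        assert cov.devoid_fraction == 1.0

    def test_generator_gap_recovered_within_one_voxel(self):
        params = NMJPhantomParams(
            coverage_fraction=1.0, uncovered_gap_lengths=(6.0,),
            branch_length_range=(12.0, 14.0), seed=8,
        )
        stack, gt = generate_nmj_stack(params)
        seg = segment_channels(stack)
        cov = compute_coverage(seg, reach_radius=1.0)
        # one voxel-length diagonal step at (0.44, 0.25, 0.25) μm
        tol = float(np.linalg.norm(params.voxel_size))
        assert cov.max_uncovered_um == pytest.approx(6.0, abs=2 * tol)

    def test_matches_brute_force_oracle(self, small_phantom_batch):
        for _, stack, _, _ in small_phantom_batch[:4]:
            seg = segment_channels(stack)
            cov = compute_coverage(seg, reach_radius=1.0)
            oracle_runs, oracle_devoid = brute_force_coverage(seg, 1.0)
            assert cov.devoid_fraction == pytest.approx(oracle_devoid, abs=1e-9)
            lib_runs = [r for _, r in cov.per_branch_uncovered]
            assert lib_runs == pytest.approx(oracle_runs, abs=1e-9)

    def test_enlarging_pre_mask_never_increases_devoidness(self):
        stack, _ = generate_nmj_stack(NMJPhantomParams(
            coverage_fraction=0.5, n_branches=3, branch_length_range=(7.0, 11.0),
            seed=13))
        seg = segment_channels(stack)
        cov0 = compute_coverage(seg, reach_radius=1.0)
        seg_big = NMJSegmentation(
            post_mask=seg.post_mask,
            pre_mask=ndimage.binary_dilation(seg.pre_mask, iterations=2),
            nucleus_labels=seg.nucleus_labels,
            branches=seg.branches, voxel_size=seg.voxel_size,
        )
        cov1 = compute_coverage(seg_big, reach_radius=1.0)
        assert cov1.devoid_fraction <= cov0.devoid_fraction + 1e-12
        for (_, r0), (_, r1) in zip(cov0.per_branch_uncovered, cov1.per_branch_uncovered):
            assert r1 <= r0 + 1e-12

    def test_bad_reach_radius(self):
        post, vs = _tube_stack()
        seg = _seg_from_masks(post, post, np.zeros_like(post, np.int32), vs)
        with pytest.raises(ValueError):
            compute_coverage(seg, reach_radius=0.0)


class TestGeometry:
    def test_box_volume_is_exact_arithmetic(self):
        vs = (0.44, 0.2, 0.2)
        post = np.zeros((16, 32, 32), dtype=bool)
        post[2:12, 4:14, 4:14] = True  # 10×10×10 voxels
        vox = np.zeros((3, 16, 32, 32), dtype=np.float32)
        vox[0, post] = 7.0
        stack = ConfocalStack(vox, ["AChR", "nerve", "DAPI"], vs)
        seg = _seg_from_masks(post, np.zeros_like(post), np.zeros_like(post, np.int32), vs)
        geom = quantify_geometry(seg, stack)
        assert geom.volume_um3 == pytest.approx(1000 * 0.44 * 0.2 * 0.2)  # 17.6
        assert geom.cumulative_intensity == pytest.approx(7000.0)

    def test_intensity_linear_volume_invariant(self):
        stack, _ = generate_nmj_stack(NMJPhantomParams(seed=6))
        seg = segment_channels(stack)
        g1 = quantify_geometry(seg, stack)
        doubled = ConfocalStack(
            np.concatenate([stack.voxels[:1] * 2, stack.voxels[1:]]),
            stack.channel_names, stack.voxel_size,
        )
        g2 = quantify_geometry(seg, doubled)
        assert g2.cumulative_intensity == pytest.approx(2 * g1.cumulative_intensity)
        assert g2.volume_um3 == g1.volume_um3

    def test_scale_invariance_of_volume_and_lengths(self):
        base = dict(coverage_fraction=1.0, uncovered_gap_lengths=(6.0,),
                    branch_length_range=(12.0, 14.0), n_branches=2,
                    n_postsynaptic_nuclei=0, n_nonsynaptic_nuclei=0, seed=21)
        p_coarse = NMJPhantomParams(**base)
        p_fine = NMJPhantomParams(**base, voxel_size=(0.22, 0.125, 0.125))
        _, gt_c = generate_nmj_stack(p_coarse)
        _, gt_f = generate_nmj_stack(p_fine)
        assert gt_f.true_volume == pytest.approx(gt_c.true_volume, rel=0.03)
        assert max(gt_f.true_uncovered_lengths) == pytest.approx(
            max(gt_c.true_uncovered_lengths), abs=float(np.linalg.norm(p_coarse.voxel_size))
        )


class TestNucleusOverlap:
    def _stack_with_nucleus(self, offset_vox):
        vs = (0.44, 0.25, 0.25)
        shape = (28, 64, 64)
        post = np.zeros(shape, dtype=bool)
        post[12:17, 20:44, 20:44] = True  # a slab
        nuc = np.zeros(shape, dtype=np.int32)
        zz, yy, xx = np.indices(shape).astype(float)
        cz, cy, cx = 14 + offset_vox, 32, 32
        r = (((zz - cz) * vs[0] / 1.5) ** 2 + ((yy - cy) * vs[1] / 2.0) ** 2
             + ((xx - cx) * vs[2] / 2.0) ** 2)
        nuc[r <= 1.0] = 1
        return _seg_from_masks(post, np.zeros_like(post), nuc, vs)

    def test_nucleus_inside_dilated_mask_fraction_one(self):
        seg = self._stack_with_nucleus(offset_vox=0)
        fr = nucleus_overlap_fractions(seg)
        assert fr == [(1, pytest.approx(1.0))]

    def test_distant_nucleus_fraction_zero(self):
        seg = self._stack_with_nucleus(offset_vox=12)  # > radius + apposition away
        fr = nucleus_overlap_fractions(seg)
        assert fr[0][1] == 0.0

    def test_phantom_target_fraction_recovered(self):
        params = NMJPhantomParams(seed=5, n_postsynaptic_nuclei=1,
                                  n_nonsynaptic_nuclei=0,
                                  nucleus_overlap_targets=(0.40,))
        stack, gt = generate_nmj_stack(params)
        seg = segment_channels(stack)
        fr = nucleus_overlap_fractions(seg)
        assert len(fr) == 1
        assert fr[0][1] == pytest.approx(0.40, abs=0.05)


class TestSkeletonBranches:
    def test_straight_line_single_branch_length(self):
        vs = (0.44, 0.25, 0.25)
        skel = np.zeros((5, 5, 40), dtype=bool)
        skel[2, 2, 5:35] = True
        branches = skeleton_branches(skel, vs)
        assert len(branches) == 1
        assert branches[0].length_um == pytest.approx(29 * 0.25)

    def test_cross_decomposes_into_four_long_arms(self):
        vs = (1.0, 1.0, 1.0)
        skel = np.zeros((3, 21, 21), dtype=bool)
        skel[1, 10, :] = True
        skel[1, :, 10] = True  # 4 arms of 10 voxels around a center clique
        branches = skeleton_branches(skel, vs)
        long_arms = [b for b in branches if b.length_um >= 5.0]
        assert len(long_arms) == 4
        assert sum(b.length_um for b in branches) == pytest.approx(40.0, abs=3.0)

    def test_leaf_chain_is_pruned_and_path_merges(self):
        vs = (1.0, 1.0, 1.0)
        skel = np.zeros((8, 12, 30), dtype=bool)
        skel[2, 4, :] = True
        for i, (dy, dx) in enumerate([(1, 0), (2, 1), (3, 2)]):
            skel[3 + i, 4 + dy, 15 + dx] = True  # 3-voxel twig off the path
        branches = skeleton_branches(skel, vs, prune_um=4.0)
        assert len(branches) == 1
        # one through-branch; junction cleanup may detour it by ≤ 2 diagonals
        assert branches[0].length_um == pytest.approx(29.0, abs=2.0)

    def test_isolated_voxel_kept_as_zero_length_branch(self):
        skel = np.zeros((3, 3, 3), dtype=bool)
        skel[1, 1, 1] = True
        branches = skeleton_branches(skel, (1.0, 1.0, 1.0))
        assert len(branches) == 1
        assert branches[0].length_um == 0.0
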