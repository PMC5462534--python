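"""From a confocal stack to measured NMJ quantities.

The neuromuscular junction (NMJ) is measured on three channels: the
α-bungarotoxin-labelled acetylcholine-receptor (AChR) channel defines
the post-synaptic apparatus ("pretzel"), a nerve-terminal marker
cocktail defines the pre-synaptic terminal, and DAPI defines nuclei.

Pipeline:

1. :func:`segment_channels` — per-channel Gaussian smoothing + Otsu
   threshold; the largest connected AChR component is the NMJ; nuclei
   are split by a watershed on the distance transform; the post-synaptic
   mask is skeletonized and decomposed into branches with physical
   geodesic lengths.
2. :func:`compute_coverage` — a skeleton voxel counts as *covered* when
   any pre-synaptic voxel lies within ``reach_radius`` μm of it
   (apposed membranes are near, not colocalized). Reports the maximal
   contiguous uncovered geodesic run per branch and the devoid fraction
   of the whole skeleton.
3. :func:`quantify_geometry` — post-synaptic volume, cumulative AChR
   intensity, and the number of elaborate (>5 μm) branches.
4. :func:`nucleus_overlap_fractions` — per-nucleus fraction of DAPI
   volume lying within the post-synaptic apparatus dilated by an
   apposition radius (synaptic myonuclei sit under, not inside, the
   endplate).

All thresholds live in :class:`MorphometryConfig` and are echoed into
outputs for provenance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.morphology import skeletonize
from skimage.segmentation import watershed

from ._skeleton import Branch, skeleton_branches
from .stack import ConfocalStack

__all__ = [
    "MorphometryConfig",
    "NMJSegmentation",
    "CoverageProfile",
    "NMJGeometry",
    "segment_channels",
    "compute_coverage",
    "quantify_geometry",
    "nucleus_overlap_fractions",
]


@dataclass
class MorphometryConfig:
    """Tunable measurement parameters (all physical units).

    smooth_sigma_um
        Gaussian pre-smoothing applied before Otsu thresholding.
    reach_radius_um
        Proximity radius defining pre-synaptic coverage of a skeleton
        voxel.
    apposition_radius_um
        Dilation of the post-synaptic mask used when intersecting
        nuclei (myonuclei appose the endplate from below).
    min_pre_object_um3, min_nucleus_volume_um3
        Small-object rejection for the noisy pre-synaptic and DAPI
        masks.
    nucleus_peak_min_distance_um
        Minimum separation of watershed seed peaks when splitting
        touching nuclei.
    """

    smooth_sigma_um: float = 0.2
    reach_radius_um: float = 1.0
    apposition_radius_um: float = 1.0
    min_pre_object_um3: float = 0.5
    min_nucleus_volume_um3: float = 8.0
    nucleus_peak_min_distance_um: float = 2.0
    achr_channel: str = "AChR"
    nerve_channel: str = "nerve"
    dapi_channel: str = "DAPI"


@dataclass
class NMJSegmentation:
    """Binary masks plus the skeleton of the post-synaptic apparatus."""

    post_mask: np.ndarray      # bool (z, y, x), BTX+ post-synaptic apparatus
    pre_mask: np.ndarray       # bool, nerve-terminal cocktail
    nucleus_labels: np.ndarray  # int labels, 0 = background
    branches: list[Branch]
    voxel_size: tuple[float, float, float]
    nmj_found: bool = True

    @property
    def skeleton_mask(self) -> np.ndarray:
        m = np.zeros(self.post_mask.shape, dtype=bool)
        for b in self.branches:
            m[tuple(b.path.T)] = True
        return m


@dataclass
class CoverageProfile:
    """Pre-synaptic coverage of the post-synaptic skeleton."""

    per_branch_uncovered: list[tuple[int, float]]  # (branch id, max contiguous uncovered μm)
    devoid_fraction: float
    total_skeleton_length_um: float
    reach_radius_um: float

    @property
    def covered_fraction(self) -> float:
        return 1.0 - self.devoid_fraction

    @property
    def max_uncovered_um(self) -> float:
        if not self.per_branch_uncovered:
            return 0.0
        return max(u for _, u in self.per_branch_uncovered)


@dataclass
class NMJGeometry:
    volume_um3: float
    cumulative_intensity: float
    n_branches_ge_5um: int
    branch_lengths_um: list[float] = field(default_factory=list)
    concave_side_normal: tuple[float, float, float] | None = None


def _sigma_voxels(sigma_um: float, voxel_size: tuple[float, float, float]) -> tuple[float, ...]:
    return tuple(sigma_um / v for v in voxel_size)


def _otsu_mask(
    channel: np.ndarray, sigma_vox: tuple[float, ...], min_separation: float = 6.0
) -> np.ndarray:
    """Gaussian smoothing + Otsu, with a signal floor.

    Otsu always splits the histogram, even when a channel contains
    nothing but noise; the split is only kept when the foreground mean
    exceeds the background by ``min_separation`` background standard
    deviations, otherwise the channel is declared empty.
    """
    smoothed = ndimage.gaussian_filter(channel.astype(np.float64), sigma=sigma_vox)
    if smoothed.max() <= smoothed.min():
        return np.zeros(channel.shape, dtype=bool)
    mask = smoothed > threshold_otsu(smoothed)
    if not mask.any() or mask.all():
        return np.zeros(channel.shape, dtype=bool)
    bg = smoothed[~mask]
    separation = (smoothed[mask].mean() - bg.mean()) / (bg.std() + 1e-12)
    if separation < min_separation:
        return np.zeros(channel.shape, dtype=bool)
    return mask


def _remove_small(mask: np.ndarray, min_voxels: int) -> np.ndarray:
    if min_voxels <= 1 or not mask.any():
        return mask
    labels, n = ndimage.label(mask)
    if n == 0:
        return mask
    counts = np.bincount(labels.ravel())
    keep = counts >= min_voxels
    keep[0] = False
    return keep[labels]


def _largest_component(mask: np.ndarray) -> np.ndarray:
    labels, n = ndimage.label(mask)
    if n == 0:
        return mask
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return labels == int(counts.argmax())


def segment_channels(stack: ConfocalStack, cfg: MorphometryConfig | None = None) -> NMJSegmentation:
    """Segment AChR / nerve-terminal / DAPI channels of one NMJ stack.

    An all-zero AChR channel yields a segmentation with
    ``nmj_found=False`` and empty masks rather than an exception, so
    batch scoring can record "no NMJ found" per stack.
    """
    cfg = cfg or MorphometryConfig()
    vs = stack.voxel_size
    sig = _sigma_voxels(cfg.smooth_sigma_um, vs)
    voxel_volume = float(np.prod(vs))

    achr = stack.channel(cfg.achr_channel)
    post = _otsu_mask(achr, sig)
    found = bool(post.any())
    if found:
        post = _largest_component(post)

    nerve = stack.channel(cfg.nerve_channel)
    pre = _otsu_mask(nerve, sig)
    pre = _remove_small(pre, int(round(cfg.min_pre_object_um3 / voxel_volume)))

    dapi = stack.channel(cfg.dapi_channel)
    nuc_mask = _otsu_mask(dapi, sig)
    nuc_mask = _remove_small(nuc_mask, int(round(cfg.min_nucleus_volume_um3 / voxel_volume)))
    nucleus_labels = _split_nuclei(nuc_mask, vs, cfg)

    branches = []
    if found:
        skel = skeletonize(post)
        if not skel.any():
            # thinning can erase a compact patch entirely; keep its center
            # (distance-transform maximum) so coverage is still defined
            skel = np.zeros_like(post)
            dist_in = ndimage.distance_transform_edt(post, sampling=vs)
            skel[np.unravel_index(int(dist_in.argmax()), post.shape)] = True
        branches = skeleton_branches(skel, vs)
    return NMJSegmentation(
        post_mask=post,
        pre_mask=pre,
        nucleus_labels=nucleus_labels,
        branches=branches,
        voxel_size=vs,
        nmj_found=found,
    )


def _split_nuclei(mask: np.ndarray, voxel_size, cfg: MorphometryConfig) -> np.ndarray:
    if not mask.any():
        return np.zeros(mask.shape, dtype=np.int32)
    dist = ndimage.distance_transform_edt(mask, sampling=voxel_size)
    cc, _ = ndimage.label(mask)
    min_dist_vox = max(1, int(round(cfg.nucleus_peak_min_distance_um / min(voxel_size))))
    peaks = peak_local_max(dist, min_distance=min_dist_vox, labels=cc, exclude_border=False)
    if len(peaks) == 0:
        return cc.astype(np.int32)
    markers = np.zeros(mask.shape, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    labels = watershed(-dist, markers, mask=mask)
    return labels.astype(np.int32)


def compute_coverage(seg: NMJSegmentation, reach_radius: float | None = None) -> CoverageProfile:
    """Measure pre-synaptic coverage of the post-synaptic skeleton.

    A skeleton voxel is covered iff the nearest pre-synaptic voxel
    center lies within ``reach_radius`` μm (exact Euclidean distance
    transform with anisotropic sampling). Per branch, the maximal
    contiguous uncovered geodesic run is reported; the devoid fraction
    is uncovered skeleton length over total skeleton length, each step
    weighted by the mean uncovered state of its two endpoints.
    """
    reach = seg_reach = reach_radius if reach_radius is not None else MorphometryConfig().reach_radius_um
    if reach <= 0:
        raise ValueError(f"reach_radius must be positive, got {reach}")

    vs = np.asarray(seg.voxel_size, dtype=float)
    if seg.pre_mask.any():
        dist_to_pre = ndimage.distance_transform_edt(~seg.pre_mask, sampling=tuple(vs))
    else:
        dist_to_pre = np.full(seg.pre_mask.shape, np.inf)

    per_branch: list[tuple[int, float]] = []
    covered_len = 0.0
    total_len = 0.0
    # fallback accounting for zero-length (single-voxel) skeletons
    n_vox = 0
    n_vox_covered = 0

    for bid, br in enumerate(seg.branches):
        pts = br.path
        d = dist_to_pre[tuple(pts.T)]
        uncovered = d > reach
        n_vox += len(pts)
        n_vox_covered += int((~uncovered).sum())
        if len(pts) < 2:
            per_branch.append((bid, 0.0))
            continue
        steps = np.sqrt((((np.diff(pts, axis=0)) * vs) ** 2).sum(axis=1))
        total_len += float(steps.sum())
        w_unc = 0.5 * (uncovered[:-1].astype(float) + uncovered[1:].astype(float))
        covered_len += float((steps * (1.0 - w_unc)).sum())
        # maximal contiguous uncovered run: sum of steps joining consecutive
        # uncovered voxels
        max_run = 0.0
        run = 0.0
        in_run = False
        for i in range(len(pts)):
            if uncovered[i]:
                if in_run:
                    run += float(steps[i - 1])
                in_run = True
                max_run = max(max_run, run)
            else:
                in_run = False
                run = 0.0
        per_branch.append((bid, max_run))

    if total_len > 0:
        devoid = 1.0 - covered_len / total_len
    elif n_vox > 0:
        devoid = 1.0 - n_vox_covered / n_vox
    else:
        devoid = 1.0
    devoid = min(1.0, max(0.0, devoid))
    return CoverageProfile(
        per_branch_uncovered=per_branch,
        devoid_fraction=devoid,
        total_skeleton_length_um=total_len,
        reach_radius_um=float(seg_reach),
    )


def quantify_geometry(
    seg: NMJSegmentation,
    stack: ConfocalStack,
    cfg: MorphometryConfig | None = None,
    elaborate_branch_min_um: float = 5.0,
) -> NMJGeometry:
    """Post-synaptic volume, cumulative AChR intensity, elaborate-branch count.

    Volume is the voxel count of the post-synaptic mask times the voxel
    volume; cumulative intensity sums the AChR channel over that mask.
    """
    cfg = cfg or MorphometryConfig()
    voxel_volume = float(np.prod(seg.voxel_size))
    volume = float(seg.post_mask.sum()) * voxel_volume
    achr = stack.channel(cfg.achr_channel)
    cumulative = float(achr[seg.post_mask].sum())
    lengths = [b.length_um for b in seg.branches]
    n_elab = int(sum(1 for L in lengths if L > elaborate_branch_min_um))
    return NMJGeometry(
        volume_um3=volume,
        cumulative_intensity=cumulative,
        n_branches_ge_5um=n_elab,
        branch_lengths_um=lengths,
    )


def nucleus_overlap_fractions(
    seg: NMJSegmentation, cfg: MorphometryConfig | None = None
) -> list[tuple[int, float]]:
    """Per-nucleus fraction of volume inside the dilated post-synaptic mask.

    fraction = |nucleus ∩ dilate(post, apposition_radius)| / |nucleus|,
    computed in 3D. Zero-volume labels are excluded with a warning.
    """
    cfg = cfg or MorphometryConfig()
    labels = seg.nucleus_labels
    ids = np.unique(labels)
    ids = ids[ids > 0]
    if len(ids) == 0:
        return []
    if seg.post_mask.any():
        dist = ndimage.distance_transform_edt(~seg.post_mask, sampling=seg.voxel_size)
        dilated = dist <= cfg.apposition_radius_um
    else:
        dilated = np.zeros(seg.post_mask.shape, dtype=bool)

    out: list[tuple[int, float]] = []
    sizes = ndimage.sum_labels(np.ones(labels.shape), labels, ids)
    inter = ndimage.sum_labels(dilated.astype(float), labels, ids)
    for nid, size, ov in zip(ids, sizes, inter):
        if size == 0:
            warnings.warn(f"nucleus label {nid} has zero volume; excluded")
            continue
        out.append((int(nid), float(ov / size)))
    return out
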