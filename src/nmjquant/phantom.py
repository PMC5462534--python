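"""Ground-truth-labelled synthetic data: 3D NMJ stacks and 2D fiber sections.

The NMJ phantom emulates the geometry the scoring procedure assumes:

* a branched tubular post-synaptic "pretzel" — tubes of radius
  ``branch_radius`` along smooth curves branching off a central arc,
  draped over a gently curved sheet so the junction has a defined
  concave (muscle) side;
* a pre-synaptic terminal synthesized as a tube along the *covered*
  intervals of the post-synaptic centerline, offset toward the convex
  side — so the uncovered geodesic length is exactly controllable via
  ``coverage_fraction`` and explicitly carved gaps;
* ellipsoidal nuclei placed by bisection to hit requested overlap
  fractions with the (dilated) post-synaptic apparatus, plus
  non-synaptic nuclei placed clear of it;
* Gaussian PSF blur, then Gaussian read noise (optional Poisson shot
  noise) — ground truth is exact pre-noise.

Ground-truth coverage quantities (per-branch uncovered runs, devoid
fraction, innervation class) are computed from the *continuous*
centerline geometry with the same proximity ("reach") definition the
analysis uses, via exact point-to-tube distances — independent of the
voxel grid the measurement pipeline sees. Carved gaps are widened by the
geometric reach margin so a nominal 6 μm gap produces a 6 μm uncovered
run under the default reach radius.

All geometry is in micrometres; arrays are indexed ``(z, y, x)``. The
axial voxel step defaults to 0.44 μm (the acquisition convention), with
0.25 μm lateral pixels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .classify import ClassificationThresholds, classify_postsynaptic, classify_presynaptic
from .morphometry import CoverageProfile, NMJGeometry
from .stack import ConfocalStack, SectionImage

__all__ = [
    "PhantomBoundsError",
    "NMJPhantomParams",
    "GroundTruth",
    "generate_nmj_stack",
    "sample_phantom_params",
    "CLASS_COMBINATIONS",
    "voxelized_ellipsoid_volume",
    "FiberPhantomParams",
    "FiberGroundTruth",
    "generate_fiber_section",
]

_CENTERLINE_STEP = 0.2  # μm arclength sampling of phantom curves


class PhantomBoundsError(ValueError):
    """The requested phantom geometry does not fit inside the stack."""


@dataclass
class NMJPhantomParams:
    """Parameters of one synthetic NMJ stack.

    ``coverage_fraction`` is the fraction of post-synaptic centerline
    arclength overlaid by pre-synaptic signal; ``uncovered_gap_lengths``
    are explicit gaps (μm of uncovered run) carved on top of it.
    ``nucleus_overlap_targets`` are requested overlap fractions for the
    post-synaptic nuclei; overlaps much above ~0.6 are geometrically
    unattainable for a nucleus apposed to a thin tube, in which case the
    closest achievable fraction is produced (and recorded as truth).
    """

    n_branches: int = 4
    branch_length_range: tuple[float, float] = (8.0, 15.0)
    branch_radius: float = 1.2
    trunk_length: float = 15.0
    coverage_fraction: float = 1.0
    uncovered_gap_lengths: Sequence[float] = ()
    n_postsynaptic_nuclei: int = 3
    n_nonsynaptic_nuclei: int = 3
    nucleus_radii: tuple[float, float, float] = (1.8, 2.4, 2.4)  # (z, y, x) semi-axes
    nucleus_overlap_targets: Sequence[float] | None = None
    voxel_size: tuple[float, float, float] = (0.44, 0.25, 0.25)
    psf_sigma: tuple[float, float, float] = (0.4, 0.2, 0.2)
    noise_sd: float = 0.0
    poisson_noise: bool = False
    amplitude: float = 100.0
    stack_extent: tuple[float, float, float] = (14.0, 38.0, 38.0)  # μm (z, y, x)
    pre_radius: float = 0.9
    pre_offset: float = 1.2
    coverage_reach: float = 1.0  # μm; matches the analysis default reach radius
    sheet_radius: float = 60.0   # curvature radius of the endplate sheet
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.coverage_fraction <= 1.0:
            raise ValueError("coverage_fraction must lie in [0, 1]")
        lo, hi = self.branch_length_range
        if lo <= 0 or hi <= 0 or lo > hi:
            raise ValueError("branch_length_range must be positive with min <= max")
        for name in ("branch_radius", "trunk_length", "pre_radius", "pre_offset",
                     "coverage_reach", "amplitude"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if any(v <= 0 for v in self.voxel_size) or any(v <= 0 for v in self.stack_extent):
            raise ValueError("voxel_size and stack_extent must be positive")
        if any(r <= 0 for r in self.nucleus_radii):
            raise ValueError("nucleus_radii must be positive")
        if any(g <= 0 for g in self.uncovered_gap_lengths):
            raise ValueError("gap lengths must be positive")
        if self.nucleus_overlap_targets is not None:
            if any(not 0.0 <= t <= 1.0 for t in self.nucleus_overlap_targets):
                raise ValueError("nucleus_overlap_targets must lie in [0, 1]")
        if self.n_branches < 0 or self.n_postsynaptic_nuclei < 0 or self.n_nonsynaptic_nuclei < 0:
            raise ValueError("counts must be non-negative")


@dataclass
class GroundTruth:
    """Voxel-exact and continuous-geometry truth for one phantom stack."""

    post_mask: np.ndarray
    pre_mask: np.ndarray
    nucleus_labels: np.ndarray
    nucleus_overlap_fractions: list[float]
    true_branch_lengths: list[float]
    true_uncovered_lengths: list[float]  # per-branch maximal contiguous uncovered run
    true_devoid_fraction: float
    true_class_pre: str
    true_class_post: str
    true_myonuclear_count: int
    true_volume: float               # μm³, |post_mask| × voxel volume
    true_cumulative_intensity: float  # noiseless AChR sum over post_mask
    concave_side_normal: tuple[float, float, float] = (-1.0, 0.0, 0.0)

    def to_json_dict(self) -> dict:
        """Scalar/list truth for the JSON sidecar (masks are saved as TIFF)."""
        d = asdict(self)
        for key in ("post_mask", "pre_mask", "nucleus_labels"):
            d.pop(key)
        return d


# ---------------------------------------------------------------------------
# centerline geometry


def _resample_polyline(pts: np.ndarray, step: float) -> np.ndarray:
    """Resample a polyline to uniform arclength spacing (keeps endpoints)."""
    seg = np.sqrt(((np.diff(pts, axis=0)) ** 2).sum(axis=1))
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    n = max(2, int(round(total / step)) + 1)
    s = np.linspace(0.0, total, n)
    out = np.empty((n, pts.shape[1]))
    for d in range(pts.shape[1]):
        out[:, d] = np.interp(s, cum, pts[:, d])
    return out


def _arclength(pts: np.ndarray) -> np.ndarray:
    seg = np.sqrt(((np.diff(pts, axis=0)) ** 2).sum(axis=1))
    return np.concatenate([[0.0], np.cumsum(seg)])


def _build_centerlines(params: NMJPhantomParams, rng: np.random.Generator) -> list[dict]:
    """Plan trunk + side branches in the (y, x) parameter plane, lift to 3D.

    Returns a list of branch dicts with keys ``points`` (N×3 physical
    z,y,x), ``cumlen`` (N,), ``length``.
    """
    _, Y, X = params.stack_extent
    y0, x0 = Y / 2.0, X / 2.0
    margin = params.branch_radius + 1.5

    phi = rng.uniform(0, 2 * np.pi)
    cphi, sphi = math.cos(phi), math.sin(phi)
    curve_c = rng.uniform(0.01, 0.03) * rng.choice([-1.0, 1.0])

    half = params.trunk_length / 2.0
    u = np.arange(-half, half + _CENTERLINE_STEP / 2, _CENTERLINE_STEP)
    w = curve_c * u ** 2
    trunk_yx = np.column_stack([
        y0 + u * sphi + w * cphi,
        x0 + u * cphi - w * sphi,
    ])
    trunk_yx = _resample_polyline(trunk_yx, _CENTERLINE_STEP)
    if (trunk_yx.min() < margin or trunk_yx[:, 0].max() > Y - margin
            or trunk_yx[:, 1].max() > X - margin):
        raise PhantomBoundsError(
            f"trunk of length {params.trunk_length} μm does not fit in a "
            f"{params.stack_extent} μm stack with {margin:.1f} μm margin"
        )

    curves_yx = [trunk_yx]
    cum_t = _arclength(trunk_yx)
    L_t = cum_t[-1]
    for i in range(params.n_branches):
        Lb = rng.uniform(*params.branch_length_range)
        # attach points spread along the trunk, alternating sides
        s_att = (i + 1) / (params.n_branches + 1) * L_t + rng.uniform(-0.06, 0.06) * L_t
        s_att = float(np.clip(s_att, 0.5, L_t - 0.5))
        k = int(np.searchsorted(cum_t, s_att))
        k = min(max(k, 1), len(trunk_yx) - 1)
        p0 = trunk_yx[k]
        tang = trunk_yx[k] - trunk_yx[k - 1]
        tang = tang / (np.linalg.norm(tang) + 1e-12)
        normal = np.array([-tang[1], tang[0]])
        side = 1.0 if i % 2 == 0 else -1.0
        # branches must not run into each other: tubes that touch merge
        # into loops the branch/coverage truth model does not describe
        clearance = 2.0 * params.branch_radius + 0.8
        accepted = np.concatenate(curves_yx)
        tree = cKDTree(accepted)
        ok = False
        for _try in range(60):
            ang = rng.uniform(-0.6, 0.6)
            ca, sa = math.cos(ang), math.sin(ang)
            d = side * (ca * normal) + sa * tang
            d = d / np.linalg.norm(d)
            perp = np.array([-d[1], d[0]])
            p2 = p0 + d * Lb
            p1 = p0 + d * (0.5 * Lb) + perp * rng.uniform(-0.2, 0.2) * Lb
            t = np.linspace(0, 1, 120)[:, None]
            bez = (1 - t) ** 2 * p0 + 2 * t * (1 - t) * p1 + t ** 2 * p2
            bez = _resample_polyline(bez, _CENTERLINE_STEP)
            cum_b = _arclength(bez)
            bez = bez[cum_b <= Lb + _CENTERLINE_STEP / 2]  # trim to target length
            if not (bez.min() >= margin and bez[:, 0].max() <= Y - margin
                    and bez[:, 1].max() <= X - margin):
                continue
            # clearance check, ignoring the legitimate attach neighbourhood
            dist_acc, idx_acc = tree.query(bez)
            near_attach = np.linalg.norm(accepted[idx_acc] - p0, axis=1) < 4.5
            if np.any((dist_acc < clearance) & ~near_attach):
                continue
            curves_yx.append(bez)
            ok = True
            break
        if not ok:
            raise PhantomBoundsError(
                f"could not fit branch of length {Lb:.1f} μm inside the stack "
                "with inter-branch clearance; increase stack_extent or shorten "
                "branch_length_range"
            )

    # lift onto the curved sheet: concave side faces -z (the muscle fiber)
    Z = params.stack_extent[0]
    z_top = Z - 3.2
    branches = []
    for yx in curves_yx:
        r2 = (yx[:, 0] - y0) ** 2 + (yx[:, 1] - x0) ** 2
        z = z_top - r2 / (2.0 * params.sheet_radius)
        pts = np.column_stack([z, yx])
        cum = _arclength(pts)
        branches.append({"points": pts, "cumlen": cum, "length": float(cum[-1])})
    return branches


# ---------------------------------------------------------------------------
# coverage carving


def _reach_margin(params: NMJPhantomParams) -> float:
    """Geodesic distance from a pre-tube end still 'covered' under reach.

    A skeleton point at geodesic distance d past the end of the
    pre-synaptic tube sees its surface at ≈ sqrt(d² + h²) − r_pre where
    h is the centerline offset; it counts as covered while that is
    ≤ reach. Carved gaps are widened by this margin per side so nominal
    gap length equals the reach-measured uncovered run.
    """
    h = params.pre_offset
    rr = params.coverage_reach + params.pre_radius
    if rr <= h:
        return 0.0
    return math.sqrt(rr * rr - h * h)


def _carve_coverage(
    branches: list[dict], params: NMJPhantomParams, rng: np.random.Generator
) -> list[np.ndarray]:
    """Per-branch boolean arrays marking centerline samples covered by
    pre-synaptic signal."""
    lengths = np.array([b["length"] for b in branches])
    offsets = np.concatenate([[0.0], np.cumsum(lengths)])
    L_total = float(lengths.sum())
    delta = _reach_margin(params)

    covered = []
    cf = params.coverage_fraction
    if cf >= 1.0:
        covered = [np.ones(len(b["points"]), dtype=bool) for b in branches]
    elif cf <= 0.0:
        covered = [np.zeros(len(b["points"]), dtype=bool) for b in branches]
    else:
        # place k covered intervals of total length cf * L_total at random
        # non-overlapping global arclength positions
        c_total = cf * L_total
        k = int(rng.integers(1, 4))
        parts = rng.dirichlet(np.ones(k)) * c_total
        free = L_total - c_total
        gaps_between = rng.dirichlet(np.ones(k + 1)) * free
        starts = np.cumsum(gaps_between[:-1]) + np.concatenate([[0.0], np.cumsum(parts[:-1])])
        intervals = [(s, s + p) for s, p in zip(starts, parts)]
        for bi, b in enumerate(branches):
            s_global = offsets[bi] + b["cumlen"]
            cov = np.zeros(len(s_global), dtype=bool)
            for a, e in intervals:
                cov |= (s_global >= a) & (s_global <= e)
            covered.append(cov)

    # explicit gaps, widened by the reach margin on each side; carved on
    # side branches away from the trunk so no crossing tube re-covers them
    prox_margin = 2.5  # clears the trunk's pre-synaptic tube at the attach point
    end_margin = 1.0
    for g in params.uncovered_gap_lengths:
        carve = g + 2 * delta
        side = [i for i in range(1, len(branches))
                if branches[i]["length"] > carve + prox_margin + end_margin]
        trunk_ok = branches[0]["length"] > carve + 2 * prox_margin
        if side:
            bi = int(rng.choice(side))
            lo = prox_margin
        elif trunk_ok:
            bi, lo = 0, prox_margin
        else:
            raise PhantomBoundsError(
                f"no branch long enough to carve a {g} μm uncovered gap "
                f"(needs > {carve + prox_margin + end_margin:.1f} μm)"
            )
        b = branches[bi]
        s0 = rng.uniform(lo, b["length"] - carve - end_margin)
        sel = (b["cumlen"] >= s0) & (b["cumlen"] <= s0 + carve)
        covered[bi] = covered[bi] & ~sel
    return covered


def _true_coverage(
    branches: list[dict], covered: list[np.ndarray], params: NMJPhantomParams,
    reach_pad: float = 0.0,
) -> tuple[list[float], float]:
    """Continuous-geometry oracle: per-branch max uncovered run + devoid fraction.

    A centerline sample is covered iff its distance to the pre-synaptic
    tube surface (offset centerline, radius pre_radius) is within the
    reach radius. Exact point distances via a KD-tree over the densely
    sampled pre centerline. ``reach_pad`` perturbs the reach radius
    (used by the sampler to demand a clearance margin either way).
    """
    pre_pts = np.concatenate(
        [b["points"][cov] for b, cov in zip(branches, covered) if cov.any()]
        or [np.empty((0, 3))]
    )
    if len(pre_pts):
        pre_pts = pre_pts + np.array([params.pre_offset, 0.0, 0.0])
        tree = cKDTree(pre_pts)
    else:
        tree = None

    reach = params.coverage_reach + params.pre_radius + reach_pad
    max_runs: list[float] = []
    unc_len = 0.0
    tot_len = 0.0
    for b in branches:
        pts = b["points"]
        if tree is None:
            unc = np.ones(len(pts), dtype=bool)
        else:
            d, _ = tree.query(pts)
            unc = d > reach
        steps = np.diff(b["cumlen"])
        tot_len += float(steps.sum())
        w = 0.5 * (unc[:-1].astype(float) + unc[1:].astype(float))
        unc_len += float((steps * w).sum())
        max_run = run = 0.0
        in_run = False
        for i in range(len(pts)):
            if unc[i]:
                if in_run:
                    run += float(steps[i - 1])
                in_run = True
                max_run = max(max_run, run)
            else:
                in_run = False
                run = 0.0
        max_runs.append(max_run)
    devoid = unc_len / tot_len if tot_len > 0 else 1.0
    return max_runs, float(min(1.0, max(0.0, devoid)))


# ---------------------------------------------------------------------------
# voxelization


def _voxel_centers_axis(n: int, v: float) -> np.ndarray:
    return (np.arange(n) + 0.5) * v


def _seed_mask(points: np.ndarray, shape: tuple[int, int, int],
               voxel_size: tuple[float, float, float]) -> np.ndarray:
    """Mark the voxel containing each sample point."""
    idx = np.floor(points / np.asarray(voxel_size)).astype(int)
    idx = np.clip(idx, 0, np.asarray(shape) - 1)
    m = np.zeros(shape, dtype=bool)
    m[idx[:, 0], idx[:, 1], idx[:, 2]] = True
    return m


def _tube_mask(points: np.ndarray, radius: float, shape, voxel_size) -> np.ndarray:
    """Tube of given radius around densely sampled centerline points."""
    if len(points) == 0:
        return np.zeros(shape, dtype=bool)
    seeds = _seed_mask(points, shape, voxel_size)
    dist = ndimage.distance_transform_edt(~seeds, sampling=voxel_size)
    return dist <= radius


def _ellipsoid_mask_local(center, radii, shape, voxel_size):
    """Voxelized ellipsoid as (local boolean block, slices into the stack)."""
    vs = np.asarray(voxel_size)
    lo = np.maximum(np.floor((np.asarray(center) - radii) / vs).astype(int) - 1, 0)
    hi = np.minimum(np.ceil((np.asarray(center) + radii) / vs).astype(int) + 2,
                    np.asarray(shape))
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    zz = _voxel_centers_axis(shape[0], vs[0])[sl[0]]
    yy = _voxel_centers_axis(shape[1], vs[1])[sl[1]]
    xx = _voxel_centers_axis(shape[2], vs[2])[sl[2]]
    Zq = ((zz - center[0]) / radii[0]) ** 2
    Yq = ((yy - center[1]) / radii[1]) ** 2
    Xq = ((xx - center[2]) / radii[2]) ** 2
    block = Zq[:, None, None] + Yq[None, :, None] + Xq[None, None, :] <= 1.0
    return block, sl


def voxelized_ellipsoid_volume(radii, voxel_size) -> float:
    """Volume (μm³) of a voxelized ellipsoid with the given semi-axes.

    Used for geometric calibration: at fine isotropic voxels this
    approaches the analytic 4/3·π·abc.
    """
    radii = np.asarray(radii, dtype=float)
    vs = np.asarray(voxel_size, dtype=float)
    shape = tuple((np.ceil((2 * radii + 2) / vs)).astype(int))
    center = (np.asarray(shape) * vs) / 2.0
    block, _ = _ellipsoid_mask_local(center, radii, shape, vs)
    return float(block.sum()) * float(np.prod(vs))


# ---------------------------------------------------------------------------
# nuclei


def _place_nuclei(
    branches: list[dict],
    dil_dist: np.ndarray,
    params: NMJPhantomParams,
    rng: np.random.Generator,
    shape,
) -> tuple[np.ndarray, list[float]]:
    """Place post-synaptic nuclei at target overlap fractions (bisection on
    depth below the endplate sheet) and non-synaptic nuclei clear of it.

    ``dil_dist`` is the distance (μm) to the post-synaptic centerline
    seeds; the apposed region is ``dil_dist <= branch_radius +
    apposition``, the continuum dilation of the tube.
    """
    vs = np.asarray(params.voxel_size)
    radii = np.asarray(params.nucleus_radii)
    extent = np.asarray(params.stack_extent)
    apposition = 1.0  # μm, the analysis default
    dilated = dil_dist <= params.branch_radius + apposition

    if params.nucleus_overlap_targets is not None:
        targets = list(params.nucleus_overlap_targets)
        if len(targets) != params.n_postsynaptic_nuclei:
            raise ValueError("nucleus_overlap_targets length must equal n_postsynaptic_nuclei")
    else:
        targets = list(rng.uniform(0.35, 0.55, params.n_postsynaptic_nuclei))

    labels = np.zeros(shape, dtype=np.int32)
    fractions: list[float] = []
    centers: list[np.ndarray] = []
    min_sep = 2 * float(radii.max()) + 1.0
    bound_lo = radii + 0.6
    bound_hi = extent - radii - 0.6
    all_pts = np.concatenate([b["points"] for b in branches])

    def overlap_fraction(center) -> float:
        block, sl = _ellipsoid_mask_local(center, radii, shape, vs)
        n = int(block.sum())
        if n == 0:
            return 0.0
        return float((block & dilated[sl]).sum()) / n

    def in_bounds(center) -> bool:
        return bool(np.all(center >= bound_lo) and np.all(center <= bound_hi))

    def separated(center) -> bool:
        return all(np.linalg.norm(center - c) >= min_sep for c in centers)

    next_label = 1
    for target in targets:
        # descend from a random centerline point along a randomly tilted
        # downward (concave-side) ray; overlap falls monotonically with
        # depth, so bisection hits the target fraction
        best = None  # (|achieved - target|, center, achieved)
        for _try in range(150):
            p = all_pts[int(rng.integers(len(all_pts)))]
            tilt = rng.uniform(-0.7, 0.7, size=2)
            ray = np.array([-1.0, tilt[0], tilt[1]])
            ray /= np.linalg.norm(ray)
            t_max = (radii[0] + params.branch_radius + apposition + 1.5)
            f0 = overlap_fraction(p)
            if f0 <= target:
                t_star = 0.0
            else:
                lo_t, hi_t = 0.0, t_max
                for _ in range(25):
                    mid = 0.5 * (lo_t + hi_t)
                    if overlap_fraction(p + mid * ray) > target:
                        lo_t = mid
                    else:
                        hi_t = mid
                t_star = 0.5 * (lo_t + hi_t)
            center = p + t_star * ray
            if not in_bounds(center) or not separated(center):
                continue
            block, sl = _ellipsoid_mask_local(center, radii, shape, vs)
            if (labels[sl][block] != 0).any():
                continue
            achieved = overlap_fraction(center)
            err = abs(achieved - target)
            if best is None or err < best[0]:
                best = (err, center, achieved)
            if err <= 0.04:
                break
        if best is None:
            raise PhantomBoundsError(
                "could not place a post-synaptic nucleus at the requested "
                f"overlap {target:.2f}; stack too crowded or too small"
            )
        _, center, achieved = best
        block, sl = _ellipsoid_mask_local(center, radii, shape, vs)
        labels[sl][block] = next_label
        fractions.append(achieved)
        centers.append(center)
        next_label += 1

    clear = params.branch_radius + apposition + float(radii.max()) + 1.0
    for _ in range(params.n_nonsynaptic_nuclei):
        placed = False
        for _try in range(300):
            center = rng.uniform(bound_lo, bound_hi)
            idx = np.minimum(np.floor(center / vs).astype(int), np.asarray(shape) - 1)
            if dil_dist[idx[0], idx[1], idx[2]] < clear:
                continue
            if not separated(center):
                continue
            block, sl = _ellipsoid_mask_local(center, radii, shape, vs)
            if (labels[sl][block] != 0).any():
                continue
            labels[sl][block] = next_label
            fractions.append(overlap_fraction(center))
            centers.append(center)
            next_label += 1
            placed = True
            break
        if not placed:
            raise PhantomBoundsError(
                "could not place a non-synaptic nucleus clear of the endplate; "
                "reduce nucleus counts or enlarge stack_extent"
            )
    return labels, fractions


# ---------------------------------------------------------------------------
# main generator


def generate_nmj_stack(
    params: NMJPhantomParams,
    thresholds: ClassificationThresholds | None = None,
) -> tuple[ConfocalStack, GroundTruth]:
    """Generate one 3-channel (AChR, nerve, DAPI) stack with ground truth.

    Deterministic given ``params`` (including ``params.seed``). Raises
    :class:`PhantomBoundsError` if the requested geometry cannot fit.
    """
    th = thresholds or ClassificationThresholds()
    rng = np.random.default_rng(params.seed)
    vs = params.voxel_size
    shape = tuple(int(round(e / v)) for e, v in zip(params.stack_extent, vs))

    branches = _build_centerlines(params, rng)
    covered = _carve_coverage(branches, params, rng)
    true_runs, true_devoid = _true_coverage(branches, covered, params)
    branch_lengths = [b["length"] for b in branches]

    all_pts = np.concatenate([b["points"] for b in branches])
    seeds = _seed_mask(all_pts, shape, vs)
    dist_post = ndimage.distance_transform_edt(~seeds, sampling=vs)
    post_mask = dist_post <= params.branch_radius

    cov_pts = np.concatenate(
        [b["points"][c] for b, c in zip(branches, covered) if c.any()]
        or [np.empty((0, 3))]
    )
    if len(cov_pts):
        pre_mask = _tube_mask(cov_pts + np.array([params.pre_offset, 0.0, 0.0]),
                              params.pre_radius, shape, vs)
    else:
        pre_mask = np.zeros(shape, dtype=bool)

    nucleus_labels, nuc_fracs = _place_nuclei(branches, dist_post, params, rng, shape)

    # truth labels from the continuous-geometry oracle quantities
    cov_profile = CoverageProfile(
        per_branch_uncovered=list(enumerate(true_runs)),
        devoid_fraction=true_devoid,
        total_skeleton_length_um=float(sum(branch_lengths)),
        reach_radius_um=params.coverage_reach,
    )
    true_pre = classify_presynaptic(cov_profile, th)
    n_elab = sum(1 for L in branch_lengths if L > th.postsyn_branch_min_um)
    true_post = classify_postsynaptic(
        NMJGeometry(volume_um3=0.0, cumulative_intensity=0.0, n_branches_ge_5um=n_elab), th
    )
    true_count = int(sum(1 for f in nuc_fracs if f > th.nucleus_overlap_fraction))

    # render channels: amplitude × mask, PSF blur, then noise
    sig = tuple(s / v for s, v in zip(params.psf_sigma, vs))
    amp = params.amplitude
    chans = []
    for m in (post_mask, pre_mask, nucleus_labels > 0):
        img = ndimage.gaussian_filter(m.astype(np.float32) * amp, sigma=sig)
        chans.append(img)
    true_cumulative = float(chans[0][post_mask].sum())

    noisy = []
    for img in chans:
        out = img
        if params.poisson_noise:
            out = rng.poisson(np.maximum(out, 0)).astype(np.float32)
        if params.noise_sd > 0:
            out = out + rng.normal(0.0, params.noise_sd, size=out.shape).astype(np.float32)
        noisy.append(np.maximum(out, 0.0))

    stack = ConfocalStack(
        voxels=np.stack(noisy).astype(np.float32),
        channel_names=["AChR", "nerve", "DAPI"],
        voxel_size=vs,
        provenance=f"nmjquant phantom seed={params.seed}",
    )
    truth = GroundTruth(
        post_mask=post_mask,
        pre_mask=pre_mask,
        nucleus_labels=nucleus_labels,
        nucleus_overlap_fractions=[float(f) for f in nuc_fracs],
        true_branch_lengths=[float(L) for L in branch_lengths],
        true_uncovered_lengths=[float(r) for r in true_runs],
        true_devoid_fraction=float(true_devoid),
        true_class_pre=true_pre,
        true_class_post=true_post,
        true_myonuclear_count=true_count,
        true_volume=float(post_mask.sum()) * float(np.prod(vs)),
        true_cumulative_intensity=true_cumulative,
    )
    return stack, truth


CLASS_COMBINATIONS = (
    ("innervated", "intact"),
    ("partially_innervated", "intact"),
    ("completely_denervated", "intact"),
    ("innervated", "degenerated"),
    ("completely_denervated", "degenerated"),
)


def _truth_matches(params: NMJPhantomParams, pre: str, post: str) -> bool:
    """Check the intended class combo holds with a safety margin.

    Branches can curve close to each other, so a carved gap may be
    partially re-covered by a neighbouring tube — and the voxel-grid
    measurement can shift coverage boundaries by a fraction of a μm in
    either direction. The check therefore perturbs the reach radius by
    ±0.5 μm in whichever direction would erase the intended label, and
    the sampler redraws until the label survives.
    """
    rng = np.random.default_rng(params.seed)
    branches = _build_centerlines(params, rng)
    covered = _carve_coverage(branches, params, rng)
    lengths = [b["length"] for b in branches]
    if pre == "innervated":
        # must stay innervated even if measurement reaches a bit less far
        runs, devoid = _true_coverage(branches, covered, params, reach_pad=-0.5)
        ok_pre = devoid < 0.05 and (max(runs) if runs else 0.0) < 3.5
    elif pre == "partially_innervated":
        # gap must survive even if measurement reaches a bit further
        runs, devoid = _true_coverage(branches, covered, params, reach_pad=+0.5)
        ok_pre = devoid < 0.80 and (max(runs) if runs else 0.0) > 6.0
    else:
        runs, devoid = _true_coverage(branches, covered, params, reach_pad=+0.5)
        ok_pre = devoid > 0.93
    n_elab = sum(1 for L in lengths if L > 6.0)
    ok_post = (n_elab >= 3) if post == "intact" else all(L < 4.0 for L in lengths)
    return ok_pre and ok_post


def sample_phantom_params(
    rng: np.random.Generator,
    class_combo: tuple[str, str] | None = None,
    noise_sd: float = 0.0,
) -> NMJPhantomParams:
    """Draw random phantom parameters targeting one (pre, post) class combo.

    Parameter ranges keep phantoms well clear of the decision
    thresholds, and each draw is verified against the continuous-
    geometry oracle (and redrawn if branch interference blurred the
    intended class), so the intended label equals the generated ground
    truth. A "partially innervated degenerated" NMJ is geometrically
    impossible (a patch has no branch long enough to carry a >5 μm
    uncovered run), leaving five attainable combinations.
    """
    if class_combo is None:
        class_combo = CLASS_COMBINATIONS[int(rng.integers(len(CLASS_COMBINATIONS)))]
    pre, post = class_combo

    for _attempt in range(80):
        if post == "intact":
            n_branches = int(rng.integers(3, 6))
            branch_length_range = (11.0, 15.0) if pre == "partially_innervated" else (7.0, 13.0)
            trunk_length = float(rng.uniform(13.0, 16.0))
            branch_radius = 1.2
            extent = (14.0, 38.0, 38.0)
            n_post_nuc = int(rng.integers(1, 4))
        else:  # degenerated: a compact patch without elaborate branches
            n_branches = 0
            branch_length_range = (7.0, 13.0)  # unused
            trunk_length = float(rng.uniform(2.5, 3.5))
            branch_radius = 1.8
            extent = (14.0, 24.0, 24.0)
            n_post_nuc = int(rng.integers(0, 2))  # a patch fits one apposed nucleus at most

        if pre == "innervated":
            cf, gaps = 1.0, ()
        elif pre == "partially_innervated":
            cf = 1.0
            gaps = (float(rng.uniform(6.0, 8.0)),)
        else:  # completely denervated
            cf = 0.0 if (post == "degenerated" or rng.random() < 0.7) else float(rng.uniform(0.0, 0.01))
            gaps = ()

        params = NMJPhantomParams(
            n_branches=n_branches,
            branch_length_range=branch_length_range,
            branch_radius=branch_radius,
            trunk_length=trunk_length,
            coverage_fraction=cf,
            uncovered_gap_lengths=gaps,
            n_postsynaptic_nuclei=n_post_nuc,
            n_nonsynaptic_nuclei=int(rng.integers(2, 5)),
            stack_extent=extent,
            noise_sd=noise_sd,
            seed=int(rng.integers(2 ** 31)),
        )
        try:
            if _truth_matches(params, pre, post):
                return params
        except PhantomBoundsError:
            continue
    raise RuntimeError(f"could not draw an unambiguous {class_combo} phantom")


# ---------------------------------------------------------------------------
# 2D fiber-section phantom


@dataclass
class FiberPhantomParams:
    """Parameters for a synthetic transverse muscle section.

    Fibers are a Lloyd-relaxed Voronoi mosaic; the laminin channel is
    bright on inter-fiber boundaries; MyHC IIA / IIB channels are bright
    inside fibers of the corresponding type, and IIX fibers are dark in
    both ("unstained").
    """

    n_fibers: int = 200
    fiber_area_range: tuple[float, float] = (1200.0, 3200.0)  # μm²
    type_proportions: dict = field(
        default_factory=lambda: {"IIA": 0.3, "IIB": 0.5, "IIX": 0.2}
    )
    boundary_width: float = 2.0  # μm
    pixel_size: float = 1.0      # μm
    noise_sd: float = 0.0
    amplitude: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fibers < 0:
            raise ValueError("n_fibers must be non-negative")
        lo, hi = self.fiber_area_range
        if lo <= 0 or lo > hi:
            raise ValueError("fiber_area_range must be positive with min <= max")
        tot = sum(self.type_proportions.values())
        if abs(tot - 1.0) > 1e-9:
            raise ValueError(f"type_proportions must sum to 1, got {tot}")
        if set(self.type_proportions) - {"IIA", "IIB", "IIX"}:
            raise ValueError("type_proportions keys must be IIA/IIB/IIX")
        if self.boundary_width <= 0 or self.pixel_size <= 0:
            raise ValueError("boundary_width and pixel_size must be positive")


@dataclass
class FiberGroundTruth:
    """Per-fiber truth for a synthetic section."""

    label_map: np.ndarray            # fiber interiors, 0 = background/boundary
    fiber_types: list[str]           # per fiber id 1..n
    areas_um2: list[float]           # interior pixel count × pixel_size²
    centroids: list[tuple[float, float]]  # μm (y, x)
    touches_border: list[bool]

    @property
    def n_fibers(self) -> int:
        return len(self.fiber_types)

    def to_json_dict(self) -> dict:
        return {
            "fiber_types": self.fiber_types,
            "areas_um2": self.areas_um2,
            "centroids": self.centroids,
            "touches_border": self.touches_border,
        }


def _exact_type_counts(n: int, proportions: dict) -> list[str]:
    """Largest-remainder apportionment so composition matches exactly."""
    keys = ["IIA", "IIB", "IIX"]
    raw = {k: n * proportions.get(k, 0.0) for k in keys}
    counts = {k: int(math.floor(v)) for k, v in raw.items()}
    rem = n - sum(counts.values())
    order = sorted(keys, key=lambda k: raw[k] - counts[k], reverse=True)
    for k in order[:rem]:
        counts[k] += 1
    out = []
    for k in keys:
        out.extend([k] * counts[k])
    return out


def generate_fiber_section(
    params: FiberPhantomParams,
) -> tuple[SectionImage, FiberGroundTruth]:
    """Generate a 3-channel (IIA, IIB, laminin) section image with truth."""
    rng = np.random.default_rng(params.seed)
    px = params.pixel_size
    if params.n_fibers == 0:
        side = 16
        img = np.zeros((3, side, side), dtype=np.float32)
        section = SectionImage(img, ["IIA", "IIB", "laminin"], px)
        truth = FiberGroundTruth(np.zeros((side, side), np.int32), [], [], [], [])
        return section, truth

    mean_area = 0.5 * (params.fiber_area_range[0] + params.fiber_area_range[1])
    side_um = math.sqrt(params.n_fibers * mean_area)
    W = int(math.ceil(side_um / px))
    min_dist = math.sqrt(params.fiber_area_range[0] / math.pi)  # μm

    # dart-throwing with a minimum seed distance bounds the smallest cell
    seeds = []
    tries = 0
    while len(seeds) < params.n_fibers:
        tries += 1
        if tries > 400 * params.n_fibers:
            raise ValueError(
                "could not place fiber seeds; fiber_area_range too wide for n_fibers"
            )
        cand = rng.uniform(0, side_um, size=2)
        if all(np.hypot(*(cand - s)) >= min_dist for s in seeds):
            seeds.append(cand)
    seeds = np.array(seeds)

    yy, xx = np.meshgrid(
        (np.arange(W) + 0.5) * px, (np.arange(W) + 0.5) * px, indexing="ij"
    )
    pix = np.column_stack([yy.ravel(), xx.ravel()])

    for _ in range(2):  # Lloyd relaxation evens out cell areas
        tree = cKDTree(seeds)
        _, nearest = tree.query(pix)
        lab = nearest.reshape(W, W)
        for i in range(len(seeds)):
            m = lab == i
            if m.any():
                seeds[i] = [yy[m].mean(), xx[m].mean()]

    tree = cKDTree(seeds)
    d, nearest = tree.query(pix, k=2)
    lab = (nearest[:, 0] + 1).reshape(W, W).astype(np.int32)
    boundary = ((d[:, 1] - d[:, 0]) < params.boundary_width).reshape(W, W)
    # image border is not a fiber boundary; fibers there simply touch the edge
    interiors = np.where(boundary, 0, lab)

    types = _exact_type_counts(params.n_fibers, params.type_proportions)
    types = [types[i] for i in rng.permutation(params.n_fibers)]

    amp = params.amplitude
    iia = np.zeros((W, W), dtype=np.float32)
    iib = np.zeros((W, W), dtype=np.float32)
    areas, centroids, touches = [], [], []
    border_ids = set(np.unique(np.concatenate([
        interiors[0], interiors[-1], interiors[:, 0], interiors[:, -1]
    ])))
    for i in range(params.n_fibers):
        m = interiors == i + 1
        area_px = int(m.sum())
        areas.append(area_px * px * px)
        if area_px:
            cy, cx = yy[m].mean(), xx[m].mean()
        else:
            cy, cx = float(seeds[i][0]), float(seeds[i][1])
        centroids.append((float(cy), float(cx)))
        touches.append((i + 1) in border_ids)
        level = amp * rng.uniform(0.8, 1.2)
        if types[i] == "IIA":
            iia[m] = level
        elif types[i] == "IIB":
            iib[m] = level
        # IIX: dark in both channels

    lam = np.where(boundary, amp, 0.0).astype(np.float32)
    chans = []
    for img in (iia, iib, lam):
        out = ndimage.gaussian_filter(img, sigma=1.0)
        if params.noise_sd > 0:
            out = out + rng.normal(0, params.noise_sd, out.shape).astype(np.float32)
        chans.append(np.maximum(out, 0.0))

    section = SectionImage(
        np.stack(chans).astype(np.float32), ["IIA", "IIB", "laminin"], px,
        provenance=f"nmjquant fiber phantom seed={params.seed}",
    )
    truth = FiberGroundTruth(
        label_map=interiors,
        fiber_types=types,
        areas_um2=areas,
        centroids=centroids,
        touches_border=touches,
    )
    return section, truth
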