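"""Independent brute-force oracles used only by the tests.

These deliberately avoid the library's distance-transform machinery:
coverage is decided by an all-pairs Euclidean distance computation
between skeleton voxel centers and pre-synaptic voxel centers.
"""

import numpy as np
from scipy.spatial.distance import cdist


def brute_force_coverage(seg, reach_radius: float):
    """All-pairs oracle for devoid fraction and per-branch uncovered runs.

    Returns (per_branch_max_run, devoid_fraction) using the same
    run/length conventions as the library but with coverage decided by
    an explicit distance matrix.
    """
    vs = np.asarray(seg.voxel_size, dtype=float)
    pre_coords = np.argwhere(seg.pre_mask) * vs

    per_branch = []
    unc_len = 0.0
    tot_len = 0.0
    n_vox = n_cov = 0
    for br in seg.branches:
        pts_phys = br.path * vs
        if len(pre_coords):
            dmin = cdist(pts_phys, pre_coords).min(axis=1)
            uncovered = dmin > reach_radius
        else:
            uncovered = np.ones(len(pts_phys), dtype=bool)
        n_vox += len(pts_phys)
        n_cov += int((~uncovered).sum())
        if len(pts_phys) < 2:
            per_branch.append(0.0)
            continue
        steps = np.sqrt((np.diff(pts_phys, axis=0) ** 2).sum(axis=1))
        tot_len += steps.sum()
        w = 0.5 * (uncovered[:-1].astype(float) + uncovered[1:].astype(float))
        unc_len += float((steps * w).sum())
        max_run = run = 0.0
        in_run = False
        for i in range(len(pts_phys)):
            if uncovered[i]:
                if in_run:
                    run += float(steps[i - 1])
                in_run = True
                max_run = max(max_run, run)
            else:
                in_run = False
                run = 0.0
        per_branch.append(max_run)
    if tot_len > 0:
        devoid = 1.0 - (tot_len - unc_len) / tot_len
    elif n_vox > 0:
        devoid = 1.0 - n_cov / n_vox
    else:
        devoid = 1.0
    return per_branch, float(min(1.0, max(0.0, devoid)))
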