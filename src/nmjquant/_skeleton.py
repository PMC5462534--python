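"""Skeleton branch decomposition with physical (anisotropy-aware) lengths.

A 3D skeleton mask is turned into a graph over skeleton voxels
(26-connectivity), and decomposed into branches: maximal paths whose
interior voxels have degree 2. Junctions and endpoints (degree != 2)
delimit branches; isolated cycles are returned as single closed
branches. Every step length is the Euclidean distance between voxel
centers in micrometres, so z-anisotropy is handled exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Branch", "skeleton_branches"]

# 26-neighbourhood offsets, precomputed once
_OFFSETS = np.array(
    [(dz, dy, dx)
     for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
     if (dz, dy, dx) != (0, 0, 0)],
    dtype=np.int64,
)


@dataclass
class Branch:
    """One skeleton branch: an ordered voxel polyline and its geodesic length."""

    path: np.ndarray  # (n, 3) voxel indices (z, y, x), ordered along the branch
    length_um: float

    @property
    def n_voxels(self) -> int:
        return len(self.path)


def _step_length(a: np.ndarray, b: np.ndarray, voxel_size: np.ndarray) -> float:
    d = (a - b) * voxel_size
    return float(np.sqrt(np.dot(d, d)))


def _path_length(path: np.ndarray, voxel_size: np.ndarray) -> float:
    if len(path) < 2:
        return 0.0
    d = np.diff(path, axis=0) * voxel_size
    return float(np.sqrt((d * d).sum(axis=1)).sum())


def skeleton_branches(
    skeleton: np.ndarray,
    voxel_size: tuple[float, float, float],
    prune_um: float = 2.0,
) -> list[Branch]:
    """Decompose a boolean skeleton mask into branches.

    Leaf twigs shorter than ``prune_um`` that hang off a junction are
    pruned (voxelized skeletons of tubes sprout such twigs at surface
    bumps); pruning turns the junction into a pass-through voxel so the
    two flanking segments merge back into one branch. Isolated short
    paths (both ends free, e.g. the skeleton of a compact patch) are
    never pruned.

    Parameters
    ----------
    skeleton
        Boolean 3D array; True marks skeleton voxels.
    voxel_size
        ``(z, y, x)`` voxel dimensions in μm.
    prune_um
        Twig-length cutoff; 0 disables pruning.

    Returns
    -------
    list of :class:`Branch`. Isolated single voxels become zero-length
    one-voxel branches so downstream coverage accounting still sees them.
    """
    skeleton = np.asarray(skeleton, dtype=bool)
    if prune_um > 0:
        skeleton = skeleton.copy()
        for _ in range(3):
            changed = _prune_twigs_once(skeleton, voxel_size, prune_um)
            changed |= _remove_redundant_junctions(skeleton)
            if not changed:
                break
    return _decompose(skeleton, voxel_size)


def _remove_redundant_junctions(skeleton: np.ndarray) -> bool:
    """Drop junction voxels whose neighbours stay mutually connected
    without them (surface-bump voxels that fragment a through-path)."""
    coords = np.argwhere(skeleton)
    index = {tuple(c) for c in coords}

    def neighbours(c):
        return [tuple(c + off) for off in _OFFSETS if tuple(c + off) in index]

    changed = False
    for c in coords:
        tc = tuple(c)
        if tc not in index:
            continue
        nbs = neighbours(c)
        if len(nbs) < 3:
            continue
        # connectivity of the neighbour set without c
        nb_set = set(nbs)
        stack = [nbs[0]]
        seen = {nbs[0]}
        while stack:
            cur = stack.pop()
            for off in _OFFSETS:
                nxt = (cur[0] + off[0], cur[1] + off[1], cur[2] + off[2])
                if nxt in nb_set and nxt not in seen:
                    seen.add(nxt)
                    stack.append(nxt)
        if len(seen) == len(nb_set):
            skeleton[tc] = False
            index.discard(tc)
            changed = True
    return changed


def _prune_twigs_once(skeleton: np.ndarray, voxel_size, prune_um: float) -> bool:
    """Remove junction-attached leaf twigs shorter than prune_um in place."""
    branches = _decompose(skeleton, voxel_size)
    coords_set = None
    degree_of = {}
    # recompute degrees from the mask (cheap relative to decomposition)
    coords = np.argwhere(skeleton)
    index = {tuple(c): True for c in coords}
    for c in coords:
        deg = 0
        for off in _OFFSETS:
            if (c[0] + off[0], c[1] + off[1], c[2] + off[2]) in index:
                deg += 1
        degree_of[tuple(c)] = deg
    changed = False
    for br in branches:
        if br.length_um >= prune_um or len(br.path) < 2:
            continue
        d0 = degree_of.get(tuple(br.path[0]), 0)
        d1 = degree_of.get(tuple(br.path[-1]), 0)
        if d0 >= 3 and d1 == 1:
            drop = br.path[1:]
        elif d1 >= 3 and d0 == 1:
            drop = br.path[:-1]
        else:
            continue
        skeleton[tuple(drop.T)] = False
        changed = True
    return changed


def _decompose(
    skeleton: np.ndarray, voxel_size: tuple[float, float, float]
) -> list[Branch]:
    vs = np.asarray(voxel_size, dtype=float)
    coords = np.argwhere(skeleton)
    if len(coords) == 0:
        return []

    index = {tuple(c): i for i, c in enumerate(coords)}
    # adjacency lists over voxel indices
    adj: list[list[int]] = [[] for _ in range(len(coords))]
    for i, c in enumerate(coords):
        for off in _OFFSETS:
            j = index.get((c[0] + off[0], c[1] + off[1], c[2] + off[2]))
            if j is not None and j > i:
                adj[i].append(j)
                adj[j].append(i)

    degree = np.array([len(a) for a in adj])
    nodes = np.flatnonzero(degree != 2)

    visited_edges: set[tuple[int, int]] = set()

    def edge_key(a: int, b: int) -> tuple[int, int]:
        return (a, b) if a < b else (b, a)

    branches: list[Branch] = []

    def walk(start: int, first: int) -> list[int]:
        """Walk from a node through degree-2 voxels until the next node."""
        path = [start, first]
        visited_edges.add(edge_key(start, first))
        prev, cur = start, first
        while degree[cur] == 2:
            nxt = adj[cur][0] if adj[cur][0] != prev else adj[cur][1]
            k = edge_key(cur, nxt)
            if k in visited_edges:  # closed loop back onto the start node
                break
            visited_edges.add(k)
            path.append(nxt)
            prev, cur = cur, nxt
        return path

    for n in nodes:
        if degree[n] == 0:
            branches.append(Branch(path=coords[[n]], length_um=0.0))
            continue
        for nb in adj[n]:
            if edge_key(n, nb) in visited_edges:
                continue
            p = walk(n, nb)
            path = coords[p]
            branches.append(Branch(path=path, length_um=_path_length(path, vs)))

    # pure cycles: every voxel degree 2, untouched by the node sweep
    for i in range(len(coords)):
        if degree[i] != 2:
            continue
        if all(edge_key(i, nb) in visited_edges for nb in adj[i]):
            continue
        # trace the cycle
        p = [i]
        prev, cur = i, adj[i][0]
        visited_edges.add(edge_key(i, cur))
        while cur != i:
            p.append(cur)
            nxt = adj[cur][0] if adj[cur][0] != prev else adj[cur][1]
            visited_edges.add(edge_key(cur, nxt))
            prev, cur = cur, nxt
        p.append(i)  # close the loop for length accounting
        path = coords[p]
        branches.append(Branch(path=path, length_um=_path_length(path, vs)))

    return branches
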