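"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's own algorithms: the Sholl oracle
samples points densely along every edge and counts sign changes of the
radial distance; the feature oracle recomputes every morphology feature
by naive recursive traversal of an adjacency map.
"""

from __future__ import annotations

import numpy as np


def dense_sholl_counts(arbor, step: float = 1.0, ds: float = 0.01) -> np.ndarray:
    """Sphere crossings counted from points every ``ds`` um along each edge."""
    rel = arbor.xyz - arbor.soma_xyz
    dist = np.linalg.norm(rel, axis=1)
    n_shells = int(np.floor(dist.max() / step + 1e-9)) + 1
    radii = step * np.arange(1, n_shells + 1)
    counts = np.zeros(n_shells, dtype=int)
    pidx = arbor.parent_index
    for c in range(arbor.n_nodes):
        p = pidx[c]
        if p < 0:
            continue
        a, b = rel[p], rel[c]
        length = np.linalg.norm(b - a)
        if length == 0:
            continue
        n = max(int(np.ceil(length / ds)), 1)
        t = np.linspace(0.0, 1.0, n + 1)
        d = np.linalg.norm(a[None, :] + t[:, None] * (b - a)[None, :], axis=1)
        sgn = np.signbit(d[:, None] - radii[None, :])
        counts += np.sum(np.diff(sgn, axis=0) != 0, axis=0)
    return counts


def naive_features(arbor, step: float = 1.0) -> dict:
    """All 13 features by plain recursive traversal (independent of the
    library's implementation; Sholl-derived fields from the dense oracle)."""
    n = arbor.n_nodes
    pidx = arbor.parent_index
    children: dict[int, list[int]] = {i: [] for i in range(n)}
    for i in range(n):
        if pidx[i] >= 0:
            children[int(pidx[i])].append(i)
    root = arbor.root_index

    def edge_len(i):
        return float(np.linalg.norm(arbor.xyz[i] - arbor.xyz[int(pidx[i])]))

    total_length = sum(edge_len(i) for i in range(n) if pidx[i] >= 0)
    tips = [i for i in range(n) if not children[i] and i != root]
    branch_points = [i for i in range(n)
                     if (i != root and len(children[i]) >= 2)
                     or (i == root and len(children[i]) >= 3)]
    n_branches = len(tips) + sum(1 for b in branch_points if b != root)

    # depth & path distance by recursion
    import sys
    sys.setrecursionlimit(10000)
    bp = set(branch_points)
    depth_best = {"v": 0}
    path_best = {"v": 0.0}

    def walk(i, nbif, dist):
        if i in bp and i != root:
            nbif += 1
        if not children[i]:
            if i != root:
                depth_best["v"] = max(depth_best["v"], nbif)
                path_best["v"] = max(path_best["v"], dist)
            return
        for c in children[i]:
            walk(c, nbif, dist + edge_len(c))

    walk(root, 1 if root in bp else 0, 0.0)

    eu = max(float(np.linalg.norm(arbor.xyz[i] - arbor.xyz[root]))
             for i in range(n))
    counts = dense_sholl_counts(arbor, step=step)
    radii = step * np.arange(1, len(counts) + 1)
    nz = [i for i, c in enumerate(counts) if c > 0]
    ext = arbor.xyz.max(axis=0) - arbor.xyz.min(axis=0)
    return {
        "total_length": total_length,
        "mean_branch_length": total_length / n_branches if n_branches else 0.0,
        "arbor_depth": float(depth_best["v"]),
        "n_branch_points": float(len(branch_points)),
        "n_tips": float(len(tips)),
        "n_branches": float(n_branches),
        "max_euclidean_distance": eu,
        "max_path_distance": path_best["v"],
        "sholl_total": float(counts.sum()),
        "sholl_max": float(counts.max()) if len(counts) else 0.0,
        "sholl_max_radius": float(radii[nz[-1]]) if nz else 0.0,
        "sholl_radius_at_max": float(radii[int(np.argmax(counts))]) if nz else 0.0,
        "bounding_box_volume": float(ext[0] * ext[1] * ext[2]),
    }
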