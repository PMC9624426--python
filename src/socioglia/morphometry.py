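"""Single-neuron and microglial morphometrics on SWC skeletons.

The unit of analysis is a reconstructed arbor: a rooted tree of 3D points
(micrometres) in the standard 7-column SWC format. From it we compute

* classic arbor features (total length, branch statistics, arbor depth —
  the maximum number of bifurcations on any soma-to-tip path),
* a 3D Sholl profile: the number of times the piecewise-linear skeleton
  crosses each concentric sphere centred on the soma, at a fixed radius
  step (1 micrometre by default),
* summary Sholl statistics (total/max intersections, maximum occupied
  radius, radius of peak complexity),
* skeleton statistics for microglia (total process length, endpoint
  count) and a mean-normalised variance for time-series of such values.

Sholl crossings are counted exactly, per edge, by solving |p(t)| = r on
each segment rather than by sampling. Distance along a straight segment
is a convex function of the parameter, so each edge contributes at most
two crossings per sphere; a node that falls exactly on a sphere is
counted once and attributed to its parent-side edge, and a segment
tangent to a sphere counts once.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping

import numpy as np

__all__ = [
    "NeuronArbor",
    "ShollProfile",
    "SWCError",
    "read_swc",
    "write_swc",
    "sholl_profile",
    "sholl_stats",
    "arbor_features",
    "skeleton_stats",
    "timeseries_variability",
    "FEATURE_NAMES",
]

#: Canonical feature order for feature tables and downstream clustering.
FEATURE_NAMES = (
    "total_length",
    "mean_branch_length",
    "arbor_depth",
    "n_branch_points",
    "n_tips",
    "n_branches",
    "max_euclidean_distance",
    "max_path_distance",
    "sholl_total",
    "sholl_max",
    "sholl_max_radius",
    "sholl_radius_at_max",
    "bounding_box_volume",
)


class SWCError(ValueError):
    """Raised for malformed SWC content (dangling parents, cycles, ...)."""


@dataclass
class NeuronArbor:
    """A rooted neuron skeleton in micrometres.

    Parameters
    ----------
    ids : integer node identifiers (arbitrary, unique).
    types : SWC structure types (1 = soma).
    xyz : (n, 3) float coordinates in um.
    radius : per-node radius in um (carried through, never used in metrics).
    parent : parent id per node; -1 marks the root.
    """

    ids: np.ndarray
    types: np.ndarray
    xyz: np.ndarray
    radius: np.ndarray
    parent: np.ndarray

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=np.int64)
        self.types = np.asarray(self.types, dtype=np.int64)
        self.xyz = np.asarray(self.xyz, dtype=np.float64)
        self.radius = np.asarray(self.radius, dtype=np.float64)
        self.parent = np.asarray(self.parent, dtype=np.int64)
        self._validate()

    # -- structure ---------------------------------------------------------
    def _validate(self) -> None:
        n = len(self.ids)
        if n == 0:
            raise SWCError("empty arbor")
        if self.xyz.shape != (n, 3):
            raise SWCError("coordinate array must be (n, 3)")
        if not np.all(np.isfinite(self.xyz)):
            raise SWCError("non-finite coordinates")
        if len(np.unique(self.ids)) != n:
            raise SWCError("duplicate node ids")
        roots = np.flatnonzero(self.parent == -1)
        if len(roots) != 1:
            raise SWCError(f"expected exactly one root, found {len(roots)}")
        self._root_index = int(roots[0])
        id_to_index = {int(i): k for k, i in enumerate(self.ids)}
        pidx = np.empty(n, dtype=np.int64)
        for k in range(n):
            p = int(self.parent[k])
            if p == -1:
                pidx[k] = -1
            elif p not in id_to_index:
                raise SWCError(f"node {int(self.ids[k])} references absent parent {p}")
            else:
                pidx[k] = id_to_index[p]
        self._parent_index = pidx
        # cycle / connectivity check: walk each node to the root
        seen_root = 0
        for k in range(n):
            slow = k
            visited = 0
            while slow != -1:
                slow = int(pidx[slow])
                visited += 1
                if visited > n:
                    raise SWCError("cycle detected in parent pointers")
            seen_root += 1
        if seen_root != n:  # pragma: no cover - unreachable with single root
            raise SWCError("disconnected arbor")

    @property
    def n_nodes(self) -> int:
        return len(self.ids)

    @property
    def root_index(self) -> int:
        return self._root_index

    @property
    def parent_index(self) -> np.ndarray:
        """Parent position (index into arrays) per node, -1 at the root."""
        return self._parent_index

    @property
    def soma_xyz(self) -> np.ndarray:
        return self.xyz[self._root_index]

    def children_index(self) -> list[list[int]]:
        out: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for k, p in enumerate(self._parent_index):
            if p >= 0:
                out[int(p)].append(k)
        return out

    def edge_lengths(self) -> np.ndarray:
        """Length of the edge above each non-root node (0 at the root)."""
        d = np.zeros(self.n_nodes)
        mask = self._parent_index >= 0
        d[mask] = np.linalg.norm(
            self.xyz[mask] - self.xyz[self._parent_index[mask]], axis=1
        )
        return d

    def with_xyz(self, xyz: np.ndarray) -> "NeuronArbor":
        return NeuronArbor(self.ids.copy(), self.types.copy(), np.asarray(xyz, float),
                           self.radius.copy(), self.parent.copy())


@dataclass
class ShollProfile:
    """Sphere-crossing counts at radii step, 2*step, ... centred on the soma."""

    step: float
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.step <= 0:
            raise ValueError("step must be positive")

    @property
    def radii(self) -> np.ndarray:
        return self.step * np.arange(1, len(self.counts) + 1)


# ---------------------------------------------------------------------------
# SWC I/O
# ---------------------------------------------------------------------------

def read_swc(source: str | IO[str]) -> NeuronArbor:
    """Parse 7-column SWC text (path, string, or text stream) into an arbor.

    Lines beginning with '#' and blank lines are ignored. Structural errors
    (missing parent, multiple roots, cycles) raise :class:`SWCError` naming
    the offending line where possible.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        s = str(source)
        if "\n" in s or s.strip().startswith("#"):
            text = s
        else:
            with open(s, "r", encoding="utf-8") as fh:
                text = fh.read()
    ids, types, xyz, radius, parent = [], [], [], [], []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) != 7:
            raise SWCError(f"line {lineno}: expected 7 columns, got {len(fields)}")
        try:
            ids.append(int(fields[0]))
            types.append(int(fields[1]))
            xyz.append([float(fields[2]), float(fields[3]), float(fields[4])])
            radius.append(float(fields[5]))
            parent.append(int(fields[6]))
        except ValueError as exc:
            raise SWCError(f"line {lineno}: {exc}") from exc
    if not ids:
        raise SWCError("no SWC records found")
    try:
        return NeuronArbor(np.array(ids), np.array(types), np.array(xyz),
                           np.array(radius), np.array(parent))
    except SWCError as exc:
        # attach the line of the first offending id when we can find one
        raise SWCError(str(exc)) from exc


def write_swc(arbor: NeuronArbor, dest: str | IO[str] | None = None) -> str:
    """Serialize an arbor as 7-column SWC; returns the text."""
    buf = io.StringIO()
    buf.write("# id type x y z radius parent\n")
    for k in range(arbor.n_nodes):
        x, y, z = (float(c) for c in arbor.xyz[k])
        buf.write(
            f"{int(arbor.ids[k])} {int(arbor.types[k])} "
            f"{x!r} {y!r} {z!r} {float(arbor.radius[k])!r} {int(arbor.parent[k])}\n"
        )
    text = buf.getvalue()
    if dest is None:
        return text
    if hasattr(dest, "write"):
        dest.write(text)
    else:
        with open(dest, "w", encoding="utf-8") as fh:
            fh.write(text)
    return text


# ---------------------------------------------------------------------------
# Sholl analysis
# ---------------------------------------------------------------------------

_EPS = 1e-9


def sholl_profile(arbor: NeuronArbor, step: float = 1.0) -> ShollProfile:
    """Exact sphere-crossing counts of the skeleton around the soma.

    For every concentric sphere of radius ``k * step`` the returned count is
    the number of crossings of the piecewise-linear arbor, computed per edge
    from the convex distance function |p(t)|: a monotone edge crosses each
    sphere whose radius lies strictly between its endpoint distances (the
    parent endpoint is exclusive, the child endpoint inclusive, so a node
    sitting exactly on a sphere is counted once, on its parent side); an
    edge with an interior distance minimum is split there, and exact
    tangency counts as a single crossing.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    center = arbor.soma_xyz
    rel = arbor.xyz - center
    dist = np.linalg.norm(rel, axis=1)
    rmax = float(dist.max())
    n_shells = int(math.floor(rmax / step + _EPS)) + 1
    counts = np.zeros(max(n_shells, 1), dtype=np.int64)

    pidx = arbor.parent_index
    for child in range(arbor.n_nodes):
        p = int(pidx[child])
        if p < 0:
            continue
        a = rel[p]
        b = rel[child]
        v = b - a
        vv = float(v @ v)
        d_p = float(dist[p])
        d_c = float(dist[child])
        if vv == 0.0:
            continue  # zero-length edge: no crossings of its own
        t_star = -float(a @ v) / vv
        if 0.0 < t_star < 1.0:
            # interior minimum: split into a descending and an ascending half
            d_min = float(np.linalg.norm(a + t_star * v))
            _add_range(counts, d_min, d_p, step, exclude_hi=True)   # parent side
            _add_range(counts, d_min, d_c, step, exclude_hi=False)  # child side
            k_min = round(d_min / step)
            if k_min >= 1 and abs(d_min - k_min * step) < _EPS * max(1.0, d_min):
                counts[k_min - 1] += 1  # exact tangency counts once
        else:
            lo, hi = (d_p, d_c) if d_c >= d_p else (d_c, d_p)
            # parent endpoint exclusive, child endpoint inclusive
            if d_c >= d_p:
                _add_range(counts, lo, hi, step, exclude_hi=False)
            else:
                _add_range(counts, lo, hi, step, exclude_hi=True)
                # child exactly on a sphere: include it (attributed here)
                k = round(d_c / step)
                if k >= 1 and abs(d_c - k * step) < _EPS * max(1.0, d_c):
                    counts[k - 1] += 1
    # trim trailing zeros beyond the farthest node but keep at least one shell
    return ShollProfile(step=step, counts=counts)


def _add_range(counts: np.ndarray, lo: float, hi: float, step: float,
               exclude_hi: bool) -> None:
    """Increment shells with lo < k*step <= hi (or < hi when exclude_hi)."""
    if hi <= lo:
        return
    k_lo = math.floor(lo / step + _EPS)  # k*step <= lo
    k_hi = math.floor(hi / step + _EPS)
    if exclude_hi and k_hi >= 1 and abs(hi - k_hi * step) < _EPS * max(1.0, hi):
        k_hi -= 1
    k_start = max(k_lo + 1, 1)
    if k_hi >= k_start:
        if k_hi > len(counts):
            raise AssertionError("shell array too small")  # pragma: no cover
        counts[k_start - 1:k_hi] += 1


def sholl_stats(profile: ShollProfile) -> dict[str, float]:
    """Summary statistics of a Sholl profile.

    ``sholl_max_radius`` is the largest radius with at least one crossing;
    ``sholl_radius_at_max`` is the smallest radius attaining the maximum
    count. Both are 0 for an all-zero profile.
    """
    counts = profile.counts
    if counts.size == 0 or counts.max() == 0:
        return {"sholl_total": 0.0, "sholl_max": 0.0,
                "sholl_max_radius": 0.0, "sholl_radius_at_max": 0.0}
    radii = profile.radii
    nz = np.flatnonzero(counts > 0)
    mx = int(counts.max())
    return {
        "sholl_total": float(counts.sum()),
        "sholl_max": float(mx),
        "sholl_max_radius": float(radii[nz[-1]]),
        "sholl_radius_at_max": float(radii[int(np.argmax(counts))]),
    }


# ---------------------------------------------------------------------------
# Arbor features
# ---------------------------------------------------------------------------

def _topology(arbor: NeuronArbor):
    """Children lists, tips, branch points (root excluded unless degree>=3)."""
    children = arbor.children_index()
    root = arbor.root_index
    tips = [k for k in range(arbor.n_nodes)
            if not children[k] and k != root]
    if arbor.n_nodes == 1:
        tips = []
    branch_points = [k for k in range(arbor.n_nodes)
                     if (len(children[k]) >= 2 and k != root)
                     or (k == root and len(children[k]) >= 3)]
    return children, tips, branch_points


def arbor_features(arbor: NeuronArbor, sholl_step: float = 1.0,
                   profile: ShollProfile | None = None) -> dict[str, float]:
    """The 13-feature morphology vector used for clustering and factoring.

    A *branch* is the path between consecutive topological nodes (root,
    branch points, tips); *arbor depth* is the maximum number of
    bifurcation points on any soma-to-tip path (a root of degree >= 3
    counts as a bifurcation, a root of degree <= 2 does not).
    """
    children, tips, branch_points = _topology(arbor)
    root = arbor.root_index
    elen = arbor.edge_lengths()
    total_length = float(elen.sum())

    bp_set = set(branch_points)
    # path distance from soma and branch-point count along the path
    path_dist = np.zeros(arbor.n_nodes)
    bp_on_path = np.zeros(arbor.n_nodes, dtype=np.int64)
    stack = [root]
    while stack:
        k = stack.pop()
        for c in children[k]:
            path_dist[c] = path_dist[k] + elen[c]
            bp_on_path[c] = bp_on_path[k] + (1 if c in bp_set else 0)
            stack.append(c)
    if root in bp_set:
        bp_on_path += 1

    n_tips = len(tips)
    n_branch_points = len(branch_points)
    # Branches are maximal unbranched paths between topological nodes; every
    # non-root topological node terminates exactly one of them.
    n_branches = n_tips + sum(1 for b in branch_points if b != root)

    arbor_depth = int(bp_on_path[tips].max()) if tips else 0
    mean_branch_length = total_length / n_branches if n_branches else 0.0

    eu = np.linalg.norm(arbor.xyz - arbor.soma_xyz, axis=1)
    max_euclidean = float(eu.max())
    max_path = float(path_dist[tips].max()) if tips else 0.0

    if profile is None:
        profile = sholl_profile(arbor, step=sholl_step)
    ss = sholl_stats(profile)

    extent = arbor.xyz.max(axis=0) - arbor.xyz.min(axis=0)
    bbox = float(np.prod(extent))

    return {
        "total_length": total_length,
        "mean_branch_length": mean_branch_length,
        "arbor_depth": float(arbor_depth),
        "n_branch_points": float(n_branch_points),
        "n_tips": float(n_tips),
        "n_branches": float(n_branches),
        "max_euclidean_distance": max_euclidean,
        "max_path_distance": max_path,
        "sholl_total": ss["sholl_total"],
        "sholl_max": ss["sholl_max"],
        "sholl_max_radius": ss["sholl_max_radius"],
        "sholl_radius_at_max": ss["sholl_radius_at_max"],
        "bounding_box_volume": bbox,
    }


def features_table(arbors: Iterable[NeuronArbor], sholl_step: float = 1.0,
                   neuron_ids: Iterable[str] | None = None,
                   conditions: Iterable[str] | None = None,
                   larva_ids: Iterable[str] | None = None):
    """One row of the 13 features per neuron, as a pandas DataFrame."""
    import pandas as pd

    arbors = list(arbors)
    rows = [arbor_features(a, sholl_step=sholl_step) for a in arbors]
    df = pd.DataFrame(rows, columns=list(FEATURE_NAMES))
    df.insert(0, "neuron_id",
              list(neuron_ids) if neuron_ids is not None
              else [f"neuron_{i:04d}" for i in range(len(arbors))])
    df["condition"] = list(conditions) if conditions is not None else ""
    df["larva_id"] = list(larva_ids) if larva_ids is not None else ""
    return df


def skeleton_stats(skeleton: NeuronArbor) -> dict[str, float]:
    """Total process length and endpoint count of a (microglial) skeleton.

    Endpoints are the non-root degree-1 nodes (process tips); the root is
    additionally counted as an endpoint only when the skeleton is an
    unbranched path, where both ends are morphological process tips.
    """
    children = skeleton.children_index()
    root = skeleton.root_index
    total = float(skeleton.edge_lengths().sum())
    endpoints = 0
    branched = any(len(children[k]) >= 2 for k in range(skeleton.n_nodes))
    for k in range(skeleton.n_nodes):
        degree = len(children[k]) + (0 if k == root else 1)
        if degree == 1:
            if k == root and branched:
                continue
            endpoints += 1
    return {"total_length": total, "n_endpoints": float(endpoints)}


def timeseries_variability(values: Iterable[float], squared_mean: bool = False) -> float:
    """Mean-normalised variance of a time series: sample variance / mean.

    With ``squared_mean=True`` returns var/mean**2 (the squared coefficient
    of variation) instead.
    """
    v = np.asarray(list(values), dtype=float)
    if v.size < 2:
        raise ValueError("need at least two timepoints")
    m = float(v.mean())
    if m == 0:
        raise ValueError("series mean is zero; mean-normalised variance undefined")
    var = float(v.var(ddof=1))
    return var / (m * m) if squared_mean else var / m
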