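"""Branching-process generator for synthetic neuronal arbors.

Arbors grow from a soma at the origin in fixed elongation steps. At
each step a growing tip may bifurcate (rate ``branch_prob_per_um``,
occasionally a trifurcation) or, optionally, terminate stochastically
(rate ``terminate_prob_per_um``, 0 by default); daughters deflect from
the parent direction by a fixed angle at a random azimuth, which keeps
radial distance roughly monotone along paths and the arbor reasonably
self-avoiding. A tip stops growing when it reaches the edge of the
territory the arbor innervates (``territory_radius_um`` from the soma,
emulating a bounded connective zone), and growth stops globally when the
total cable length reaches ``max_total_um``. The process is a pure
function of its parameters including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..morphometry import NeuronArbor

__all__ = ["ArborParams", "gen_arbors"]


@dataclass(frozen=True)
class ArborParams:
    branch_prob_per_um: float = 0.05
    step_um: float = 1.7
    terminate_prob_per_um: float = 0.0
    max_depth: int = 12
    max_total_um: float = 400.0
    territory_radius_um: float = 45.0
    max_path_um: float = 120.0
    trunk_cone_deg: float = 60.0
    deflection_deg: float = 40.0
    wobble_deg: float = 15.0
    trifurcation_prob: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("step_um", "max_total_um", "territory_radius_um",
                     "max_path_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("branch_prob_per_um", "terminate_prob_per_um"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.branch_prob_per_um * self.step_um > 1:
            raise ValueError("branch probability per step exceeds 1")
        if self.terminate_prob_per_um * self.step_um > 1:
            raise ValueError("termination probability per step exceeds 1")
        if self.max_depth < 0:
            raise ValueError("max_depth must be non-negative")
        if not 0.0 <= self.trifurcation_prob <= 1.0:
            raise ValueError("trifurcation_prob must be in [0, 1]")


def _unit_sphere(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _deflect(direction: np.ndarray, angle_deg: float,
             rng: np.random.Generator) -> np.ndarray:
    """Unit vector at a fixed angle from ``direction``, random azimuth."""
    a = np.radians(angle_deg)
    # orthonormal frame around the direction
    ref = np.array([1.0, 0.0, 0.0])
    if abs(direction @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(direction, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(direction, e1)
    phi = rng.uniform(0, 2 * np.pi)
    out = (np.cos(a) * direction
           + np.sin(a) * (np.cos(phi) * e1 + np.sin(phi) * e2))
    return out / np.linalg.norm(out)


def _grow_one(params: ArborParams, rng: np.random.Generator) -> NeuronArbor:
    step = params.step_um
    p_branch = params.branch_prob_per_um * step
    p_term = params.terminate_prob_per_um * step

    xyz = [np.zeros(3)]
    parent = [-1]
    types = [1]  # soma
    # active tips: (node_index, direction, bifurcation depth, path length)
    if params.trunk_cone_deg >= 180.0:
        trunk_dir = _unit_sphere(rng)
    else:
        # preferred projection axis (+x) with a random tilt inside the cone
        tilt = params.trunk_cone_deg * np.sqrt(rng.uniform())
        trunk_dir = _deflect(np.array([1.0, 0.0, 0.0]), tilt, rng)
    tips = [(0, trunk_dir, 0, 0.0)]
    total = 0.0
    while tips and total + step <= params.max_total_um + 1e-12:
        node, direction, depth, path = tips.pop(0)
        new_xyz = xyz[node] + step * direction
        xyz.append(new_xyz)
        parent.append(node)
        types.append(3)  # dendrite
        new_idx = len(xyz) - 1
        total += step
        path += step
        if np.linalg.norm(new_xyz) >= params.territory_radius_um:
            continue  # tip reached the territory boundary
        if path >= params.max_path_um:
            continue  # neurite reached its maximum extension
        u = rng.uniform()
        if u < p_term:
            continue
        if u < p_term + p_branch and depth < params.max_depth:
            # mostly bifurcations, occasionally a trifurcation, as in real
            # reconstructions (and so tip/branch-point counts are not
            # perfectly collinear across a sample)
            n_daughters = 3 if rng.uniform() < params.trifurcation_prob else 2
            for _ in range(n_daughters):
                d = _deflect(direction, params.deflection_deg, rng)
                tips.append((new_idx, d, depth + 1, path))
        else:
            # slight tortuosity so successive nodes do not line up exactly
            cont = (_deflect(direction, params.wobble_deg, rng)
                    if params.wobble_deg > 0 else direction)
            tips.append((new_idx, cont, depth, path))
    n = len(xyz)
    return NeuronArbor(
        ids=np.arange(1, n + 1),
        types=np.array(types),
        xyz=np.vstack(xyz),
        radius=np.full(n, 0.5),
        parent=np.array([-1] + [p + 1 for p in parent[1:]]),
    )


def gen_arbors(params: ArborParams, n: int) -> list[NeuronArbor]:
    """Generate ``n`` independent arbors; sub-streams derive from the seed."""
    if n < 0:
        raise ValueError("n must be non-negative")
    root = np.random.default_rng(params.seed)
    seeds = root.integers(0, 2**31 - 1, size=n)
    return [_grow_one(params, np.random.default_rng(int(s))) for s in seeds]
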