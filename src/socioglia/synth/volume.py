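"""Generator for synthetic forebrain volumes with microglia centroids.

The forebrain is an ellipsoid on the voxel grid; the neuropil sub-mask
is grown outward from an interior focus until it holds exactly the
requested fraction of forebrain voxels (so the measured fraction is
within rounding of the target by construction). Microglia centroids are
sampled from forebrain voxels with a dorsoventral weighting
``exp(dorsal_bias * z_norm)``; ``dorsal_bias = 0`` gives a uniform
z-distribution, positive values shift cells dorsally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..volumetrics import VolumeLabels

__all__ = ["VolumeParams", "gen_volume"]


@dataclass(frozen=True)
class VolumeParams:
    grid_shape: tuple[int, int, int] = (48, 64, 32)
    voxel_um: tuple[float, float, float] = (2.0, 2.0, 2.0)
    neuropil_fraction: float = 0.10
    n_microglia: int = 100
    dorsal_bias: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s < 4 for s in self.grid_shape):
            raise ValueError("grid_shape axes must be >= 4")
        if any(v <= 0 for v in self.voxel_um):
            raise ValueError("voxel_um must be positive")
        if not 0.0 < self.neuropil_fraction < 1.0:
            raise ValueError("neuropil_fraction must be in (0, 1)")
        if self.n_microglia < 0:
            raise ValueError("n_microglia must be non-negative")


def gen_volume(params: VolumeParams) -> VolumeLabels:
    """Build one labeled volume; deterministic in ``params.seed``."""
    rng = np.random.default_rng(params.seed)
    nx, ny, nz = params.grid_shape
    ix, iy, iz = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                             indexing="ij")
    cx, cy, cz = (nx - 1) / 2.0, (ny - 1) / 2.0, (nz - 1) / 2.0
    rx, ry, rz = 0.45 * nx, 0.45 * ny, 0.45 * nz
    ell = (((ix - cx) / rx) ** 2 + ((iy - cy) / ry) ** 2
           + ((iz - cz) / rz) ** 2)
    forebrain = ell <= 1.0

    # neuropil: the closest round(frac * N) forebrain voxels to a focus
    fb_idx = np.argwhere(forebrain)
    n_fb = len(fb_idx)
    n_np = int(round(params.neuropil_fraction * n_fb))
    focus = np.array([cx, cy + 0.2 * ny, cz])
    d2 = np.sum(((fb_idx - focus) / np.array([1.0, 1.0, 0.7])) ** 2, axis=1)
    order = np.argsort(d2, kind="stable")
    neuropil = np.zeros_like(forebrain)
    sel = fb_idx[order[:n_np]]
    neuropil[sel[:, 0], sel[:, 1], sel[:, 2]] = True

    # microglia centroids: weighted draw of forebrain voxels, dorsal bias in z
    z_norm = fb_idx[:, 2] / max(nz - 1, 1)
    w = np.exp(params.dorsal_bias * z_norm)
    w = w / w.sum()
    if params.n_microglia > 0:
        chosen = rng.choice(n_fb, size=params.n_microglia, replace=True, p=w)
        vox = np.asarray(params.voxel_um)
        jitter = rng.uniform(-0.4, 0.4, size=(params.n_microglia, 3))
        centroids = (fb_idx[chosen] + jitter) * vox
    else:
        centroids = np.zeros((0, 3))

    return VolumeLabels(forebrain_mask=forebrain, neuropil_mask=neuropil,
                        microglia_centroids=centroids,
                        voxel_um=params.voxel_um)
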