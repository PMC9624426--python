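"""Forebrain volumetrics and affine registration of point sets / arbors.

Whole-population measurements on a segmented forebrain: the neuropil
volume fraction (labeled neurite voxels / forebrain voxels), microglial
abundance normalized to forebrain volume (reported per 10^6 um^3), the
neuropil centre of mass and the mean microglial z position, each
normalized per axis to the forebrain bounding extent (0 = ventral floor,
1 = dorsal roof for z).

Registration is correspondence-based: a 12-parameter affine (rotation,
scaling, shearing, translation) is fitted to matched point pairs by
least squares and applied to SWC arbors so neurons reconstructed in
different brains can be placed in a shared reference forebrain. Voxel
convention: world coordinate = index * voxel_um (voxel centres, 0-based).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation
from sklearn.base import BaseEstimator

from .morphometry import NeuronArbor

__all__ = [
    "VolumeLabels",
    "AffineTransform",
    "AffineRegression",
    "density_metrics",
    "fit_affine",
    "apply_affine",
    "decompose_affine",
    "compose_affine",
]


@dataclass
class VolumeLabels:
    """Voxel masks (forebrain, neuropil) plus microglia centroids in um."""

    forebrain_mask: np.ndarray
    neuropil_mask: np.ndarray
    microglia_centroids: np.ndarray
    voxel_um: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.forebrain_mask = np.asarray(self.forebrain_mask, bool)
        self.neuropil_mask = np.asarray(self.neuropil_mask, bool)
        self.microglia_centroids = np.atleast_2d(
            np.asarray(self.microglia_centroids, float).reshape(-1, 3))
        if self.forebrain_mask.shape != self.neuropil_mask.shape:
            raise ValueError("mask shapes differ")
        if np.any(self.neuropil_mask & ~self.forebrain_mask):
            raise ValueError("neuropil mask extends outside the forebrain")
        if any(v <= 0 for v in self.voxel_um):
            raise ValueError("voxel_um must be positive")

    @property
    def voxel_volume_um3(self) -> float:
        return float(np.prod(self.voxel_um))


def density_metrics(v: VolumeLabels) -> dict[str, float]:
    """Forebrain-normalized density and position metrics.

    ``microglia_per_volume`` is the centroid count per 10^6 um^3 of
    forebrain; positional metrics are normalized per axis to the
    forebrain mask's bounding extent in world coordinates.
    """
    fb = int(v.forebrain_mask.sum())
    if fb == 0:
        raise ValueError("empty forebrain mask")
    np_vox = int(v.neuropil_mask.sum())
    density = np_vox / fb
    per_vol = len(v.microglia_centroids) / (fb * v.voxel_volume_um3) * 1e6

    vox = np.asarray(v.voxel_um)
    idx = np.argwhere(v.forebrain_mask).astype(float)
    lo = idx.min(axis=0) * vox
    hi = idx.max(axis=0) * vox
    extent = np.where(hi > lo, hi - lo, 1.0)

    np_idx = np.argwhere(v.neuropil_mask).astype(float)
    if len(np_idx):
        com = np_idx.mean(axis=0) * vox
        com_norm = (com - lo) / extent
    else:
        com_norm = np.full(3, np.nan)

    if len(v.microglia_centroids) and np.isfinite(v.microglia_centroids).all():
        mean_z = float(np.mean((v.microglia_centroids[:, 2] - lo[2]) / extent[2]))
    else:
        mean_z = float("nan")

    return {
        "neuropil_density": float(density),
        "microglia_per_volume": float(per_vol),
        "neuropil_com_norm_x": float(com_norm[0]),
        "neuropil_com_norm_y": float(com_norm[1]),
        "neuropil_com_norm_z": float(com_norm[2]),
        "microglia_mean_z_norm": mean_z,
    }


# ---------------------------------------------------------------------------
# Affine transforms
# ---------------------------------------------------------------------------

@dataclass
class AffineTransform:
    """x -> A @ x + t with a non-singular 3x3 linear part."""

    matrix: np.ndarray
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, float).reshape(3, 3)
        self.translation = np.asarray(self.translation, float).reshape(3)
        if abs(np.linalg.det(self.matrix)) < 1e-12:
            raise ValueError("linear part is singular")

    def __call__(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, float))
        return pts @ self.matrix.T + self.translation

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(3), np.zeros(3))


class AffineRegression(BaseEstimator):
    """Least-squares 12-parameter affine fit from point correspondences.

    scikit-learn style: ``fit(src, dst)`` estimates the transform,
    ``transform(points)`` applies it. Fitted attributes: ``transform_``
    (an :class:`AffineTransform`) and ``residual_rms_``.
    """

    def fit(self, X: np.ndarray, y: np.ndarray) -> "AffineRegression":
        src = np.asarray(X, float)
        dst = np.asarray(y, float)
        if src.shape != dst.shape or src.ndim != 2 or src.shape[1] != 3:
            raise ValueError("src and dst must both be (n, 3)")
        n = len(src)
        if n < 4:
            raise ValueError("need at least 4 correspondences")
        centered = src - src.mean(axis=0)
        if np.linalg.matrix_rank(centered, tol=1e-9) < 3:
            raise ValueError("source points are coplanar or degenerate")
        design = np.hstack([src, np.ones((n, 1))])
        sol, *_ = np.linalg.lstsq(design, dst, rcond=None)
        A = sol[:3].T
        t = sol[3]
        self.transform_ = AffineTransform(A, t)
        resid = self.transform_(src) - dst
        self.residual_rms_ = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
        return self

    def transform(self, points: np.ndarray) -> np.ndarray:
        return self.transform_(points)


def fit_affine(src: np.ndarray, dst: np.ndarray) -> AffineTransform:
    """Fit x -> A x + t minimizing sum |T(src) - dst|^2 (>=4 non-coplanar pts)."""
    return AffineRegression().fit(src, dst).transform_


def apply_affine(obj, T: AffineTransform):
    """Apply an affine to a point array or a :class:`NeuronArbor`.

    Topology, ids and radii of an arbor are untouched; only coordinates map.
    """
    if isinstance(obj, NeuronArbor):
        return obj.with_xyz(T(obj.xyz))
    return T(np.asarray(obj, float))


def decompose_affine(T: AffineTransform, center: np.ndarray | None = None) -> dict:
    """Split an affine into rotation / scales / shears / translation.

    Fixed order about ``center`` (default origin):
    ``x -> R @ Sh @ Sc @ (x - c) + c + t`` where ``Sc`` is diagonal
    (positive scales), ``Sh`` unit upper-triangular (shears), ``R`` a
    rotation. A negative-determinant linear part is flagged as a
    reflection (``reflection: True``) by negating the z scale.
    """
    c = np.zeros(3) if center is None else np.asarray(center, float).reshape(3)
    A = T.matrix
    reflection = bool(np.linalg.det(A) < 0)
    Q, U = np.linalg.qr(A)
    # enforce positive diagonal on U
    signs = np.sign(np.diag(U))
    signs[signs == 0] = 1.0
    Q = Q * signs
    U = signs[:, None] * U
    if reflection:
        # Q has det -1; flip its last column into a negative z scale
        Q = Q.copy()
        Q[:, 2] *= -1
        U = U.copy()
        U[2, :] *= -1
    scales = np.diag(U).copy()
    shear = U / scales[None, :]  # unit upper-triangular (column-scaled)
    angles = Rotation.from_matrix(Q).as_euler("xyz", degrees=True)
    # translation component relative to the stated center
    t = T.translation + A @ c - c
    return {
        "rotation_deg": angles,
        "scales": scales,
        "shears": np.array([shear[0, 1], shear[0, 2], shear[1, 2]]),
        "translation": t,
        "center": c,
        "reflection": reflection,
    }


def compose_affine(parts: dict) -> AffineTransform:
    """Inverse of :func:`decompose_affine` (round-trips within 1e-9)."""
    c = np.asarray(parts["center"], float)
    R = Rotation.from_euler("xyz", parts["rotation_deg"], degrees=True).as_matrix()
    scales = np.asarray(parts["scales"], float)
    sxy, sxz, syz = parts["shears"]
    Sh = np.array([[1.0, sxy, sxz], [0.0, 1.0, syz], [0.0, 0.0, 1.0]])
    A = R @ Sh @ np.diag(scales)
    t = np.asarray(parts["translation"], float) - A @ c + c
    return AffineTransform(A, t)
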