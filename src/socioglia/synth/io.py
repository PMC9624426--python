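"""Writers and readers for the generated artifacts.

Formats: trajectories as CSV, arbors as 7-column SWC, volumes as TIFF
stacks plus a centroid CSV, expression as MatrixMarket + TSV metadata.
Each writer has a matching reader and round-trips without loss of the
quantities the analyses consume.
"""

from __future__ import annotations

import os

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import tifffile

from ..morphometry import NeuronArbor, read_swc, write_swc
from ..volumetrics import VolumeLabels

__all__ = [
    "write_arbors_swc",
    "read_arbors_swc",
    "write_volume",
    "read_volume",
    "write_expression_mtx",
    "read_expression_mtx",
]


def write_arbors_swc(arbors, out_dir: str, prefix: str = "arbor") -> list[str]:
    os.makedirs(out_dir, exist_ok=True)
    paths = []
    for i, arbor in enumerate(arbors):
        path = os.path.join(out_dir, f"{prefix}_{i:04d}.swc")
        write_swc(arbor, path)
        paths.append(path)
    return paths


def read_arbors_swc(paths) -> list[NeuronArbor]:
    return [read_swc(p) for p in paths]


def write_volume(v: VolumeLabels, out_dir: str, prefix: str = "volume") -> dict:
    """Masks as uint8 TIFF stacks (z-major pages), centroids as CSV."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "forebrain": os.path.join(out_dir, f"{prefix}_forebrain.tif"),
        "neuropil": os.path.join(out_dir, f"{prefix}_neuropil.tif"),
        "centroids": os.path.join(out_dir, f"{prefix}_centroids.csv"),
        "meta": os.path.join(out_dir, f"{prefix}_voxel_um.csv"),
    }
    tifffile.imwrite(paths["forebrain"],
                     v.forebrain_mask.transpose(2, 1, 0).astype(np.uint8))
    tifffile.imwrite(paths["neuropil"],
                     v.neuropil_mask.transpose(2, 1, 0).astype(np.uint8))
    pd.DataFrame(v.microglia_centroids,
                 columns=["x_um", "y_um", "z_um"]).to_csv(paths["centroids"],
                                                          index=False)
    pd.DataFrame([{"vx": v.voxel_um[0], "vy": v.voxel_um[1],
                   "vz": v.voxel_um[2]}]).to_csv(paths["meta"], index=False)
    return paths


def read_volume(paths: dict) -> VolumeLabels:
    fb = tifffile.imread(paths["forebrain"]).transpose(2, 1, 0).astype(bool)
    npl = tifffile.imread(paths["neuropil"]).transpose(2, 1, 0).astype(bool)
    cent = pd.read_csv(paths["centroids"])[["x_um", "y_um", "z_um"]].to_numpy(float)
    meta = pd.read_csv(paths["meta"]).iloc[0]
    return VolumeLabels(fb, npl, cent, voxel_um=(meta.vx, meta.vy, meta.vz))


def write_expression_mtx(adata: ad.AnnData, out_dir: str) -> dict:
    """counts.mtx (cells x genes) + genes.tsv + cells.tsv."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "mtx": os.path.join(out_dir, "counts.mtx"),
        "genes": os.path.join(out_dir, "genes.tsv"),
        "cells": os.path.join(out_dir, "cells.tsv"),
    }
    counts = adata.layers.get("counts", adata.X)
    scipy.io.mmwrite(paths["mtx"], sp.csr_matrix(counts))
    pd.DataFrame({"gene": adata.var_names}).to_csv(paths["genes"], sep="\t",
                                                   index=False)
    cells = adata.obs.reset_index()
    cells.to_csv(paths["cells"], sep="\t", index=False)
    return paths


def read_expression_mtx(paths: dict) -> ad.AnnData:
    counts = scipy.io.mmread(paths["mtx"]).toarray().astype(np.int64)
    genes = pd.read_csv(paths["genes"], sep="\t")["gene"].astype(str)
    cells = pd.read_csv(paths["cells"], sep="\t")
    obs = cells.set_index(cells.columns[0])
    adata = ad.AnnData(X=counts.astype(np.float64), obs=obs,
                       var=pd.DataFrame(index=pd.Index(genes, name="gene")))
    adata.layers["counts"] = counts
    return adata
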