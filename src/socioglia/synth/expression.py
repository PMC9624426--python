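"""Generator for immune-cell count matrices with a planted microglial
fingerprint and condition-dependent complement-gene shifts.

Cells come in four default types — ramified, amoeboid and proliferative
microglia plus macrophages — split evenly between CVZ (conventionalized)
and GF (germ-free) conditions. Counts are negative-binomial
(mean/dispersion parameterization; zeros arise naturally). All 75
fingerprint genes are expressed highly in the microglial types and at
background level in macrophages, so combinatorial fingerprint expression
is unique to microglia. ``condition_lfc`` maps gene -> cell type ->
log2(CVZ/GF) fold change, applied symmetrically about the base mean; the
default plants the complement genes c1qa/c1qb lower in GF ramified
microglia and higher in GF amoeboid microglia.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import anndata as ad
import numpy as np
import pandas as pd

__all__ = ["ExprParams", "gen_expression", "default_fingerprint_genes"]

_NAMED_FP = ["c1qa", "c1qb", "apoeb", "hexb", "mafb", "plxnb2a", "sall1a",
             "slc7a7"]


def default_fingerprint_genes() -> list[str]:
    """Stand-in 75-gene microglial fingerprint (8 named + 67 placeholders)."""
    return _NAMED_FP + [f"fp{i:03d}" for i in range(1, 68)]


def _default_counts() -> dict[str, int]:
    return {
        "ramified_microglia": 40,
        "amoeboid_microglia": 40,
        "proliferative_microglia": 40,
        "macrophage": 40,
    }


def _default_lfc() -> dict[str, dict[str, float]]:
    return {
        "c1qa": {"ramified_microglia": 1.0, "amoeboid_microglia": -1.0},
        "c1qb": {"ramified_microglia": 1.0, "amoeboid_microglia": -1.0},
    }


MICROGLIAL_TYPES = ("ramified_microglia", "amoeboid_microglia",
                    "proliferative_microglia")


@dataclass
class ExprParams:
    n_cells_per_type: dict[str, int] = field(default_factory=_default_counts)
    n_genes: int = 500
    fingerprint_high_mean: float = 20.0
    background_mean: float = 0.1
    marker_mean: float = 10.0
    n_markers_per_type: int = 25
    condition_lfc: dict[str, dict[str, float]] = field(default_factory=_default_lfc)
    dispersion: float = 2.0
    fingerprint_genes: list[str] = field(default_factory=default_fingerprint_genes)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.fingerprint_genes) != len(set(self.fingerprint_genes)):
            raise ValueError("duplicate fingerprint gene names")
        n_types = len(self.n_cells_per_type)
        needed = len(self.fingerprint_genes) + n_types * self.n_markers_per_type
        if self.n_genes < needed:
            raise ValueError(
                f"n_genes={self.n_genes} cannot hold {len(self.fingerprint_genes)} "
                f"fingerprint genes plus {n_types}x{self.n_markers_per_type} markers")
        if any(n < 0 for n in self.n_cells_per_type.values()):
            raise ValueError("cell counts must be non-negative")
        for v in (self.fingerprint_high_mean, self.background_mean,
                  self.marker_mean, self.dispersion):
            if v <= 0:
                raise ValueError("means and dispersion must be positive")


def gen_expression(params: ExprParams) -> ad.AnnData:
    """Sample one count matrix; deterministic in ``params.seed``.

    Returns an AnnData with integer counts in ``.X``, per-cell
    ``condition`` (CVZ/GF) and ``true_type`` in ``.obs``, and the
    fingerprint gene list in ``.uns['fingerprint_genes']``.
    """
    rng = np.random.default_rng(params.seed)
    types = list(params.n_cells_per_type)
    fp = list(params.fingerprint_genes)
    markers = {t: [f"{t[:3]}_mk{i:03d}" for i in range(1, params.n_markers_per_type + 1)]
               for t in types}
    marker_names = [g for t in types for g in markers[t]]
    n_null = params.n_genes - len(fp) - len(marker_names)
    genes = fp + marker_names + [f"null{i:04d}" for i in range(1, n_null + 1)]

    cells, conditions, cell_types = [], [], []
    for t in types:
        n = params.n_cells_per_type[t]
        for i in range(n):
            cells.append(f"{t[:3]}_{i:04d}")
            conditions.append("CVZ" if i % 2 == 0 else "GF")
            cell_types.append(t)

    gene_index = {g: j for j, g in enumerate(genes)}
    n_cells = len(cells)
    mean = np.full((n_cells, params.n_genes), params.background_mean)
    type_arr = np.array(cell_types)
    cond_arr = np.array(conditions)
    for t in types:
        rows = type_arr == t
        if t in MICROGLIAL_TYPES:
            for g in fp:
                mean[rows, gene_index[g]] = params.fingerprint_high_mean
        for g in markers[t]:
            mean[rows, gene_index[g]] = params.marker_mean
    # condition shifts, symmetric about the base mean: CVZ * 2^(+lfc/2),
    # GF * 2^(-lfc/2), so log2(CVZ/GF) equals the planted value
    for g, per_type in params.condition_lfc.items():
        if g not in gene_index:
            raise ValueError(f"condition_lfc gene {g!r} not in gene list")
        j = gene_index[g]
        for t, lfc in per_type.items():
            rows_cv = (type_arr == t) & (cond_arr == "CVZ")
            rows_gf = (type_arr == t) & (cond_arr == "GF")
            mean[rows_cv, j] *= 2.0 ** (lfc / 2.0)
            mean[rows_gf, j] *= 2.0 ** (-lfc / 2.0)

    lam = rng.gamma(shape=params.dispersion, scale=mean / params.dispersion)
    counts = rng.poisson(lam).astype(np.int64)

    obs = pd.DataFrame({"condition": conditions, "true_type": cell_types},
                       index=pd.Index(cells, name="cell_id"))
    var = pd.DataFrame(index=pd.Index(genes, name="gene"))
    adata = ad.AnnData(X=counts.astype(np.float64), obs=obs, var=var)
    adata.layers["counts"] = counts
    adata.uns["fingerprint_genes"] = fp
    return adata
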