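"""Core in-memory containers shared across pipeline stages.

The pipeline moves a small set of typed objects between stages: a sparse
gene x cell UMI matrix with metadata (:class:`CellCounts`), per-cluster
pseudobulk matrices with a normalization stage tag (:class:`PseudobulkSet`),
founder-haplotype dosages (:class:`FounderGenotypes`), trajectory/pseudotime
results (:class:`TrajectorySet`) and learned gene networks (:class:`GeneDAG`).
All tabular payloads are plain pandas objects so stages compose with the
usual scientific-Python stack.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

#: Normalization stages in their mandatory order.
PSEUDOBULK_STAGES = ("raw_mean", "cpm", "vst", "quantile")

REQUIRED_GENE_COLS = ("symbol", "chrom", "tss_pos", "mito", "rpl", "rps")
REQUIRED_CELL_COLS = ("sample_id", "cluster_label")


class SchemaError(ValueError):
    """Raised when an input object is missing required columns or flags."""


class StageError(ValueError):
    """Raised when a normalization step is applied out of order."""


@dataclass
class CellCounts:
    """Sparse gene x cell UMI count matrix with gene and cell metadata.

    Parameters
    ----------
    matrix
        ``(n_genes, n_cells)`` sparse matrix of non-negative integer counts.
    gene_meta
        One row per gene: ``symbol``, ``chrom``, ``tss_pos`` (1-based) and
        boolean flags ``mito``/``rpl``/``rps``.
    cell_meta
        One row per cell: ``sample_id``, ``cluster_label`` and optionally
        ``batch``.
    """

    matrix: sp.spmatrix
    gene_meta: pd.DataFrame
    cell_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.matrix = sp.csr_matrix(self.matrix)
        if self.matrix.shape != (len(self.gene_meta), len(self.cell_meta)):
            raise SchemaError(
                f"matrix shape {self.matrix.shape} does not match "
                f"{len(self.gene_meta)} genes x {len(self.cell_meta)} cells"
            )
        missing = [c for c in REQUIRED_GENE_COLS if c not in self.gene_meta.columns]
        if missing:
            raise SchemaError(f"gene_meta missing columns: {missing}")
        missing = [c for c in REQUIRED_CELL_COLS if c not in self.cell_meta.columns]
        if missing:
            raise SchemaError(f"cell_meta missing columns: {missing}")
        if self.gene_meta["symbol"].duplicated().any():
            dup = self.gene_meta["symbol"][self.gene_meta["symbol"].duplicated()]
            raise SchemaError(f"duplicate gene symbols: {sorted(set(dup))[:5]}")

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[1]

    @property
    def symbols(self) -> pd.Index:
        return pd.Index(self.gene_meta["symbol"])

    def subset_cells(self, mask: np.ndarray) -> "CellCounts":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return CellCounts(
            self.matrix[:, idx],
            self.gene_meta.reset_index(drop=True),
            self.cell_meta.iloc[idx].reset_index(drop=True),
        )

    def subset_genes(self, mask: np.ndarray) -> "CellCounts":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return CellCounts(
            self.matrix[idx, :],
            self.gene_meta.iloc[idx].reset_index(drop=True),
            self.cell_meta.reset_index(drop=True),
        )


@dataclass
class PseudobulkSet:
    """Per-cluster gene x sample pseudobulk matrices with a stage tag.

    ``matrices`` maps a cluster label to a genes x samples DataFrame.  The
    ``stage`` tag tracks the normalization chain and stage transitions are
    only allowed in the order raw_mean -> cpm -> vst -> quantile.
    """

    matrices: dict[str, pd.DataFrame]
    stage: str = "raw_mean"
    contributing_cells: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.stage not in PSEUDOBULK_STAGES:
            raise StageError(f"unknown stage {self.stage!r}")

    def require_stage(self, stage: str) -> None:
        if self.stage != stage:
            raise StageError(
                f"operation requires stage {stage!r} but set is at {self.stage!r}"
            )

    def advance(self, matrices: dict[str, pd.DataFrame], new_stage: str) -> "PseudobulkSet":
        order = PSEUDOBULK_STAGES.index
        if order(new_stage) != order(self.stage) + 1:
            raise StageError(f"cannot advance from {self.stage!r} to {new_stage!r}")
        return PseudobulkSet(matrices, new_stage, self.contributing_cells)

    @property
    def clusters(self) -> list[str]:
        return list(self.matrices)


@dataclass
class FounderGenotypes:
    """Founder haplotype dosages for a multiparent population.

    ``dosage`` has shape ``(n_samples, n_markers, n_founders)``; each
    sample/marker 8-vector sums to 2 (diploid).  ``marker_map`` has one row
    per marker with ``marker``, ``chrom`` and 1-based ``pos``.
    """

    dosage: np.ndarray
    marker_map: pd.DataFrame
    sample_ids: list[str]
    founder_labels: tuple[str, ...] = ("A", "B", "C", "D", "E", "F", "G", "H")

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        n_s, n_m, n_f = self.dosage.shape
        if n_m != len(self.marker_map) or n_s != len(self.sample_ids):
            raise SchemaError("dosage shape inconsistent with marker map / samples")
        sums = self.dosage.sum(axis=2)
        if not np.allclose(sums, 2.0, atol=1e-6):
            raise SchemaError("dosage vectors must sum to 2 at every marker")

    @property
    def n_markers(self) -> int:
        return self.dosage.shape[1]

    def marker_index(self, marker: str) -> int:
        idx = self.marker_map.index[self.marker_map["marker"] == marker]
        if len(idx) == 0:
            raise KeyError(f"marker {marker!r} not in map")
        return int(idx[0])


@dataclass
class TrajectorySet:
    """Lineages (ordered cluster paths) with per-cell pseudotime and weights.

    ``pseudotime`` and ``weights`` are cells x lineages DataFrames (NaN /
    zero where a cell's cluster is not on the lineage); ``reduced_space`` is
    the cells x components embedding used for inference.
    """

    lineages: list[list[str]]
    pseudotime: pd.DataFrame
    weights: pd.DataFrame
    reduced_space: np.ndarray
    cell_clusters: pd.Series

    @property
    def lineage_ids(self) -> list[str]:
        return list(self.pseudotime.columns)


@dataclass
class GeneDAG:
    """A directed acyclic gene network learned for one co-expression module."""

    cluster_label: str
    module_id: str
    nodes: list[str]
    edges: list[tuple[str, str]]
    score: float = float("nan")

    def copy(self) -> "GeneDAG":
        return GeneDAG(
            self.cluster_label, self.module_id, list(self.nodes), list(self.edges), self.score
        )


@dataclass
class ModulePartition:
    """Signed co-expression module assignment for one cluster's pseudobulk."""

    cluster_label: str
    assignments: pd.Series  # gene -> module id, "unassigned" for the residual pool
    eigengenes: pd.DataFrame = field(default_factory=pd.DataFrame)  # samples x modules
    kme: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    params: dict = field(default_factory=dict)

    def modules(self) -> list[str]:
        mods = [m for m in self.assignments.unique() if m != "unassigned"]
        return sorted(mods)

    def members(self, module: str) -> list[str]:
        return list(self.assignments.index[self.assignments == module])
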