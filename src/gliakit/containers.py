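"""Core in-memory containers shared across the pipeline.

The central object is :class:`CountMatrix`, a genes x cells UMI count
matrix with per-cell metadata, mirroring the layout of a CellRanger-style
filtered matrix (MTX + genes.tsv + barcodes.tsv).  Downstream stages carry
log-normalized expression in :class:`NormalizedMatrix` and per-cell QC
quantities in a plain :class:`pandas.DataFrame` (see
:func:`gliakit.qc.compute_cell_metrics`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = ["CountMatrix", "GeneAnnotation", "NormalizedMatrix"]


@dataclass
class CountMatrix:
    """Genes x cells matrix of non-negative integer UMI counts.

    Parameters
    ----------
    counts
        Sparse (CSR) or dense matrix, shape ``(n_genes, n_cells)``.
    gene_ids
        Ordered gene names, length ``n_genes``, unique.
    barcodes
        Ordered cell barcodes, length ``n_cells``, unique.
    cell_meta
        Per-cell metadata indexed by barcode (sample, condition, age, sex,
        cell_type, cluster ... whichever are known at this stage).
    """

    counts: sp.spmatrix
    gene_ids: np.ndarray
    barcodes: np.ndarray
    cell_meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if not sp.issparse(self.counts):
            self.counts = sp.csr_matrix(np.asarray(self.counts))
        self.counts = self.counts.tocsr()
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.barcodes = np.asarray(self.barcodes, dtype=object)
        if self.counts.shape != (len(self.gene_ids), len(self.barcodes)):
            raise ValueError(
                f"counts shape {self.counts.shape} inconsistent with "
                f"{len(self.gene_ids)} genes x {len(self.barcodes)} barcodes"
            )
        if len(set(self.barcodes)) != len(self.barcodes):
            raise ValueError("barcodes are not unique")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene ids are not unique")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("counts must be non-negative")
        if self.cell_meta.empty:
            self.cell_meta = pd.DataFrame(index=pd.Index(self.barcodes, name="barcode"))
        else:
            self.cell_meta = self.cell_meta.loc[list(self.barcodes)]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def gene_index(self, genes: Sequence[str]) -> np.ndarray:
        """Positions of ``genes`` in :attr:`gene_ids`; raises on a miss."""
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in lookup]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing[:5]}")
        return np.array([lookup[g] for g in genes], dtype=int)

    def subset_cells(self, mask: np.ndarray) -> "CountMatrix":
        """New matrix keeping cells where ``mask`` is true; order preserved."""
        mask = np.asarray(mask, dtype=bool)
        return CountMatrix(
            counts=self.counts[:, mask],
            gene_ids=self.gene_ids,
            barcodes=self.barcodes[mask],
            cell_meta=self.cell_meta.loc[mask].copy(),
        )

    def subset_genes(self, keep: np.ndarray) -> "CountMatrix":
        keep = np.asarray(keep, dtype=bool)
        return CountMatrix(
            counts=self.counts[keep, :],
            gene_ids=self.gene_ids[keep],
            barcodes=self.barcodes,
            cell_meta=self.cell_meta.copy(),
        )

    def total_counts(self) -> np.ndarray:
        """Per-cell UMI totals (nCount_RNA)."""
        return np.asarray(self.counts.sum(axis=0)).ravel()


MITO_PREFIX = "mt-"
RIBO_PREFIXES = ("Rps", "Rpl")

#: genes excluded before subtype clustering because they inject variance
#: unrelated to cell state (the transgene itself, sex genes, abundant
#: lncRNAs, known ambient-prone transcripts)
DEFAULT_EXCLUDED_CONFOUNDERS = (
    "Sod1",
    "Gm8566",
    "Cmss1",
    "Cdk8",
    "Xist",
    "Gm42418",
    "Gm424181",
    "Malat1",
)


@dataclass
class GeneAnnotation:
    """Per-gene annotation table: chromosome plus mito/ribo/confounder flags.

    ``table`` is indexed by gene name with columns ``chromosome``,
    ``is_mito``, ``is_ribo``, ``is_excluded_confounder``.
    """

    table: pd.DataFrame

    @classmethod
    def from_genes(
        cls,
        gene_ids: Sequence[str],
        chromosome: dict[str, str] | None = None,
        excluded_confounders: Sequence[str] = DEFAULT_EXCLUDED_CONFOUNDERS,
    ) -> "GeneAnnotation":
        """Build from prefix conventions (mt- mitochondrial, Rps/Rpl ribosomal).

        ``chromosome`` maps gene -> chromosome label; genes not listed get
        "un" (unknown).  Y-linked genes must be declared here for sex calls.
        """
        chromosome = chromosome or {}
        genes = list(gene_ids)
        excluded = set(excluded_confounders)
        table = pd.DataFrame(
            {
                "chromosome": [chromosome.get(g, "un") for g in genes],
                "is_mito": [g.startswith(MITO_PREFIX) for g in genes],
                "is_ribo": [g.startswith(RIBO_PREFIXES) for g in genes],
                "is_excluded_confounder": [g in excluded for g in genes],
            },
            index=pd.Index(genes, name="gene"),
        )
        return cls(table)

    def require_cover(self, gene_ids: Sequence[str]) -> None:
        missing = set(gene_ids) - set(self.table.index)
        if missing:
            raise KeyError(f"unannotated genes: {sorted(missing)[:5]}")

    def genes_on(self, chrom: str) -> list[str]:
        return list(self.table.index[self.table["chromosome"] == chrom])

    @property
    def mito_genes(self) -> list[str]:
        return list(self.table.index[self.table["is_mito"]])

    @property
    def ribo_genes(self) -> list[str]:
        return list(self.table.index[self.table["is_ribo"]])

    @property
    def excluded_confounders(self) -> list[str]:
        return list(self.table.index[self.table["is_excluded_confounder"]])


@dataclass
class NormalizedMatrix:
    """Log-scale expression, genes x cells, from depth normalization + log1p."""

    values: np.ndarray
    gene_ids: np.ndarray
    barcodes: np.ndarray
    scale_factor: float = 1e4
    cell_meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.barcodes = np.asarray(self.barcodes, dtype=object)
        if self.values.shape != (len(self.gene_ids), len(self.barcodes)):
            raise ValueError("values shape inconsistent with gene/barcode lists")
        if self.cell_meta.empty:
            self.cell_meta = pd.DataFrame(index=pd.Index(self.barcodes, name="barcode"))

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def gene_index(self, genes: Sequence[str]) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in lookup]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing[:5]}")
        return np.array([lookup[g] for g in genes], dtype=int)

    def subset_genes(self, keep: np.ndarray) -> "NormalizedMatrix":
        keep = np.asarray(keep, dtype=bool)
        return NormalizedMatrix(
            values=self.values[keep, :],
            gene_ids=self.gene_ids[keep],
            barcodes=self.barcodes,
            scale_factor=self.scale_factor,
            cell_meta=self.cell_meta.copy(),
        )
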