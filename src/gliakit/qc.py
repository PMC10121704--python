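"""Per-cell quality control, the Xist/Y sex classifier, and module scoring.

The stages here run in the order a droplet dataset is cleaned: a raw-UMI
pre-filter on barcodes, per-cell QC metrics, transcriptional sex
assignment from Xist and Y-linked genes, cell-type specific QC gates, and
expression-bin-matched gene-set (module) scoring used for immediate-early
gene, cell-cycle and subtype-signature readouts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import CountMatrix, GeneAnnotation, NormalizedMatrix

__all__ = [
    "filter_droplets",
    "compute_cell_metrics",
    "assign_sex",
    "CellTypeThresholds",
    "CELLTYPE_QC",
    "apply_celltype_qc",
    "module_score",
    "assign_cell_cycle",
]

XIST_GENE = "Xist"


class EmptyFilterResult(ValueError):
    """All barcodes were removed by a filter (input itself was non-empty)."""


def filter_droplets(raw: CountMatrix, min_umi: int = 100) -> CountMatrix:
    """Drop barcodes whose total UMI count is below ``min_umi``.

    A barcode with exactly ``min_umi`` UMIs is retained.  Gene set and
    barcode order are preserved.
    """
    if raw.n_cells == 0:
        raise ValueError("input matrix has no barcodes")
    totals = raw.total_counts()
    keep = totals >= min_umi
    if not keep.any():
        raise EmptyFilterResult(
            f"no barcode reaches {min_umi} UMIs (max total {totals.max():.0f})"
        )
    return raw.subset_cells(keep)


def compute_cell_metrics(
    m: CountMatrix,
    ann: GeneAnnotation,
    xist_gene: str = XIST_GENE,
) -> pd.DataFrame:
    """Per-cell QC metrics.

    Returns a DataFrame indexed by barcode with columns

    - ``nFeature_RNA``: genes with nonzero count
    - ``nCount_RNA``:   total UMIs
    - ``percent_mt``:   100 x mito UMIs / total UMIs (0 where total is 0)
    - ``xist_count``:   UMIs of the Xist gene (0 if absent from the matrix)
    - ``nFeature_Y``:   number of Y-chromosome genes detected
    - ``nCount_Y``:     UMIs on Y-chromosome genes
    - ``zero_total``:   flag for cells with no counts at all
    """
    ann.require_cover(m.gene_ids)
    counts = m.counts.tocsc()
    total = np.asarray(counts.sum(axis=0)).ravel()
    n_feature = np.asarray((counts > 0).sum(axis=0)).ravel()

    flags = ann.table.loc[list(m.gene_ids)]
    mito_mask = flags["is_mito"].to_numpy()
    y_mask = (flags["chromosome"] == "Y").to_numpy()

    mito_counts = np.asarray(counts[mito_mask, :].sum(axis=0)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        percent_mt = np.where(total > 0, 100.0 * mito_counts / np.maximum(total, 1), 0.0)

    y_sub = counts[y_mask, :]
    n_count_y = np.asarray(y_sub.sum(axis=0)).ravel()
    n_feature_y = np.asarray((y_sub > 0).sum(axis=0)).ravel()

    if xist_gene in set(m.gene_ids):
        xist = np.asarray(counts[m.gene_index([xist_gene])[0], :].todense()).ravel()
    else:
        xist = np.zeros(m.n_cells)

    return pd.DataFrame(
        {
            "nFeature_RNA": n_feature.astype(int),
            "nCount_RNA": total,
            "percent_mt": percent_mt,
            "xist_count": xist,
            "nFeature_Y": n_feature_y.astype(int),
            "nCount_Y": n_count_y,
            "zero_total": total == 0,
        },
        index=pd.Index(m.barcodes, name="barcode"),
    )


def assign_sex(metrics: pd.DataFrame) -> pd.Series:
    """Transcriptional sex call per cell from raw Xist and Y-gene counts.

    male   iff xist_count < 1 and nFeature_Y > 0;
    female iff xist_count > 0 and nFeature_Y < 2 and nCount_Y < 2;
    everything else is "undefined" and marked for exclusion downstream.
    The two rules are mutually exclusive, so evaluation order is immaterial.
    """
    xist = metrics["xist_count"].to_numpy()
    nfy = metrics["nFeature_Y"].to_numpy()
    ncy = metrics["nCount_Y"].to_numpy()
    male = (xist < 1) & (nfy > 0)
    female = (xist > 0) & (nfy < 2) & (ncy < 2)
    out = np.where(male, "male", np.where(female, "female", "undefined"))
    return pd.Series(out, index=metrics.index, name="assigned_sex")


@dataclass(frozen=True)
class CellTypeThresholds:
    """QC gate for one cell type; all comparisons are strict inequalities."""

    min_features: float
    min_counts: float
    max_counts: float
    max_percent_mt: float


# Printed per-type gates for the three glial populations of interest.
CELLTYPE_QC: dict[str, CellTypeThresholds] = {
    "astrocyte": CellTypeThresholds(1000, 2000, 10_000, 8.0),
    "microglia": CellTypeThresholds(700, 1000, 10_000, 5.0),
    "oligodendrocyte": CellTypeThresholds(1300, 2500, 50_000, 5.0),
}


def apply_celltype_qc(
    metrics: pd.DataFrame,
    cell_type: str,
    thresholds: CellTypeThresholds | None = None,
) -> np.ndarray:
    """Keep mask for cells of ``cell_type`` under its QC gate.

    All four comparisons are strict, so a cell sitting exactly on a
    threshold is dropped.  Unknown cell types require explicit
    ``thresholds``.
    """
    if thresholds is None:
        try:
            thresholds = CELLTYPE_QC[cell_type]
        except KeyError:
            raise KeyError(
                f"no built-in QC gate for {cell_type!r}; pass thresholds="
            ) from None
    nf = metrics["nFeature_RNA"].to_numpy()
    nc = metrics["nCount_RNA"].to_numpy()
    mt = metrics["percent_mt"].to_numpy()
    return (
        (nf > thresholds.min_features)
        & (nc > thresholds.min_counts)
        & (nc < thresholds.max_counts)
        & (mt < thresholds.max_percent_mt)
    )


def module_score(
    norm: NormalizedMatrix,
    gene_set: list[str],
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int | None = 0,
) -> pd.Series:
    """Expression-bin-matched gene-set score per cell.

    Genes are cut into ``n_bins`` equal-frequency bins of mean expression
    across cells.  For every set gene, ``n_ctrl`` control genes are drawn
    with replacement from its bin; the score of a cell is the mean
    expression of the set minus the mean expression of the pooled control
    draws.  A positive score means the set is expressed above genes of
    comparable overall abundance.
    """
    present = [g for g in gene_set if g in set(norm.gene_ids)]
    if not present:
        raise KeyError("gene set has empty intersection with the matrix")
    rng = np.random.default_rng(seed)

    mean_expr = norm.values.mean(axis=1)
    # canonical order (mean, then name) so scores do not depend on the
    # storage order of genes
    order = np.lexsort((norm.gene_ids, mean_expr))
    n_bins = min(n_bins, norm.n_genes)
    bin_of = np.empty(norm.n_genes, dtype=int)
    bin_of[order] = np.floor(
        np.arange(norm.n_genes) * n_bins / norm.n_genes
    ).astype(int)
    # bin membership listed in canonical order, so control draws pick the
    # same gene names whatever the input order
    bin_members = [order[bin_of[order] == b] for b in range(n_bins)]

    set_idx = norm.gene_index(present)
    ctrl_rows: list[np.ndarray] = []
    for gi in set_idx:
        members = bin_members[bin_of[gi]]
        ctrl_rows.append(rng.choice(members, size=n_ctrl, replace=True))
    ctrl_idx = np.concatenate(ctrl_rows)

    set_mean = norm.values[set_idx, :].mean(axis=0)
    ctrl_mean = norm.values[ctrl_idx, :].mean(axis=0)
    return pd.Series(
        set_mean - ctrl_mean, index=pd.Index(norm.barcodes, name="barcode"), name="score"
    )


def assign_cell_cycle(scores_s: pd.Series, scores_g2m: pd.Series) -> pd.Series:
    """Phase call per cell from S and G2M module scores.

    The phase is the arg-max of the two scores if that maximum is positive,
    else G1.  An exact positive tie resolves to S (documented tie-break).
    """
    if not scores_s.index.equals(scores_g2m.index):
        raise ValueError("S and G2M scores must cover the same cells")
    s = scores_s.to_numpy()
    g2m = scores_g2m.to_numpy()
    phase = np.where(np.maximum(s, g2m) <= 0, "G1", np.where(s >= g2m, "S", "G2M"))
    return pd.Series(phase, index=scores_s.index, name="phase")
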