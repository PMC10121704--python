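"""Normalization, embedding, clustering, markers, DE and pseudobulk.

Expression values are depth-normalized and log-transformed once
(:func:`lognormalize`) and every statistic downstream is computed on that
scale.  Fold changes are reported as
``log2((mean(expm1 x_A) + 1) / (mean(expm1 x_B) + 1))``, i.e. on
depth-normalized counts with a pseudocount of 1, which is the scale the
0.25 / 1.0 log2FC thresholds used throughout assume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors
from statsmodels.stats.multitest import multipletests

from .containers import CountMatrix, NormalizedMatrix

__all__ = [
    "lognormalize",
    "pca_embed",
    "cluster_cells",
    "ClusterResult",
    "find_markers_all",
    "differential_expression",
    "pseudobulk",
    "pseudobulk_pca",
    "annotate_clusters",
    "subpopulation_proportions",
]


def lognormalize(m: CountMatrix, scale_factor: float = 1e4) -> NormalizedMatrix:
    """Depth normalization: ``ln(1 + scale_factor * count / cell_total)``."""
    totals = m.total_counts()
    if (totals == 0).any():
        raise ValueError("zero-total cells present; filter them first")
    dense = np.asarray(m.counts.todense(), dtype=float)
    values = np.log1p(scale_factor * dense / totals[None, :])
    return NormalizedMatrix(
        values=values,
        gene_ids=m.gene_ids,
        barcodes=m.barcodes,
        scale_factor=scale_factor,
        cell_meta=m.cell_meta.copy(),
    )


def pca_embed(
    norm: NormalizedMatrix,
    n_pcs: int = 17,
    n_hvg: int = 2000,
    scale_cap: float = 10.0,
    exclude_genes: list[str] | None = None,
) -> pd.DataFrame:
    """Cells x ``n_pcs`` PC-score embedding.

    The ``n_hvg`` most variable genes (log-scale variance) are centered,
    scaled to unit variance with values capped at ``scale_cap``, and
    decomposed by SVD.  ``exclude_genes`` (e.g. confounder genes removed
    before subtype clustering) are dropped before HVG selection.
    """
    values = norm.values
    gene_ids = norm.gene_ids
    if exclude_genes:
        drop = np.isin(gene_ids, list(exclude_genes))
        values = values[~drop, :]
        gene_ids = gene_ids[~drop]
    if n_pcs >= min(values.shape[0], values.shape[1]):
        raise ValueError("n_pcs must be below min(n_genes, n_cells)")

    var = values.var(axis=1)
    n_hvg = min(n_hvg, values.shape[0])
    hvg = np.argsort(var, kind="stable")[::-1][:n_hvg]
    x = values[np.sort(hvg), :].T  # cells x genes
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    x = np.clip((x - mu) / sd, -scale_cap, scale_cap)

    pca = PCA(n_components=n_pcs, svd_solver="full")
    scores = pca.fit_transform(x)
    return pd.DataFrame(
        scores,
        index=pd.Index(norm.barcodes, name="barcode"),
        columns=[f"PC{i + 1}" for i in range(n_pcs)],
    )


@dataclass
class ClusterResult:
    """Partition of cells from graph-based community detection."""

    labels: pd.Series  # cluster id per barcode, contiguous from 1
    n_pcs: int
    resolution: float
    k_neighbors: int
    modularity: float = field(default=float("nan"))

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max())


def _snn_graph(embedding: np.ndarray, k_neighbors: int, prune: float) -> ig.Graph:
    """Shared-nearest-neighbor graph with Jaccard edge weights."""
    n = embedding.shape[0]
    nn = NearestNeighbors(n_neighbors=k_neighbors).fit(embedding)
    adj = nn.kneighbors_graph(embedding, mode="connectivity")  # includes self
    inter = (adj @ adj.T).tocoo()
    jaccard = inter.data / (2 * k_neighbors - inter.data)
    keep = (jaccard > prune) & (inter.row < inter.col)
    edges = list(zip(inter.row[keep].tolist(), inter.col[keep].tolist()))
    g = ig.Graph(n=n, edges=edges)
    g.es["weight"] = jaccard[keep].tolist()
    return g


def cluster_cells(
    embedding: pd.DataFrame,
    k_neighbors: int = 20,
    resolution: float = 0.5,
    seed: int = 0,
    prune: float = 1 / 15,
) -> ClusterResult:
    """Graph-based clustering of cells in PC space.

    A k-nearest-neighbor graph (Euclidean) is converted to
    shared-nearest-neighbor Jaccard weights (edges pruned below ``prune``)
    and partitioned by resolution-parameterized modularity optimization.
    Labels are contiguous integers from 1, ordered by decreasing cluster
    size; fixed ``seed`` makes the partition deterministic.
    """
    x = np.asarray(embedding, dtype=float)
    if x.shape[0] < k_neighbors + 1:
        raise ValueError("need at least k_neighbors + 1 cells")
    g = _snn_graph(x, k_neighbors, prune)
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight",
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=-1,
    )
    raw = np.asarray(part.membership)
    # relabel 1..K by decreasing size, ties by first occurrence
    sizes = pd.Series(raw).value_counts(sort=False)
    order = sizes.sort_values(ascending=False, kind="stable").index
    remap = {old: new + 1 for new, old in enumerate(order)}
    labels = pd.Series(
        [remap[c] for c in raw], index=embedding.index, name="cluster"
    )
    return ClusterResult(
        labels=labels,
        n_pcs=x.shape[1],
        resolution=resolution,
        k_neighbors=k_neighbors,
        modularity=part.quality(),
    )


def _log2fc(values: np.ndarray, in_mask: np.ndarray, out_mask: np.ndarray) -> np.ndarray:
    """log2FC on depth-normalized counts with +1 pseudocount, per gene."""
    mean_in = np.expm1(values[:, in_mask]).mean(axis=1)
    mean_out = np.expm1(values[:, out_mask]).mean(axis=1)
    return np.log2((mean_in + 1.0) / (mean_out + 1.0))


def _adjust(p: np.ndarray, method: str) -> np.ndarray:
    if method == "bonferroni":
        return np.minimum(p * len(p), 1.0)
    if method in ("bh", "fdr_bh"):
        return multipletests(p, method="fdr_bh")[1]
    raise ValueError(f"unknown correction {method!r}")


def find_markers_all(
    norm: NormalizedMatrix,
    clusters: pd.Series,
    min_pct: float = 0.10,
    min_log2fc: float = 0.25,
    correction: str = "bonferroni",
) -> pd.DataFrame:
    """One-vs-rest Wilcoxon marker genes per cluster.

    For each cluster, every gene is tested cluster-vs-rest with the
    rank-sum test (normal approximation, tie-corrected); reported markers
    express in at least ``min_pct`` of the cluster's cells and have
    log2FC above ``min_log2fc``.  ``p_adj`` corrects over all tested
    genes of that cluster.
    """
    labels = clusters.loc[list(norm.barcodes)].to_numpy()
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("need at least 2 clusters to find markers")
    rows = []
    for cl in uniq:
        in_mask = labels == cl
        if in_mask.sum() < 3:
            raise ValueError(f"cluster {cl} has fewer than 3 cells")
        out_mask = ~in_mask
        x = norm.values[:, in_mask]
        y = norm.values[:, out_mask]
        pct_in = (x > 0).mean(axis=1)
        pct_out = (y > 0).mean(axis=1)
        lfc = _log2fc(norm.values, in_mask, out_mask)
        res = stats.mannwhitneyu(x, y, axis=1, alternative="two-sided")
        p = np.asarray(res.pvalue)
        p_adj = _adjust(p, correction)
        keep = (pct_in >= min_pct) & (lfc > min_log2fc)
        df = pd.DataFrame(
            {
                "cluster": cl,
                "gene": norm.gene_ids[keep],
                "log2FC": lfc[keep],
                "p": p[keep],
                "p_adj": p_adj[keep],
                "pct_in": pct_in[keep],
                "pct_out": pct_out[keep],
            }
        )
        rows.append(df.sort_values("p_adj", kind="stable"))
    return pd.concat(rows, ignore_index=True)


def differential_expression(
    norm: NormalizedMatrix,
    cells_a: np.ndarray,
    cells_b: np.ndarray,
    test: str = "t",
    min_cells_detected: int = 3,
    correction: str = "bonferroni",
    padj_threshold: float = 0.05,
    log2fc_threshold: float = 1.0,
) -> pd.DataFrame:
    """Two-group differential expression on log-normalized values.

    ``cells_a`` / ``cells_b`` are boolean masks or barcode lists.  Genes
    detected in fewer than ``min_cells_detected`` cells of the union are
    not tested.  ``test`` is Welch's t-test ("t", default) or Wilcoxon
    ("wilcoxon").  The ``significant`` flag marks
    ``p_adj < padj_threshold`` and ``|log2FC| > log2fc_threshold``;
    rows are never dropped by the flag.  Genes with zero variance in both
    groups get p = 1 and ``degenerate`` = True.
    """
    mask_a = _cell_mask(norm, cells_a)
    mask_b = _cell_mask(norm, cells_b)
    if mask_a.sum() < 3 or mask_b.sum() < 3:
        raise ValueError("each group needs at least 3 cells")

    union = mask_a | mask_b
    detected = (norm.values[:, union] > 0).sum(axis=1)
    tested = detected >= min_cells_detected
    x = norm.values[np.ix_(tested, mask_a)]
    y = norm.values[np.ix_(tested, mask_b)]

    lfc = _log2fc(norm.values[tested, :], mask_a, mask_b)
    degenerate = (x.var(axis=1) == 0) & (y.var(axis=1) == 0)
    if test == "t":
        res = stats.ttest_ind(x, y, axis=1, equal_var=False)
        p = np.asarray(res.pvalue)
    elif test == "wilcoxon":
        res = stats.mannwhitneyu(x, y, axis=1, alternative="two-sided")
        p = np.asarray(res.pvalue)
    else:
        raise ValueError(f"unknown test {test!r}")
    p = np.where(degenerate | ~np.isfinite(p), 1.0, p)
    p_adj = _adjust(p, correction)

    out = pd.DataFrame(
        {
            "gene": norm.gene_ids[tested],
            "log2FC": lfc,
            "p": p,
            "p_adj": p_adj,
            "pct_in": (x > 0).mean(axis=1),
            "pct_out": (y > 0).mean(axis=1),
            "degenerate": degenerate,
            "test": test,
        }
    )
    out["significant"] = (out["p_adj"] < padj_threshold) & (
        out["log2FC"].abs() > log2fc_threshold
    )
    return out


def _cell_mask(norm: NormalizedMatrix, cells) -> np.ndarray:
    cells = np.asarray(cells)
    if cells.dtype == bool:
        if cells.shape != (norm.n_cells,):
            raise ValueError("boolean mask length mismatch")
        return cells
    barcode_set = set(cells.tolist())
    return np.array([b in barcode_set for b in norm.barcodes])


def pseudobulk(
    m: CountMatrix,
    keys: tuple[str, ...] = ("condition", "age", "sex"),
) -> pd.DataFrame:
    """Sum counts of cells sharing a metadata key into one column per group.

    Returns genes x groups with a MultiIndex column of the key values.
    Empty groups are absent; total counts are conserved exactly.
    """
    for key in keys:
        if key not in m.cell_meta.columns:
            raise KeyError(f"cell metadata lacks key {key!r}")
        if m.cell_meta[key].isna().any():
            raise KeyError(f"cell metadata key {key!r} has missing values")
    group_ids = pd.MultiIndex.from_frame(m.cell_meta[list(keys)])
    dense = np.asarray(m.counts.todense())
    frame = pd.DataFrame(dense.T, index=group_ids)  # cells x genes
    summed = frame.groupby(level=list(range(len(keys))), sort=True).sum()
    out = summed.T
    out.index = pd.Index(m.gene_ids, name="gene")
    return out


def pseudobulk_pca(
    pb: pd.DataFrame, n_pcs: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """PCA of pseudobulk samples; returns (scores, loadings, explained ratio).

    Columns are library-size normalized to counts per million, log1p
    transformed and gene-centered; samples are the observations.
    Loadings let outlier-driving genes be read off the separating PC.
    """
    if pb.shape[1] < 3:
        raise ValueError("pseudobulk PCA needs at least 3 samples")
    totals = pb.sum(axis=0).to_numpy(dtype=float)
    if (totals == 0).any():
        raise ValueError("pseudobulk column with zero total")
    cpm = np.log1p(1e6 * pb.to_numpy(dtype=float) / totals[None, :])
    centered = cpm - cpm.mean(axis=1, keepdims=True)
    n_pcs = n_pcs or min(pb.shape[1] - 1, 10)
    pca = PCA(n_components=n_pcs, svd_solver="full")
    scores = pca.fit_transform(centered.T)  # samples x pcs
    cols = [f"PC{i + 1}" for i in range(n_pcs)]
    return (
        pd.DataFrame(scores, index=pb.columns, columns=cols),
        pd.DataFrame(pca.components_.T, index=pb.index, columns=cols),
        pca.explained_variance_ratio_,
    )


def annotate_clusters(
    norm: NormalizedMatrix,
    clusters: pd.Series,
    canonical_markers: dict[str, list[str]],
    min_expressing: float = 0.80,
    rule: str = "each",
) -> pd.Series:
    """Label clusters by canonical marker expression.

    A cluster is labeled with a type iff at least ``min_expressing`` of
    its cells have nonzero expression of the type's markers — under the
    default ``rule="each"``, every listed marker must individually clear
    the fraction; ``rule="any"`` requires any one marker to.  Clusters
    matching zero or multiple types are labeled "ambiguous"; nothing is
    silently chosen.
    """
    if not canonical_markers:
        raise ValueError("canonical_markers is empty")
    all_markers = sorted({g for gs in canonical_markers.values() for g in gs})
    idx = norm.gene_index(all_markers)  # raises on absent marker
    pos = dict(zip(all_markers, idx))

    labels = clusters.loc[list(norm.barcodes)].to_numpy()
    out: dict[int, str] = {}
    for cl in np.unique(labels):
        cells = labels == cl
        matches = []
        for ctype, markers in canonical_markers.items():
            fracs = [
                (norm.values[pos[g], cells] > 0).mean() for g in markers
            ]
            ok = (
                all(f >= min_expressing for f in fracs)
                if rule == "each"
                else any(f >= min_expressing for f in fracs)
            )
            if ok:
                matches.append(ctype)
        out[int(cl)] = matches[0] if len(matches) == 1 else "ambiguous"
    return pd.Series(out, name="cell_type").rename_axis("cluster")


def subpopulation_proportions(
    clusters: pd.Series, cell_meta: pd.DataFrame, strata: tuple[str, ...] = ("condition",)
) -> pd.DataFrame:
    """Cluster composition per stratum: fractions of each stratum's cells.

    Rows are clusters, columns strata (e.g. CTRL / SOD1, or condition x
    age); each column sums to 1.
    """
    meta = cell_meta.loc[clusters.index]
    strat = meta[list(strata)].astype(str).agg("/".join, axis=1)
    table = pd.crosstab(clusters, strat)
    return table / table.sum(axis=0)
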