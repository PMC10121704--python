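"""End-to-end orchestration of the single-cell and imaging pipelines.

``run_sc_pipeline`` chains the cleaning and analysis stages — droplet
pre-filter, QC metrics, sex assignment (undefined excluded), cell-type
QC gates, normalization, clustering, annotation, markers, per-time-point
differential expression, pseudobulk PCA and GSEA on the end-stage
contrast — and records how many cells each gate removed in a
:class:`RunManifest`.  ``run_imaging_pipeline`` batches one quantification
over a directory of TIFF stacks and aggregates per animal.

Cell-type labels for the QC gates come from the input metadata when
present; otherwise a preliminary cluster-and-annotate pass on the
sex-defined cells supplies them, mirroring how an annotated dataset is
gated per population.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import analysis, imaging, qc
from .containers import CountMatrix, GeneAnnotation
from .gsea import gsea_preranked, rank_genes
from .io import read_stack_tiff
from .simulate.counts import DEFAULT_MARKERS

__all__ = ["PipelineConfig", "RunManifest", "run_sc_pipeline", "run_imaging_pipeline"]


@dataclass
class PipelineConfig:
    """All stage parameters; the defaults are the pipeline's standard
    operating point (100-UMI pre-filter, resolution 0.5 / 0.2, 17 PCs,
    10-800 gene sets, 1000 permutations)."""

    # gates
    do_droplet_filter: bool = True
    do_sex_filter: bool = True
    do_celltype_qc: bool = True
    min_umi: int = 100
    # normalization / clustering
    scale_factor: float = 1e4
    n_pcs: int = 17
    n_hvg: int = 2000
    k_neighbors: int = 20
    resolution: float = 0.5
    subtype_resolution: float = 0.2
    annotate_min_expressing: float = 0.80
    # markers / DE
    marker_min_pct: float = 0.10
    marker_min_log2fc: float = 0.25
    de_test: str = "t"
    de_padj: float = 0.05
    de_log2fc: float = 1.0
    # GSEA
    gsea_min_size: int = 10
    gsea_max_size: int = 800
    gsea_n_perm: int = 1000
    gsea_age: str = "4M"
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


@dataclass
class RunManifest:
    """Per-stage record counts and the resolved parameter snapshot."""

    params: dict
    stages: dict = field(default_factory=dict)
    started: str = ""
    finished: str = ""

    def record(self, stage: str, **counts) -> None:
        self.stages[stage] = counts

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=str))


def _now() -> str:
    return datetime.now(timezone.utc).isoformat()


def run_sc_pipeline(
    m: CountMatrix,
    ann: GeneAnnotation,
    gene_sets: dict[str, list[str]] | None = None,
    canonical_markers: dict[str, list[str]] | None = None,
    config: PipelineConfig | None = None,
) -> tuple[dict, RunManifest]:
    """Run the single-cell pipeline; returns (outputs, manifest).

    Outputs hold the retained matrix, per-cell metrics and sex labels,
    cluster labels and annotations, marker table, per-time-point DE
    tables, pseudobulk PCA scores/loadings, and (when ``gene_sets`` is
    given) the GSEA table for the end-stage condition contrast.
    """
    config = config or PipelineConfig()
    canonical_markers = canonical_markers or {
        t: list(g) for t, g in DEFAULT_MARKERS.items()
    }
    manifest = RunManifest(params=asdict(config), started=_now())
    outputs: dict = {}
    n0 = m.n_cells

    if config.do_droplet_filter:
        m = qc.filter_droplets(m, config.min_umi)
    manifest.record("droplet_filter", cells_in=n0, cells_out=m.n_cells)

    metrics = qc.compute_cell_metrics(m, ann)
    sex = qc.assign_sex(metrics)
    m.cell_meta["assigned_sex"] = sex.to_numpy()
    if config.do_sex_filter:
        keep = (sex != "undefined").to_numpy()
        n_in = m.n_cells
        m = m.subset_cells(keep)
        metrics = metrics.loc[keep]
        manifest.record("sex_filter", cells_in=n_in, cells_out=m.n_cells)
    outputs["metrics"] = metrics
    outputs["sex"] = m.cell_meta["assigned_sex"]

    # provisional typing for the per-type QC gates
    if "cell_type" in m.cell_meta.columns and m.cell_meta["cell_type"].notna().all():
        cell_types = m.cell_meta["cell_type"]
    else:
        norm0 = analysis.lognormalize(m, config.scale_factor)
        emb0 = analysis.pca_embed(norm0, config.n_pcs, config.n_hvg)
        cl0 = analysis.cluster_cells(
            emb0, config.k_neighbors, config.resolution, seed=config.seed
        )
        types0 = analysis.annotate_clusters(
            norm0, cl0.labels, canonical_markers, config.annotate_min_expressing
        )
        cell_types = cl0.labels.map(types0)
    m.cell_meta["cell_type"] = cell_types.to_numpy()

    if config.do_celltype_qc:
        n_in = m.n_cells
        keep = np.ones(m.n_cells, dtype=bool)
        removed_per_type = {}
        for ctype, thresholds in qc.CELLTYPE_QC.items():
            in_type = (m.cell_meta["cell_type"] == ctype).to_numpy()
            ok = qc.apply_celltype_qc(metrics, ctype, thresholds)
            keep &= ~in_type | ok
            removed_per_type[ctype] = int((in_type & ~ok).sum())
        m = m.subset_cells(keep)
        metrics = metrics.loc[keep]
        manifest.record(
            "celltype_qc", cells_in=n_in, cells_out=m.n_cells, **removed_per_type
        )
    outputs["matrix"] = m

    norm = analysis.lognormalize(m, config.scale_factor)
    emb = analysis.pca_embed(norm, config.n_pcs, config.n_hvg)
    clusters = analysis.cluster_cells(
        emb, config.k_neighbors, config.resolution, seed=config.seed
    )
    cluster_types = analysis.annotate_clusters(
        norm, clusters.labels, canonical_markers, config.annotate_min_expressing
    )
    outputs["clusters"] = clusters
    outputs["cluster_types"] = cluster_types
    manifest.record("clustering", cells=m.n_cells, clusters=clusters.n_clusters)

    if clusters.n_clusters >= 2:
        outputs["markers"] = analysis.find_markers_all(
            norm, clusters.labels, config.marker_min_pct, config.marker_min_log2fc
        )

    de_tables: dict[str, pd.DataFrame] = {}
    meta = m.cell_meta
    for age in sorted(meta["age"].unique()):
        mask_a = ((meta["age"] == age) & (meta["condition"] == "SOD1")).to_numpy()
        mask_b = ((meta["age"] == age) & (meta["condition"] == "CTRL")).to_numpy()
        if mask_a.sum() >= 3 and mask_b.sum() >= 3:
            de_tables[age] = analysis.differential_expression(
                norm,
                mask_a,
                mask_b,
                test=config.de_test,
                padj_threshold=config.de_padj,
                log2fc_threshold=config.de_log2fc,
            )
    outputs["de"] = de_tables
    manifest.record("differential_expression", contrasts=len(de_tables))

    pb = analysis.pseudobulk(m, keys=("condition", "age", "sex"))
    outputs["pseudobulk"] = pb
    if pb.shape[1] >= 3:
        scores, loadings, evr = analysis.pseudobulk_pca(pb)
        outputs["pseudobulk_pca"] = {
            "scores": scores,
            "loadings": loadings,
            "explained_variance_ratio": evr,
        }
    manifest.record("pseudobulk", groups=pb.shape[1])

    if gene_sets and config.gsea_age in de_tables:
        ranked = rank_genes(de_tables[config.gsea_age])
        try:
            outputs["gsea"] = gsea_preranked(
                ranked,
                gene_sets,
                min_size=config.gsea_min_size,
                max_size=config.gsea_max_size,
                n_perm=config.gsea_n_perm,
                seed=config.seed,
            )
            manifest.record("gsea", sets_tested=len(outputs["gsea"]))
        except ValueError:
            manifest.record("gsea", sets_tested=0)

    manifest.finished = _now()
    return outputs, manifest


def run_imaging_pipeline(
    image_dir: str | Path,
    measurement: str,
    n_frames: int = 20,
    threshold_method: str = "otsu",
) -> tuple[pd.DataFrame, pd.DataFrame, RunManifest]:
    """Batch one quantification over a directory of TIFF stacks.

    Files are ``<animal>__<image>.tif`` with JSON sidecars; per-image
    values are aggregated into per-animal means.  ``measurement`` is
    ``intensity`` (Yen-limited integrated density), ``mbp`` (fiber
    volume fraction) or ``sholl`` (profile area under the curve, soma at
    the largest-component centroid).
    """
    image_dir = Path(image_dir)
    files = sorted(image_dir.glob("*.tif")) + sorted(image_dir.glob("*.tiff"))
    if not files:
        raise FileNotFoundError(f"no TIFF stacks in {image_dir}")
    manifest = RunManifest(
        params={"measurement": measurement, "n_frames": n_frames}, started=_now()
    )
    rows = []
    for path in files:
        stack = read_stack_tiff(path)
        stem = path.stem
        animal = stem.split("__")[0]
        if measurement == "intensity":
            value = imaging.integrated_density_limited(stack).value
        elif measurement == "mbp":
            value = imaging.fiber_volume_fraction(
                stack, n_frames, method=threshold_method
            ).value
        elif measurement == "sholl":
            proj = imaging.max_projection(stack)
            thr = imaging.yen_threshold(proj)
            mask = proj > thr
            center = imaging.soma_center_from_mask(mask, stack.pixel_size_um)
            prof = imaging.sholl_profile(mask, center, stack.pixel_size_um)
            value = float(np.nansum(prof.intersections))
        else:
            raise ValueError(f"unknown measurement {measurement!r}")
        rows.append({"animal": animal, "image": stem, "value": value})
    per_image = pd.DataFrame(rows)
    per_animal = per_image.groupby("animal", as_index=False)["value"].mean()
    manifest.record(
        "imaging", images=len(per_image), animals=len(per_animal)
    )
    manifest.finished = _now()
    return per_image, per_animal, manifest
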