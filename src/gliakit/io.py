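"""Readers and writers for the on-disk formats the pipeline exchanges.

Counts travel as Matrix-Market triplets with genes.tsv / barcodes.tsv
sidecars (the CellRanger layout), gene annotation and per-cell tables as
CSV, gene sets as GMT, image stacks as multi-page TIFF with a JSON
sidecar holding the pixel geometry, and pipeline configuration as YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import tifffile
import yaml

from .containers import CountMatrix, GeneAnnotation
from .imaging import ImageStack

__all__ = [
    "write_counts_mtx",
    "read_counts_mtx",
    "write_annotation_csv",
    "read_annotation_csv",
    "write_stack_tiff",
    "read_stack_tiff",
    "load_config_yaml",
    "dump_config_yaml",
]


def write_counts_mtx(m: CountMatrix, outdir: str | Path) -> None:
    """Write matrix.mtx + genes.tsv + barcodes.tsv (+ cell_meta.csv)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(outdir / "matrix.mtx", sp.coo_matrix(m.counts))
    pd.Series(m.gene_ids).to_csv(outdir / "genes.tsv", sep="\t", index=False, header=False)
    pd.Series(m.barcodes).to_csv(
        outdir / "barcodes.tsv", sep="\t", index=False, header=False
    )
    if len(m.cell_meta.columns):
        m.cell_meta.to_csv(outdir / "cell_meta.csv")


def read_counts_mtx(indir: str | Path) -> CountMatrix:
    indir = Path(indir)
    counts = sp.csr_matrix(scipy.io.mmread(indir / "matrix.mtx"))
    genes = pd.read_csv(indir / "genes.tsv", sep="\t", header=None)[0].to_numpy(object)
    barcodes = pd.read_csv(indir / "barcodes.tsv", sep="\t", header=None)[0].to_numpy(
        object
    )
    meta_path = indir / "cell_meta.csv"
    meta = (
        pd.read_csv(meta_path, index_col=0) if meta_path.exists() else pd.DataFrame()
    )
    return CountMatrix(counts=counts, gene_ids=genes, barcodes=barcodes, cell_meta=meta)


def write_annotation_csv(ann: GeneAnnotation, path: str | Path) -> None:
    ann.table.to_csv(path)


def read_annotation_csv(path: str | Path) -> GeneAnnotation:
    table = pd.read_csv(path, index_col=0)
    for col in ("is_mito", "is_ribo", "is_excluded_confounder"):
        table[col] = table[col].astype(bool)
    return GeneAnnotation(table)


def write_stack_tiff(stack: ImageStack, path: str | Path) -> None:
    """Multi-page TIFF plus a .json sidecar with the pixel geometry."""
    path = Path(path)
    tifffile.imwrite(path, stack.data.astype(np.float32), photometric="minisblack")
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps(
            {
                "pixel_size_um": list(stack.pixel_size_um),
                "z_step_um": stack.z_step_um,
            }
        )
    )


def read_stack_tiff(path: str | Path) -> ImageStack:
    path = Path(path)
    data = tifffile.imread(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    if not sidecar.exists():
        raise FileNotFoundError(f"missing sidecar metadata {sidecar}")
    meta = json.loads(sidecar.read_text())
    return ImageStack(
        data=data,
        pixel_size_um=tuple(meta["pixel_size_um"]),
        z_step_um=float(meta["z_step_um"]),
    )


def load_config_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a key-value mapping")
    return cfg


def dump_config_yaml(cfg: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
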