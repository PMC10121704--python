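"""Shared fixtures: small simulated datasets reused across test modules."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from gliakit.containers import CountMatrix, GeneAnnotation, NormalizedMatrix
from gliakit.simulate import SimCountConfig, simulate_counts
from gliakit.simulate.counts import _default_subpopulations


@pytest.fixture(scope="session")
def clean_sim():
    """Small clean dataset: no doublets, no ambient; 4 samples x 150 cells."""
    cfg = SimCountConfig(
        n_cells_per_sample=150,
        doublet_rate=0.0,
        ambient_fraction=0.0,
        conditions=("CTRL", "SOD1"),
        ages=("4M",),
        sexes=("female", "male"),
        seed=11,
    )
    return simulate_counts(cfg)


@pytest.fixture(scope="session")
def default_sim():
    """Dataset under the generator defaults (doublets + ambient), 2 samples."""
    cfg = SimCountConfig(
        n_cells_per_sample=400,
        conditions=("CTRL",),
        ages=("1M",),
        sexes=("female", "male"),
        seed=7,
    )
    return simulate_counts(cfg)


@pytest.fixture(scope="session")
def subpop_sim():
    """Three types plus one SOD1-exclusive subpopulation, no other effects."""
    activated = _default_subpopulations()[0]
    cfg = SimCountConfig(
        n_cells_per_sample=800,
        doublet_rate=0.0,
        ambient_fraction=0.0,
        condition_effects=(),
        subpopulations=(activated,),
        conditions=("CTRL", "SOD1"),
        ages=("4M",),
        sexes=("female", "male"),
        seed=13,
    )
    return simulate_counts(cfg)


@pytest.fixture()
def toy_counts():
    """Hand-sized count matrix with known per-cell sums and gene classes."""
    genes = ["Aqp4", "mt-Sim0", "Xist", "Eif2s3y", "Uty", "Gene1", "Gene2"]
    #                c1  c2  c3  c4
    counts = np.array(
        [
            [10, 0, 5, 0],  # Aqp4
            [5, 0, 0, 1],  # mt-Sim0
            [0, 2, 0, 0],  # Xist
            [0, 0, 3, 0],  # Eif2s3y (Y)
            [0, 0, 4, 1],  # Uty (Y)
            [30, 90, 0, 50],  # Gene1
            [5, 8, 88, 48],  # Gene2
        ]
    )
    barcodes = [f"c{i}" for i in range(1, 5)]
    m = CountMatrix(
        counts=sp.csr_matrix(counts), gene_ids=np.array(genes), barcodes=np.array(barcodes)
    )
    ann = GeneAnnotation.from_genes(
        genes, chromosome={"Eif2s3y": "Y", "Uty": "Y", "Xist": "X"}
    )
    return m, ann, counts


def make_norm(values, genes=None, barcodes=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    barcodes = barcodes or [f"c{i}" for i in range(values.shape[1])]
    return NormalizedMatrix(
        values=values, gene_ids=np.array(genes, object), barcodes=np.array(barcodes, object)
    )
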