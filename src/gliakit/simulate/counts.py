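"""Negative-binomial UMI count simulator with planted ground truth.

The generator emulates the structure of a droplet scRNA-seq experiment on
FACS-enriched cortical glia: 16 samples (2 conditions x 4 ages x 2
sexes), three dominant glial cell types with canonical marker genes,
Xist/Y-gene sex structure, a low mitochondrial fraction, ~1-2% ambient
contamination, and a 3.9% doublet formation rate.  Counts are drawn from
a gamma-Poisson (negative binomial) model with a shared dispersion and
lognormal library sizes; every planted label is recorded in
:class:`SimTruth` so recovery can be scored exactly.

Doublets are formed by summing the pre-ambient counts of two emitted
singlets of the same sample (parents recorded), after which ambient
counts — Poisson draws from the dataset-mean expression profile at the
configured fraction of each barcode's library size — are added to every
barcode.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from ..containers import CountMatrix, GeneAnnotation

__all__ = [
    "ConditionEffect",
    "Subpopulation",
    "SimCountConfig",
    "SimTruth",
    "simulate_counts",
]

# canonical cortex glial markers, with the mean fold-elevation planted in
# the owning cell type
DEFAULT_MARKERS: dict[str, dict[str, float]] = {
    "astrocyte": {"Aqp4": 8.0, "Aldh1l1": 8.0, "Gjb6": 8.0},
    "microglia": {"Cx3cr1": 8.0, "Aif1": 8.0},
    "oligodendrocyte": {"Mobp": 8.0, "Apod": 8.0, "Plp1": 8.0, "Cldn11": 8.0},
}

DEFAULT_Y_GENES = ("Eif2s3y", "Uty", "Ddx3y", "Kdm5d")


@dataclass(frozen=True)
class ConditionEffect:
    """A planted expression shift in one cell type of the SOD1 condition."""

    name: str
    cell_type: str
    genes: tuple[str, ...]
    log2_effect: float
    ages: tuple[str, ...]


@dataclass(frozen=True)
class Subpopulation:
    """A planted subtype within a parent cell type.

    ``fraction`` is the share of the parent type's cells recruited into
    the subpopulation; membership may be restricted to particular
    conditions / ages / sexes (None = unrestricted), which is how a
    condition-exclusive cluster is planted.  Besides the named markers,
    ``n_program_genes`` auto-named genes are elevated ``program_fold``-x
    in members, giving the subpopulation a transcriptome-wide identity a
    clustering can find, the way a real cell state differs in many genes.
    """

    name: str
    parent_type: str
    fraction: float
    markers: dict[str, float]
    conditions: tuple[str, ...] | None = None
    ages: tuple[str, ...] | None = None
    sexes: tuple[str, ...] | None = None
    n_program_genes: int = 40
    program_fold: float = 4.0

    def program_genes(self) -> list[str]:
        return [f"{self.name}.prog{i:02d}" for i in range(self.n_program_genes)]

    def allows(self, condition: str, age: str, sex: str) -> bool:
        return (
            (self.conditions is None or condition in self.conditions)
            and (self.ages is None or age in self.ages)
            and (self.sexes is None or sex in self.sexes)
        )


def _default_condition_effects() -> tuple[ConditionEffect, ...]:
    return (
        ConditionEffect(
            name="late_microglia_response",
            cell_type="microglia",
            genes=tuple(f"Deg{i:02d}" for i in range(1, 31)),
            log2_effect=2.0,
            ages=("4M",),
        ),
    )


def _default_subpopulations() -> tuple[Subpopulation, ...]:
    return (
        # disease-associated microglial state present only in SOD1 samples
        Subpopulation(
            name="activated_microglia",
            parent_type="microglia",
            fraction=0.10,
            markers={"Apoe": 6.0, "Cst7": 6.0, "Lpl": 6.0, "Itgax": 6.0},
            conditions=("SOD1",),
        ),
        # stress-response astrocyte cluster confined to 3M CTRL males,
        # marked by Cdkn1a / Fkbp5
        Subpopulation(
            name="stress_astrocyte",
            parent_type="astrocyte",
            fraction=0.08,
            markers={"Cdkn1a": 6.0, "Fkbp5": 6.0, "Dusp1": 6.0},
            conditions=("CTRL",),
            ages=("3M",),
            sexes=("male",),
        ),
    )


@dataclass
class SimCountConfig:
    """Study-shaped defaults for the count simulator.

    The default design is the full study layout: 2 conditions x 4 ages x
    2 sexes, one sample each, three glial types at their observed
    relative abundances, a 3.9% doublet rate and 1.5% ambient fraction.
    """

    n_cells_per_sample: int = 2500
    cell_type_proportions: dict[str, float] = field(
        default_factory=lambda: {
            "astrocyte": 0.28,
            "microglia": 0.42,
            "oligodendrocyte": 0.30,
        }
    )
    n_genes: int = 2000
    marker_table: dict[str, dict[str, float]] = field(
        default_factory=lambda: {t: dict(g) for t, g in DEFAULT_MARKERS.items()}
    )
    xist_gene: str = "Xist"
    y_genes: tuple[str, ...] = DEFAULT_Y_GENES
    condition_effects: tuple[ConditionEffect, ...] = field(
        default_factory=_default_condition_effects
    )
    subpopulations: tuple[Subpopulation, ...] = field(
        default_factory=_default_subpopulations
    )
    conditions: tuple[str, ...] = ("CTRL", "SOD1")
    ages: tuple[str, ...] = ("1M", "2M", "3M", "4M")
    sexes: tuple[str, ...] = ("female", "male")
    doublet_rate: float = 0.039
    ambient_fraction: float = 0.015
    mito_fraction_mean: float = 0.03
    libsize_lognormal: tuple[float, float] = (math.log(5000.0), 0.35)
    nb_dispersion: float = 2.0
    n_mito_genes: int = 10
    n_ribo_genes: int = 20
    # abundance weights on a scale where the median gene is ~1
    xist_weight: float = 15.0
    y_weight: float = 3.0
    marker_background: float = 0.15  # canonical markers outside their type
    effect_gene_baseline: float = 2.0  # condition-effect genes before the shift
    # each type's broad expression program: many modestly elevated genes
    n_program_genes_per_type: int = 100
    program_fold: float = 4.0
    program_baseline: float = 0.75
    seed: int = 0

    def type_program_genes(self, cell_type: str) -> list[str]:
        return [
            f"{cell_type}.prog{i:03d}" for i in range(self.n_program_genes_per_type)
        ]

    def validate(self) -> None:
        total = sum(self.cell_type_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"cell type proportions sum to {total}, not 1")
        for name, frac in [
            ("doublet_rate", self.doublet_rate),
            ("ambient_fraction", self.ambient_fraction),
            ("mito_fraction_mean", self.mito_fraction_mean),
        ]:
            if not 0 <= frac < 1:
                raise ValueError(f"{name} must lie in [0, 1)")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        named = self.named_genes()
        if self.n_genes < len(named):
            raise ValueError(
                f"n_genes={self.n_genes} below the {len(named)} named genes"
            )
        for ctype in self.marker_table:
            if ctype not in self.cell_type_proportions:
                raise ValueError(f"marker table names unknown type {ctype!r}")

    def named_genes(self) -> list[str]:
        names: list[str] = []
        for ctype, table in self.marker_table.items():
            names.extend(table)
            names.extend(self.type_program_genes(ctype))
        names.append(self.xist_gene)
        names.extend(self.y_genes)
        for eff in self.condition_effects:
            names.extend(eff.genes)
        for sub in self.subpopulations:
            names.extend(sub.markers)
            names.extend(sub.program_genes())
        names.extend(f"mt-Sim{i}" for i in range(self.n_mito_genes))
        names.extend(f"Rps-sim{i}" for i in range(self.n_ribo_genes))
        seen: dict[str, None] = {}
        for n in names:
            seen.setdefault(n)
        return list(seen)


@dataclass
class SimTruth:
    """Planted labels per emitted barcode plus gene-level bookkeeping.

    ``cells`` holds one row per barcode: sample, condition, age, true sex,
    cell_type (``a+b`` for doublets), subpopulation, is_doublet and the
    parent barcodes of doublets.  ``de_genes`` maps each planted
    condition effect to its gene list; ``annotation`` is the matching
    :class:`GeneAnnotation`.
    """

    cells: pd.DataFrame
    de_genes: dict[str, list[str]]
    subpop_markers: dict[str, list[str]]
    annotation: GeneAnnotation


def _build_universe(config: SimCountConfig) -> tuple[list[str], GeneAnnotation]:
    named = config.named_genes()
    n_filler = config.n_genes - len(named)
    genes = named + [f"Gene{i:05d}" for i in range(n_filler)]
    chromosome = {g: "Y" for g in config.y_genes}
    chromosome[config.xist_gene] = "X"
    ann = GeneAnnotation.from_genes(genes, chromosome=chromosome)
    return genes, ann


def _base_abundance(config: SimCountConfig, rng: np.random.Generator, genes) -> np.ndarray:
    """Relative abundance per gene before type/sex/condition scaling.

    Filler genes draw lognormal abundances (median 1); genes with a
    planted role get controlled baselines so their detectability does
    not depend on the lognormal draw: canonical markers and subpopulation
    markers sit at a low background outside their owners, type/subpop
    program genes at ``program_baseline``, condition-effect genes at
    ``effect_gene_baseline``.  Mitochondrial genes are rescaled so their
    expected share of a cell's counts equals ``mito_fraction_mean``;
    Xist and Y genes start at zero and are set per sex.
    """
    a = rng.lognormal(mean=0.0, sigma=1.0, size=len(genes))
    idx = {g: i for i, g in enumerate(genes)}
    for ctype, table in config.marker_table.items():
        for gene in table:
            a[idx[gene]] = config.marker_background
        for gene in config.type_program_genes(ctype):
            a[idx[gene]] = config.program_baseline
    for sub in config.subpopulations:
        for gene in sub.markers:
            a[idx[gene]] = config.marker_background * 2
        for gene in sub.program_genes():
            a[idx[gene]] = config.program_baseline
    for eff in config.condition_effects:
        for gene in eff.genes:
            a[idx[gene]] = config.effect_gene_baseline
    sexed = [idx[config.xist_gene]] + [idx[g] for g in config.y_genes]
    a[sexed] = 0.0
    mito = [i for i, g in enumerate(genes) if g.startswith("mt-")]
    non_mito = np.setdiff1d(np.arange(len(genes)), np.array(mito))
    target = config.mito_fraction_mean
    a[mito] = a[mito] / a[mito].sum() * (target / (1 - target)) * a[non_mito].sum()
    return a


def _group_profile(
    base: np.ndarray,
    idx: dict[str, int],
    config: SimCountConfig,
    cell_type: str,
    subpop: str | None,
    condition: str,
    age: str,
    sex: str,
) -> np.ndarray:
    a = base.copy()
    for gene, fold in config.marker_table.get(cell_type, {}).items():
        a[idx[gene]] = fold  # absolute weight: markers are reliably detected
    for gene in config.type_program_genes(cell_type):
        a[idx[gene]] *= config.program_fold
    if subpop is not None:
        sub = next(s for s in config.subpopulations if s.name == subpop)
        for gene, fold in sub.markers.items():
            a[idx[gene]] = fold
        for gene in sub.program_genes():
            a[idx[gene]] *= sub.program_fold
    if condition == "SOD1":
        for eff in config.condition_effects:
            if eff.cell_type == cell_type and age in eff.ages:
                for gene in eff.genes:
                    a[idx[gene]] *= 2.0 ** eff.log2_effect
    if sex == "female":
        a[idx[config.xist_gene]] = config.xist_weight
    else:
        for gene in config.y_genes:
            a[idx[gene]] = config.y_weight
    return a / a.sum()


def _nb_draw(
    rng: np.random.Generator, mu: np.ndarray, theta: float
) -> np.ndarray:
    """Gamma-Poisson draw: var = mu + mu^2 / theta, elementwise."""
    lam = rng.gamma(shape=theta, scale=mu / theta)
    return rng.poisson(lam)


def simulate_counts(config: SimCountConfig) -> tuple[CountMatrix, SimTruth]:
    """Generate a UMI count matrix and its planted truth.

    Per sample (one per condition x age x sex cell), each barcode is a
    doublet with probability ``doublet_rate``; singlets draw a cell type
    from the configured proportions (optionally upgraded into a planted
    subpopulation), a lognormal library size, and negative-binomial
    counts from the group's expression profile scaled to
    ``(1 - ambient_fraction)`` of the library.  Doublets copy the summed
    pre-ambient counts of two singlet parents.  Ambient Poisson counts
    from the dataset-mean profile are then added to every barcode.
    Identical seeds reproduce the output bit-exactly.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes, ann = _build_universe(config)
    idx = {g: i for i, g in enumerate(genes)}
    base = _base_abundance(config, rng, genes)

    types = list(config.cell_type_proportions)
    props = np.array([config.cell_type_proportions[t] for t in types])
    mu_lib, sd_lib = config.libsize_lognormal
    amb = config.ambient_fraction

    samples = [
        (cond, age, sex)
        for cond in config.conditions
        for age in config.ages
        for sex in config.sexes
    ]

    profile_cache: dict[tuple, np.ndarray] = {}

    def profile(ct: str, sub: str | None, cond: str, age: str, sex: str) -> np.ndarray:
        key = (ct, sub, cond, age, sex)
        if key not in profile_cache:
            profile_cache[key] = _group_profile(
                base, idx, config, ct, sub, cond, age, sex
            )
        return profile_cache[key]

    columns: list[np.ndarray] = []
    rows: list[dict] = []
    mean_profile_acc = np.zeros(len(genes))
    n_singlets_total = 0

    for cond, age, sex in samples:
        sample_id = f"{cond}_{age}_{sex}"
        n = config.n_cells_per_sample
        is_doublet = rng.random(n) < config.doublet_rate

        # assign type / subpopulation per barcode (doublets get two draws)
        def draw_identity():
            ct = types[rng.choice(len(types), p=props)]
            sub = None
            for s in config.subpopulations:
                if s.parent_type == ct and s.allows(cond, age, sex):
                    if rng.random() < s.fraction:
                        sub = s.name
                    break
            return ct, sub

        singlet_positions = np.flatnonzero(~is_doublet)
        doublet_positions = np.flatnonzero(is_doublet)
        if len(singlet_positions) < 2 and len(doublet_positions) > 0:
            raise ValueError("too few singlets in sample to form doublets")

        sample_cols: dict[int, np.ndarray] = {}
        sample_meta: dict[int, dict] = {}
        for pos in singlet_positions:
            ct, sub = draw_identity()
            p = profile(ct, sub, cond, age, sex)
            lib = rng.lognormal(mu_lib, sd_lib)
            own = _nb_draw(rng, lib * (1 - amb) * p, config.nb_dispersion)
            sample_cols[pos] = own
            sample_meta[pos] = {
                "cell_type": ct,
                "subpop": sub if sub is not None else "none",
                "library_size": lib,
            }
            mean_profile_acc += p
            n_singlets_total += 1

        for pos in doublet_positions:
            pa, pb = rng.choice(singlet_positions, size=2, replace=False)
            own = sample_cols[pa] + sample_cols[pb]
            sample_cols[pos] = own
            ta, tb = sample_meta[pa]["cell_type"], sample_meta[pb]["cell_type"]
            sample_meta[pos] = {
                "cell_type": f"{ta}+{tb}",
                "subpop": "none",
                "library_size": sample_meta[pa]["library_size"]
                + sample_meta[pb]["library_size"],
                "parents": (pa, pb),
            }

        for pos in range(n):
            barcode = f"{sample_id}-{pos:05d}"
            meta = sample_meta[pos]
            rows.append(
                {
                    "barcode": barcode,
                    "sample": sample_id,
                    "condition": cond,
                    "age": age,
                    "sex": sex,
                    "cell_type": meta["cell_type"],
                    "subpop": meta["subpop"],
                    "is_doublet": bool(is_doublet[pos]),
                    "library_size": meta["library_size"],
                    "parent_a": (
                        f"{sample_id}-{meta['parents'][0]:05d}"
                        if "parents" in meta
                        else ""
                    ),
                    "parent_b": (
                        f"{sample_id}-{meta['parents'][1]:05d}"
                        if "parents" in meta
                        else ""
                    ),
                }
            )
            columns.append(sample_cols[pos])

    matrix = np.stack(columns, axis=1)  # genes x cells, pre-ambient

    if amb > 0 and n_singlets_total > 0:
        p_ambient = mean_profile_acc / n_singlets_total
        libs = np.array([r["library_size"] for r in rows])
        ambient = rng.poisson(amb * np.outer(p_ambient, libs))
        matrix = matrix + ambient

    truth_cells = pd.DataFrame(rows).set_index("barcode")
    barcodes = np.array(truth_cells.index, dtype=object)
    cm = CountMatrix(
        counts=sp.csr_matrix(matrix.astype(np.int64)),
        gene_ids=np.array(genes, dtype=object),
        barcodes=barcodes,
        cell_meta=truth_cells[["sample", "condition", "age", "sex"]].copy(),
    )
    truth = SimTruth(
        cells=truth_cells,
        de_genes={e.name: list(e.genes) for e in config.condition_effects},
        subpop_markers={s.name: list(s.markers) for s in config.subpopulations},
        annotation=ann,
    )
    return cm, truth
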