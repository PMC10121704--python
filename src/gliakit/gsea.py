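"""Preranked gene-set enrichment analysis.

The enrichment score is the classic weighted Kolmogorov-Smirnov running
sum: walking down the ranked list, hits increment by ``|r_j|^p``
(normalized over hits) and misses by ``1/(N - N_H)``; the ES is the
signed maximum deviation, and the leading edge ("core enrichment") is
the hit genes at or before (after, for negative ES) the extremum.  The
null is gene-label permutation: hit positions are redrawn uniformly,
which for a fixed ranking depends only on the set size, so permutations
are shared across equal-sized sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "RankedList",
    "rank_genes",
    "enrichment_score",
    "gsea_preranked",
    "read_gmt",
    "write_gmt",
]


@dataclass
class RankedList:
    """Genes ordered by a ranking metric, descending; ties broken by name."""

    genes: np.ndarray
    metric: np.ndarray
    n_dropped_nan: int = 0
    degenerate_ties: bool = False
    _pos: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.genes = np.asarray(self.genes, dtype=object)
        self.metric = np.asarray(self.metric, dtype=float)
        if len(self.genes) != len(self.metric):
            raise ValueError("genes and metric length mismatch")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate genes in ranked list")
        self._pos = {g: i for i, g in enumerate(self.genes)}

    def __len__(self) -> int:
        return len(self.genes)

    def positions(self, gene_set) -> np.ndarray:
        """Sorted rank positions of the set members present in the list."""
        hits = sorted(self._pos[g] for g in set(gene_set) if g in self._pos)
        return np.asarray(hits, dtype=int)


def rank_genes(de: pd.DataFrame, metric: str = "log2FC") -> RankedList:
    """Build a ranked list from a DE table (columns ``gene`` and ``metric``).

    Rows with a non-finite metric are dropped (counted, warned).  Order is
    descending in the metric with exact ties broken by gene name, so the
    list — and hence every ES computed from it — is deterministic.
    """
    if len(de) == 0:
        raise ValueError("empty DE table")
    vals = de[metric].to_numpy(dtype=float)
    finite = np.isfinite(vals)
    n_dropped = int((~finite).sum())
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} genes with non-finite {metric}")
    genes = de["gene"].to_numpy(dtype=object)[finite]
    vals = vals[finite]
    order = np.lexsort((genes, -vals))
    degenerate = bool(len(vals) > 1 and np.all(vals == vals[0]))
    return RankedList(
        genes=genes[order],
        metric=vals[order],
        n_dropped_nan=n_dropped,
        degenerate_ties=degenerate,
    )


def _es_candidates(w: np.ndarray, hits: np.ndarray, n: int):
    """Running-sum deviation candidates at / just before each hit.

    ``w`` are the |metric|^p weights along the full list, ``hits`` the
    sorted hit positions.  Returns (before, after, denom-handled cum).
    Positions between hits never host the extremum except immediately
    before a hit, so these 2k candidates suffice.
    """
    k = len(hits)
    wh = w[hits]
    s = wh.sum()
    if s > 0:
        cum = np.cumsum(wh) / s
    else:  # all-zero weights: fall back to unweighted increments
        cum = np.arange(1, k + 1) / k
    miss = (hits - np.arange(k)) / (n - k)
    after = cum - miss
    before = np.concatenate(([0.0], cum[:-1])) - miss
    return before, after


def enrichment_score(
    ranked: RankedList, gene_set, weight: float = 1.0
) -> tuple[float, np.ndarray, list[str]]:
    """Weighted KS enrichment score of ``gene_set`` in ``ranked``.

    Returns ``(ES, running_sum, leading_edge)`` where ``running_sum`` is
    the full deviation profile over the list (for enrichment-curve plots)
    and ``leading_edge`` the hit genes driving the extremum.
    """
    n = len(ranked)
    hits = ranked.positions(gene_set)
    if len(hits) == 0:
        raise ValueError("gene set does not intersect the ranked universe")
    if len(hits) == n:
        raise ValueError("gene set covers the entire universe; ES undefined")

    w = np.abs(ranked.metric) ** weight
    before, after = _es_candidates(w, hits, n)
    i_max = int(np.argmax(after))
    i_min = int(np.argmin(before))
    es = float(after[i_max]) if after[i_max] >= -before[i_min] else float(before[i_min])

    if es >= 0:
        leading = [str(g) for g in ranked.genes[hits[: i_max + 1]]]
    else:
        leading = [str(g) for g in ranked.genes[hits[i_min:]]]

    # full running sum, for plotting and oracle comparison
    k = len(hits)
    step = np.full(n, -1.0 / (n - k))
    wh = w[hits]
    s = wh.sum()
    step[hits] = wh / s if s > 0 else 1.0 / k
    running = np.cumsum(step)
    return es, running, leading


def _null_es(
    w: np.ndarray, n: int, k: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Gene-permutation null ES for a set of size ``k``: vectorized."""
    pos = np.argpartition(rng.random((n_perm, n)), k - 1, axis=1)[:, :k]
    pos.sort(axis=1)
    wh = w[pos]
    s = wh.sum(axis=1, keepdims=True)
    safe = np.where(s > 0, s, 1.0)
    cum = np.cumsum(wh, axis=1) / safe
    cum = np.where(s > 0, cum, np.arange(1, k + 1) / k)
    miss = (pos - np.arange(k)[None, :]) / (n - k)
    after = cum - miss
    before = np.concatenate((np.zeros((n_perm, 1)), cum[:, :-1]), axis=1) - miss
    hi = after.max(axis=1)
    lo = before.min(axis=1)
    return np.where(hi >= -lo, hi, lo)


def gsea_preranked(
    ranked: RankedList,
    sets: dict[str, list[str]],
    min_size: int = 10,
    max_size: int = 800,
    n_perm: int = 1000,
    seed: int = 0,
    weight: float = 1.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Preranked GSEA over a gene-set collection.

    Sets are intersected with the ranked universe and kept if the
    intersection size lies in ``[min_size, max_size]``.  Per set:
    permutation p-value ``(1 + #{same-sign null at least as extreme}) /
    (1 + #same-sign nulls)``, NES = ES / mean(|same-sign null ES|), BH
    adjustment across retained sets, and a ``relevant`` flag requiring
    ``p_adj < alpha`` and a leading edge of more than one gene.
    """
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is low; p-value resolution is coarse")
    rng = np.random.default_rng(seed)
    n = len(ranked)
    w = np.abs(ranked.metric) ** weight

    retained: list[tuple[str, int, float, list[str]]] = []
    for name in sorted(sets):
        hits = ranked.positions(sets[name])
        k = len(hits)
        if k < min_size or k > max_size or k == n:
            continue
        es, _, leading = enrichment_score(ranked, sets[name], weight)
        retained.append((name, k, es, leading))
    if not retained:
        raise ValueError("no gene set passes the size filter")

    null_cache: dict[int, np.ndarray] = {}
    rows = []
    for name, k, es, leading in retained:
        if k not in null_cache:
            null_cache[k] = _null_es(w, n, k, n_perm, rng)
        null = null_cache[k]
        same_sign = null * np.sign(es) > 0 if es != 0 else np.zeros(len(null), bool)
        n_same = int(same_sign.sum())
        if n_same == 0:
            p = 1.0 / (1 + n_perm)
            nes = float("nan")
            flagged = True
        else:
            p = (1 + int((np.abs(null[same_sign]) >= abs(es)).sum())) / (1 + n_same)
            nes = es / np.abs(null[same_sign]).mean()
            flagged = False
        rows.append(
            {
                "set": name,
                "set_size_used": k,
                "ES": es,
                "NES": nes,
                "p": p,
                "leading_edge": leading,
                "no_same_sign_null": flagged,
            }
        )
    out = pd.DataFrame(rows)
    out["p_adj"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    out["relevant"] = (out["p_adj"] < alpha) & (out["leading_edge"].str.len() > 1)
    return out.sort_values("p_adj", kind="stable", ignore_index=True)


def read_gmt(path) -> dict[str, list[str]]:
    """Read a GMT gene-set file (name, description, genes...)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            if parts[0] in sets:
                raise ValueError(f"duplicate gene set name {parts[0]!r}")
            genes = [g for g in parts[2:] if g]
            if not genes:
                raise ValueError(f"empty gene set {parts[0]!r}")
            sets[parts[0]] = genes
    if not sets:
        raise ValueError(f"no gene sets in {path}")
    return sets


def write_gmt(sets: dict[str, list[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")
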