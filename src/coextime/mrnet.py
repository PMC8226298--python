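"""Mutual-rank co-expression networks.

For each gene the Pearson correlations to all other genes are converted
into ranks (rank 1 = best partner); the mutual rank of a pair is the
geometric mean of the two reciprocal ranks,
``MR(a,b) = sqrt(rank_a->b * rank_b->a)``, a symmetric co-expression
distance that is robust to the overall correlation level of a gene.
MR is mapped onto edge weights by the exponential decay
``N_x = exp(-(MR - 1)/x)`` with decay constants ``x = 5, 10, 25, 50, 100``
(network levels N1..N5); only edges with ``N_x >= 0.01`` are kept, which
caps the admitted MR at ``1 + x*ln(100)``.  Because the weight is
monotone in MR, the per-level edge sets are nested N1 ⊆ N2 ⊆ ... ⊆ N5.

The *co* direction ranks descending correlation (strongest positive
partner first); the *anti* direction ranks ascending correlation, so the
most anti-correlated partner takes rank 1.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .correlation import CorrelationMatrix

log = logging.getLogger(__name__)

DEFAULT_DECAYS = (5, 10, 25, 50, 100)
DEFAULT_THRESHOLD = 0.01


@dataclass
class RankMatrix:
    """Directed neighbor ranks: ``values[i, j]`` is the rank of gene j in
    gene i's partner list (mid-ranks for ties; self-pairs excluded by
    default, giving each row ranks 1..G-1)."""

    values: np.ndarray
    genes: pd.Index
    direction: str  # 'co' | 'anti'
    include_self: bool = False

    def __post_init__(self) -> None:
        if self.direction not in ("co", "anti"):
            raise ValueError("direction must be 'co' or 'anti'")


def rank_matrix(corr: CorrelationMatrix, direction: str = "co",
                include_self: bool = False) -> RankMatrix:
    """Rank every gene's partners by correlation.

    ``co`` ranks over ``-r`` ascending (rank 1 = highest correlation);
    ``anti`` ranks over ``+r`` ascending (rank 1 = most negative
    correlation).  By default the diagonal is excluded before ranking so a
    reciprocal best pair attains MR = 1; ``include_self=True`` instead
    ranks the full row including the self-pair, shifting co ranks by one.
    """
    if corr.axis != "gene":
        raise ValueError("mutual ranks are defined on gene-axis correlations")
    arr = corr.values.to_numpy(dtype=float)
    if not np.isfinite(arr).all():
        raise ValueError("correlation matrix has non-finite entries")
    key = -arr if direction == "co" else arr.copy()
    if not include_self:
        # push self-pairs to the end of each row's order, then void them
        np.fill_diagonal(key, np.inf)
    ranks = rankdata(key, axis=1, method="average")
    if not include_self:
        np.fill_diagonal(ranks, np.nan)
    return RankMatrix(values=ranks, genes=corr.ids, direction=direction,
                      include_self=include_self)


def mutual_rank(ranks: RankMatrix) -> pd.DataFrame:
    """``MR = sqrt(R * R^T)`` elementwise — the transpose pairs each directed
    rank with its reciprocal.  Diagonal is NaN when self-pairs are excluded."""
    r = ranks.values
    if r.shape[0] != r.shape[1]:
        raise ValueError("rank matrix must be square")
    mr = np.sqrt(r * r.T)
    return pd.DataFrame(mr, index=ranks.genes, columns=ranks.genes)


def mr_admission_cutoff(decay: float, threshold: float = DEFAULT_THRESHOLD) -> float:
    """Largest MR admitted at a decay: ``N_x >= t  <=>  MR <= 1 + x*ln(1/t)``."""
    return 1.0 + decay * math.log(1.0 / threshold)


@dataclass
class MRNetwork:
    """Decay-weighted, thresholded edge lists per network level.

    ``levels`` maps level name (N1..N5 in ascending decay order) to an
    edge DataFrame with columns ``source``, ``target``, ``weight``
    (undirected, each pair stored once with source < target).
    """

    genes: pd.Index
    direction: str
    decays: tuple[float, ...]
    threshold: float
    levels: dict[str, pd.DataFrame]
    _graphs: dict[str, nx.Graph] = field(default_factory=dict, repr=False)

    def level_names(self) -> list[str]:
        return list(self.levels)

    def decay_of(self, level: str) -> float:
        return self.decays[self.level_names().index(level)]

    def graph(self, level: str) -> nx.Graph:
        """Weighted undirected graph for a level (all genes as nodes)."""
        if level not in self._graphs:
            g = nx.Graph()
            g.add_nodes_from(self.genes)
            edges = self.levels[level]
            g.add_weighted_edges_from(
                zip(edges["source"], edges["target"], edges["weight"])
            )
            self._graphs[level] = g
        return self._graphs[level]


def build_networks(
    mr: pd.DataFrame,
    decays: tuple[float, ...] = DEFAULT_DECAYS,
    threshold: float = DEFAULT_THRESHOLD,
    direction: str = "co",
) -> MRNetwork:
    """Threshold the MR matrix into one weighted edge list per decay."""
    if any(d <= 0 for d in decays):
        raise ValueError("decay constants must be > 0")
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    decays = tuple(sorted(decays))
    genes = mr.index
    arr = mr.to_numpy(dtype=float)
    iu = np.triu_indices(arr.shape[0], k=1)
    mr_vals = arr[iu]
    levels: dict[str, pd.DataFrame] = {}
    for k, x in enumerate(decays, start=1):
        cutoff = mr_admission_cutoff(x, threshold)
        keep = np.flatnonzero(mr_vals <= cutoff)
        w = np.exp(-(mr_vals[keep] - 1.0) / x)
        levels[f"N{k}"] = pd.DataFrame(
            {
                "source": genes[iu[0][keep]],
                "target": genes[iu[1][keep]],
                "weight": w,
            }
        )
    return MRNetwork(genes=genes, direction=direction, decays=decays,
                     threshold=threshold, levels=levels)


@dataclass
class Cohort:
    """Neighbors of a seed gene (or the union over a bait list) at one
    network level.  The seed-centric graph (edges only seed -> members)
    is a star, hence has clustering coefficient zero by construction."""

    seeds: tuple[str, ...]
    members: tuple[str, ...]          # sorted by descending weight, then id
    weights: tuple[float, ...]        # per-member max weight to any seed
    level: str
    direction: str
    baits_missing: tuple[str, ...] = ()

    def __len__(self) -> int:
        return len(self.members)

    def member_set(self) -> frozenset[str]:
        return frozenset(self.members)


def gene_cohort(network: MRNetwork, gene: str, level: str) -> Cohort:
    """All neighbors of ``gene`` at ``level``, sorted by descending weight."""
    if gene not in set(network.genes):
        raise KeyError(f"unknown gene id {gene!r}")
    g = network.graph(level)
    nbrs = [(n, g[gene][n]["weight"]) for n in g.neighbors(gene)]
    nbrs.sort(key=lambda t: (-t[1], t[0]))
    return Cohort(
        seeds=(gene,),
        members=tuple(n for n, _ in nbrs),
        weights=tuple(w for _, w in nbrs),
        level=level,
        direction=network.direction,
    )


def export_network(network: MRNetwork, level: str, path: str | Path) -> None:
    """Write a level's edges as a three-column TSV (source, target, weight),
    one row per undirected edge, in deterministic lexicographic order.
    The format loads directly into standard network viewers."""
    edges = network.levels[level]
    s = edges["source"].astype(str).to_numpy()
    t = edges["target"].astype(str).to_numpy()
    swap = s > t
    out = pd.DataFrame(
        {
            "source": np.where(swap, t, s),
            "target": np.where(swap, s, t),
            "weight": edges["weight"].to_numpy(),
        }
    )
    out = out.sort_values(["source", "target"], kind="stable")
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_edge_list(path: str | Path) -> pd.DataFrame:
    """Read a three-column edge TSV as written by :func:`export_network`."""
    df = pd.read_csv(path, sep="\t")
    expected = ["source", "target", "weight"]
    if list(df.columns) != expected:
        raise ValueError(f"edge list needs columns {expected}")
    return df
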