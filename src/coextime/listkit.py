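"""Gene-list utilities on top of the mutual-rank networks.

Given a curated bait list, :func:`bait_cohort` collects the union of the
baits' co-expression cohorts at a network level — the guilt-by-association
candidate set for the pathway the baits represent.  Companion helpers
compute exact 2/3-way overlap (Venn) counts, count within-list partners
above PCC cutoffs, and verify that cohorts from nested network levels are
themselves nested.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .correlation import CorrelationMatrix
from .mrnet import Cohort, MRNetwork, gene_cohort

log = logging.getLogger(__name__)


def bait_cohort(network: MRNetwork, gene_list, level: str) -> Cohort:
    """Union of the cohorts of every bait gene at a network level.

    Baits themselves are excluded from the member list (reported counts
    exclude baits); baits absent from the network are reported, not
    silently dropped.  Each member carries its maximum edge weight to any
    bait, and members are sorted by descending weight then id.
    """
    baits = [str(g) for g in gene_list]
    if not baits:
        raise ValueError("empty bait list")
    known = set(map(str, network.genes))
    present = [g for g in baits if g in known]
    missing = tuple(g for g in baits if g not in known)
    if missing:
        log.warning("bait_cohort: %d bait(s) absent from the network: %s",
                    len(missing), list(missing)[:5])
    if not present:
        warnings.warn("no bait present in the network; empty cohort")
        return Cohort(seeds=tuple(baits), members=(), weights=(), level=level,
                      direction=network.direction, baits_missing=missing)
    bait_set = set(present)
    weight: dict[str, float] = {}
    for b in present:
        c = gene_cohort(network, b, level)
        for m, w in zip(c.members, c.weights):
            if m in bait_set:
                continue
            if m not in weight or w > weight[m]:
                weight[m] = w
    order = sorted(weight, key=lambda m: (-weight[m], m))
    return Cohort(
        seeds=tuple(baits),
        members=tuple(order),
        weights=tuple(weight[m] for m in order),
        level=level,
        direction=network.direction,
        baits_missing=missing,
    )


@dataclass
class OverlapReport:
    """Exact region cardinalities and memberships for 2–3 gene lists.

    Regions are keyed by the frozenset of list names whose exclusive
    intersection they represent; cardinalities sum to the union size.
    """

    names: tuple[str, ...]
    regions: dict[frozenset, tuple[str, ...]]

    def cardinalities(self) -> dict[frozenset, int]:
        return {k: len(v) for k, v in self.regions.items()}

    @property
    def union_size(self) -> int:
        return sum(len(v) for v in self.regions.values())

    def to_json_dict(self) -> dict:
        return {
            "names": list(self.names),
            "regions": {
                "&".join(sorted(k)): sorted(v) for k, v in self.regions.items()
            },
        }


def list_overlap(lists: dict[str, list] | None = None, **named_lists) -> OverlapReport:
    """Exclusive-region overlap of 2 or 3 named gene lists."""
    lists = dict(lists or {}, **named_lists)
    if not 2 <= len(lists) <= 3:
        raise ValueError("list_overlap supports 2 or 3 lists")
    sets = {name: set(map(str, members)) for name, members in lists.items()}
    names = tuple(sets)
    regions: dict[frozenset, tuple[str, ...]] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set.intersection(*(sets[n] for n in combo))
            outside = set.union(set(), *(sets[n] for n in names if n not in combo))
            members = inside - outside
            regions[frozenset(combo)] = tuple(sorted(members))
    return OverlapReport(names=names, regions=regions)


def pcc_subset(
    corr: CorrelationMatrix,
    gene_list,
    cutoffs: tuple[float, ...] = (0.25, 0.4, 0.5),
) -> pd.DataFrame:
    """Count, per list member, how many within-list partners exceed each
    PCC cutoff (self-pairs excluded).

    The caller partitions genes into co-expressed subsets from these
    counts with :func:`partition_by_counts`; the count thresholds that
    define "high/medium/low" co-expression are analysis choices, not
    fixed constants.
    """
    genes = [str(g) for g in gene_list]
    if len(genes) < 2:
        raise ValueError("need at least 2 genes to count within-list partners")
    missing = [g for g in genes if g not in corr.values.index]
    if missing:
        raise KeyError(f"genes absent from the correlation matrix: {missing[:5]}")
    sub = corr.values.loc[genes, genes].to_numpy(dtype=float)
    np.fill_diagonal(sub, -np.inf)  # exclude self-pairs from every count
    out = {c: (sub > c).sum(axis=1) for c in cutoffs}
    return pd.DataFrame(out, index=pd.Index(genes, name="gene"))


def partition_by_counts(
    counts: pd.Series, thresholds: dict[str, int]
) -> dict[str, list[str]]:
    """Partition genes by descending count thresholds, e.g.
    ``{"high": 10, "medium": 5, "low": 0}`` (first threshold met wins)."""
    items = sorted(thresholds.items(), key=lambda kv: -kv[1])
    out: dict[str, list[str]] = {name: [] for name, _ in items}
    for gene, c in counts.items():
        for name, t in items:
            if c >= t:
                out[name].append(str(gene))
                break
    return out


@dataclass
class NestednessReport:
    """Whether cohorts from increasing network levels form an inclusion chain."""

    nested: bool
    violations: dict[tuple[str, str], tuple[str, ...]]  # (inner, outer) -> offending genes


def nestedness_check(cohorts: list[Cohort]) -> NestednessReport:
    """Verify member-set inclusion along a list of cohorts (e.g. N1..N3)."""
    violations: dict[tuple[str, str], tuple[str, ...]] = {}
    for inner, outer in zip(cohorts, cohorts[1:]):
        extra = inner.member_set() - outer.member_set()
        if extra:
            violations[(inner.level, outer.level)] = tuple(sorted(extra))
    return NestednessReport(nested=not violations, violations=violations)
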