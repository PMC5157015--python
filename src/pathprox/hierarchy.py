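"""Regulatory-hierarchy levels in directed pathway graphs.

A synthetic root is connected to every zero-in-degree node of the pathway's
directed graph, and each gene's level is the shortest path length (SPL) in
edges from that root (root children sit at SPL 1).  Cycles are permitted;
nodes unreachable from the root (e.g. inside a source-less cycle) are
flagged unassigned.  Lower SPL means a higher regulatory level.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np
from scipy import stats

from .types import Pathway

logger = logging.getLogger(__name__)

_ROOT = "__synthetic_root__"

# SPL at or below this value counts as the top of the hierarchy in the
# two-by-two comparison; configurable because the root convention shifts
# every level by one
DEFAULT_TOP_LEVEL = 2


@dataclass
class HierarchyAssignment:
    pathway_id: str
    spl: dict[str, int]  # finite shortest path lengths from the synthetic root
    unreachable: set[str]
    root_children: set[str]  # zero in-degree nodes


def assign_spl(
    edges: Iterable[tuple[str, str]],
    genes: Iterable[str],
    pathway_id: str = "",
) -> HierarchyAssignment:
    """Breadth-first SPL from a synthetic root added above all zero-in-degree nodes."""
    graph = nx.DiGraph()
    graph.add_nodes_from(genes)
    for s, t in edges:
        if s not in graph or t not in graph:
            raise ValueError(f"edge ({s}, {t}) references a gene outside the pathway")
        graph.add_edge(s, t)

    roots = {n for n in graph.nodes if graph.in_degree(n) == 0}
    if not roots:
        logger.warning("assign_spl(%s): no zero-in-degree node; all genes unreachable",
                       pathway_id or "<anonymous>")
        return HierarchyAssignment(pathway_id, {}, set(graph.nodes), set())

    graph.add_node(_ROOT)
    for r in roots:
        graph.add_edge(_ROOT, r)
    lengths = nx.single_source_shortest_path_length(graph, _ROOT)
    spl = {n: d for n, d in lengths.items() if n != _ROOT}
    unreachable = set(graph.nodes) - set(spl) - {_ROOT}
    return HierarchyAssignment(pathway_id, spl, unreachable, roots)


def assign_spl_for_pathway(pathway: Pathway) -> HierarchyAssignment:
    if pathway.directed_edges is None:
        raise ValueError(f"pathway {pathway.pathway_id!r} has no directed edges")
    return assign_spl(pathway.directed_edges, pathway.genes, pathway.pathway_id)


@dataclass
class HierarchyComparison:
    """Proximal vs other pathway genes, pooled over pathways.

    ``ranksum_p`` tests whether proximal genes sit at lower SPL (higher
    level); the 2x2 test splits genes at the top-level threshold
    (SPL <= threshold vs deeper) with the odds ratio as the cross product.
    """

    n_proximal: int
    n_other: int
    ranksum_stat: float
    ranksum_p: float
    table: tuple[tuple[int, int], tuple[int, int]]  # rows proximal/other, cols top/lower
    odds_ratio: float
    table_p: float
    table_test: str  # "chi-square" or "fisher-exact"
    threshold: int
    skipped: bool = False
    note: str = ""


def compare_hierarchy(
    assignments: Sequence[HierarchyAssignment],
    proximal_by_pathway: Mapping[str, set[str]],
    threshold: int = DEFAULT_TOP_LEVEL,
) -> HierarchyComparison:
    """Compare SPL of proximal-intra-pathway genes with the remaining pathway
    genes, pooled over all (pathway, gene) occurrences.

    Genes in several pathways are counted once per pathway; the duplicate
    rate is logged.  The rank-sum alternative is that proximal genes have
    LOWER SPL.  The 2x2 test uses chi-square without continuity correction,
    or Fisher's exact test when any expected cell count is below 5.
    """
    prox_spl: list[int] = []
    other_spl: list[int] = []
    seen_genes: set[str] = set()
    n_occurrences = 0
    for a in assignments:
        proximal = proximal_by_pathway.get(a.pathway_id, set())
        for gene, level in a.spl.items():
            n_occurrences += 1
            (prox_spl if gene in proximal else other_spl).append(level)
        seen_genes.update(a.spl)
    if n_occurrences:
        dup_rate = 1 - len(seen_genes) / n_occurrences
        logger.info("compare_hierarchy: %d occurrences, duplicate rate %.1f%%",
                    n_occurrences, 100 * dup_rate)

    if not prox_spl or not other_spl:
        return HierarchyComparison(
            len(prox_spl), len(other_spl), math.nan, math.nan,
            ((0, 0), (0, 0)), math.nan, math.nan, "none", threshold,
            skipped=True, note="one side empty",
        )

    stat, p = stats.mannwhitneyu(prox_spl, other_spl, alternative="less")

    a = sum(1 for s in prox_spl if s <= threshold)
    b = len(prox_spl) - a
    c = sum(1 for s in other_spl if s <= threshold)
    d = len(other_spl) - c
    table = np.array([[a, b], [c, d]])
    if b * c > 0:
        odds = (a * d) / (b * c)
    else:
        odds = math.inf if a * d > 0 else math.nan
    if (stats.contingency.expected_freq(table) < 5).any():
        _, table_p = stats.fisher_exact(table)
        test = "fisher-exact"
    else:
        _, table_p, _, _ = stats.chi2_contingency(table, correction=False)
        test = "chi-square"
    return HierarchyComparison(
        n_proximal=len(prox_spl),
        n_other=len(other_spl),
        ranksum_stat=float(stat),
        ranksum_p=float(p),
        table=((a, b), (c, d)),
        odds_ratio=float(odds),
        table_p=float(table_p),
        table_test=test,
        threshold=threshold,
    )
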