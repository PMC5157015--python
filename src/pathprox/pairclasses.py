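"""Five-way gene-pair classification and the expression / PPI comparisons.

Spatially proximal pairs split three ways — sharing a pathway
(*proximal-intra-pathway*), each gene in a different pathway
(*proximal-inter-pathway*), or at least one gene in no pathway
(*proximal-generic*).  Non-proximal pairs split two ways — within a
pathway (*non-proximal-intra-pathway*) or between genes that are proximal
to nothing and in no pathway (*non-proximal-generic*).  The conventional
roman labels used in PPI comparisons are

    I   proximal-intra-pathway
    II  non-proximal-intra-pathway
    III proximal-inter-pathway
    IV  proximal-generic
    V   non-proximal-generic
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
from scipy import stats

from .types import GeneAnnotation, GenePair, Pathway, ProximityGraph, canonical_pair

logger = logging.getLogger(__name__)

PROXIMAL_INTRA = "proximal-intra-pathway"
PROXIMAL_INTER = "proximal-inter-pathway"
PROXIMAL_GENERIC = "proximal-generic"
NONPROX_INTRA = "non-proximal-intra-pathway"
NONPROX_GENERIC = "non-proximal-generic"

CLASS_ROMAN = {
    "I": PROXIMAL_INTRA,
    "II": NONPROX_INTRA,
    "III": PROXIMAL_INTER,
    "IV": PROXIMAL_GENERIC,
    "V": NONPROX_GENERIC,
}

DEFAULT_GENERIC_SAMPLE = 100_000


def _membership(pathways: Iterable[Pathway]) -> dict[str, set[str]]:
    """gene -> set of pathway ids containing it (union semantics)."""
    member: dict[str, set[str]] = {}
    for p in pathways:
        for g in p.genes:
            member.setdefault(g, set()).add(p.pathway_id)
    return member


@dataclass
class PairClassification:
    """The five-way partition of gene pairs.

    The three proximal classes partition the SGP pair set exactly and the
    non-proximal-intra-pathway class is enumerated exactly.  The
    non-proximal-generic class is quadratically large and is represented by
    a uniform random sample (``generic_sampled`` is then True).
    """

    by_label: dict[str, set[GenePair]]
    generic_sampled: bool
    n_generic_candidates: int  # genes eligible for the non-proximal-generic class

    def label_of(self, a: str, b: str) -> Optional[str]:
        pair = canonical_pair(a, b)
        for label, pairs in self.by_label.items():
            if pair in pairs:
                return label
        return None

    def by_roman(self) -> dict[str, set[GenePair]]:
        return {roman: self.by_label[label] for roman, label in CLASS_ROMAN.items()}


def classify_pairs(
    sgp: ProximityGraph,
    pathways: Iterable[Pathway],
    universe: GeneAnnotation,
    rng: Optional[np.random.Generator] = None,
    n_generic_sample: int = DEFAULT_GENERIC_SAMPLE,
) -> PairClassification:
    """Partition gene pairs into the five classes.

    Proximal classes cover every SGP pair with both endpoints in the
    universe.  Non-proximal-intra-pathway pairs are enumerated from pathway
    memberships.  Non-proximal-generic pairs (both genes proximal to
    nothing and in no pathway) are sampled uniformly (seeded via ``rng``)
    up to ``n_generic_sample``, or enumerated when fewer exist.
    """
    pathways = list(pathways)
    member = _membership(pathways)
    in_universe = set(universe)

    prox_intra: set[GenePair] = set()
    prox_inter: set[GenePair] = set()
    prox_generic: set[GenePair] = set()
    for a, b in sgp.pairs:
        if a not in in_universe or b not in in_universe:
            continue
        pa, pb = member.get(a), member.get(b)
        if pa and pb:
            if pa & pb:
                prox_intra.add((a, b))
            else:
                prox_inter.add((a, b))
        else:
            prox_generic.add((a, b))

    # exact enumeration of within-pathway non-proximal pairs
    nonprox_intra: set[GenePair] = set()
    for p in pathways:
        genes = sorted(p.genes & in_universe)
        for a, b in itertools.combinations(genes, 2):
            if (a, b) not in prox_intra:
                nonprox_intra.add((a, b))

    # genes proximal to nothing and in no pathway
    proximal_genes = sgp.genes()
    candidates = sorted(in_universe - proximal_genes - set(member))
    n_cand = len(candidates)
    total_pairs = n_cand * (n_cand - 1) // 2
    nonprox_generic: set[GenePair] = set()
    if total_pairs <= n_generic_sample:
        nonprox_generic = set(itertools.combinations(candidates, 2))
        sampled = False
    else:
        if rng is None:
            rng = np.random.default_rng()
        while len(nonprox_generic) < n_generic_sample:
            idx = rng.integers(0, n_cand, size=2 * (n_generic_sample - len(nonprox_generic)))
            for k in range(0, len(idx) - 1, 2):
                i, j = int(idx[k]), int(idx[k + 1])
                if i != j:
                    nonprox_generic.add(canonical_pair(candidates[i], candidates[j]))
                    if len(nonprox_generic) >= n_generic_sample:
                        break
        sampled = True

    logger.info(
        "classify_pairs: I=%d II=%d III=%d IV=%d V=%d%s",
        len(prox_intra), len(nonprox_intra), len(prox_inter),
        len(prox_generic), len(nonprox_generic),
        " (V sampled)" if sampled else "",
    )
    return PairClassification(
        by_label={
            PROXIMAL_INTRA: prox_intra,
            PROXIMAL_INTER: prox_inter,
            PROXIMAL_GENERIC: prox_generic,
            NONPROX_INTRA: nonprox_intra,
            NONPROX_GENERIC: nonprox_generic,
        },
        generic_sampled=sampled,
        n_generic_candidates=n_cand,
    )


def proximal_intra_pathway_genes(
    sgp: ProximityGraph, pathway: Pathway
) -> set[str]:
    """Genes of one pathway that are proximal to another gene of the same pathway."""
    out: set[str] = set()
    genes = sorted(pathway.genes)
    for a, b in itertools.combinations(genes, 2):
        if (a, b) in sgp:
            out.add(a)
            out.add(b)
    return out


@dataclass
class ExpressionGroups:
    """The three gene-level expression groups.

    A: genes with a proximal partner in a shared pathway.
    B: otherwise-proximal genes (partner outside every shared pathway).
    C: active genes with no proximal partner at all.
    """

    group_a: set[str]
    group_b: set[str]
    group_c: set[str]

    def as_dict(self) -> dict[str, set[str]]:
        return {"A": self.group_a, "B": self.group_b, "C": self.group_c}


@dataclass
class ComparisonResult:
    label: str
    n_x: int
    n_y: int
    statistic: float
    p: float
    skipped: bool = False
    note: str = ""


def expression_groups(
    sgp: ProximityGraph,
    pathways: Iterable[Pathway],
    universe: GeneAnnotation,
    expression: Mapping[str, float],
) -> tuple[ExpressionGroups, list[ComparisonResult]]:
    """Partition active genes into groups A/B/C and rank-sum test A vs B, A vs C.

    Expression values should already be per-gene maxima over transcripts.
    Empty groups make the corresponding comparison a flagged skip.
    """
    pathways = list(pathways)
    member = _membership(pathways)
    in_universe = set(universe)

    group_a: set[str] = set()
    for a, b in sgp.pairs:
        if a in in_universe and b in in_universe:
            if member.get(a, set()) & member.get(b, set()):
                group_a.add(a)
                group_a.add(b)
    proximal = {g for g in sgp.genes() if g in in_universe}
    group_b = proximal - group_a
    group_c = in_universe - proximal
    groups = ExpressionGroups(group_a, group_b, group_c)

    def values(genes: set[str]) -> np.ndarray:
        return np.array([expression[g] for g in sorted(genes) if g in expression])

    va = values(group_a)
    reports: list[ComparisonResult] = []
    for label, other in (("A_vs_B", values(group_b)), ("A_vs_C", values(group_c))):
        if len(va) == 0 or len(other) == 0:
            reports.append(ComparisonResult(label, len(va), len(other),
                                            math.nan, math.nan, skipped=True,
                                            note="empty group"))
            continue
        stat, p = stats.mannwhitneyu(va, other, alternative="two-sided")
        reports.append(ComparisonResult(label, len(va), len(other), float(stat), float(p)))
    return groups, reports


@dataclass
class PPIClassReport:
    fractions: dict[str, float]  # roman label -> fractional PPI
    counts: dict[str, tuple[int, int]]  # roman label -> (pairs with PPI, pairs)
    comparisons: list[ComparisonResult]  # I vs II, III, IV, V


def ppi_fraction_by_class(
    classification: PairClassification,
    ppi_pairs: set[GenePair] | ProximityGraph,
) -> PPIClassReport:
    """Fractional PPI per pair class and 2x2 tests of class I against each other.

    Chi-square (no continuity correction) on the 2x2 table; Fisher's exact
    test substitutes, flagged in the note, when any expected cell count is
    below 5 (including zero-count cells).  Classes with zero pairs are
    excluded with a flag.
    """
    if isinstance(ppi_pairs, ProximityGraph):
        ppi = ppi_pairs.pair_set()
    else:
        ppi = {canonical_pair(a, b) for a, b in ppi_pairs if a != b}

    fractions: dict[str, float] = {}
    counts: dict[str, tuple[int, int]] = {}
    for roman, pairs in classification.by_roman().items():
        n = len(pairs)
        hits = sum(1 for pr in pairs if pr in ppi)
        counts[roman] = (hits, n)
        fractions[roman] = hits / n if n else math.nan

    comparisons: list[ComparisonResult] = []
    hits_i, n_i = counts["I"]
    for roman in ("II", "III", "IV", "V"):
        hits_o, n_o = counts[roman]
        label = f"I_vs_{roman}"
        if n_i == 0 or n_o == 0:
            comparisons.append(ComparisonResult(label, n_i, n_o, math.nan, math.nan,
                                                skipped=True, note="empty class"))
            continue
        table = np.array([[hits_i, n_i - hits_i], [hits_o, n_o - hits_o]])
        expected = stats.contingency.expected_freq(table)
        if (expected < 5).any():
            odds, p = stats.fisher_exact(table)
            comparisons.append(ComparisonResult(label, n_i, n_o, float(odds), float(p),
                                                note="fisher-exact (small expected counts)"))
        else:
            chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
            comparisons.append(ComparisonResult(label, n_i, n_o, float(chi2), float(p)))
    return PPIClassReport(fractions=fractions, counts=counts, comparisons=comparisons)
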