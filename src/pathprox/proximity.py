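"""Edge fraction, matched-sampling nulls and pathway-proximity Z-scores.

The central statistic is the *edge fraction* (EF) of a gene set: the
fraction of all unordered gene pairs in the set that are spatially
proximal (present in the SGP set).  Its significance comes from a
sampling null: random gene sets matched to the target set gene-by-gene on
chromosome and on length (within a relative tolerance, default 20%),
drawn ``n_null_samples`` times.  The same machinery drives intra-pathway,
inter-pathway and housekeeping-versus-pathway proximity scores.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

from .types import (
    GeneAnnotation,
    GenePair,
    Pathway,
    ProximityGraph,
    RunConfig,
    canonical_pair,
)

logger = logging.getLogger(__name__)

# how many times the per-gene length tolerance may be doubled when the
# candidate pool for a target gene is exhausted
MAX_TOLERANCE_DOUBLINGS = 2


def bh_fdr(pvalues: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    All inputs must lie in (0, 1]; monotone-enforced and capped at 1.
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in (0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def edge_fraction(genes: Iterable[str], sgp: ProximityGraph) -> float:
    """Fraction of all unordered pairs within ``genes`` present in the SGP set."""
    gene_list = sorted(set(genes))
    n = len(gene_list)
    if n < 2:
        raise ValueError(f"edge fraction needs >= 2 genes, got {n}")
    hits = 0
    for i in range(n):
        for j in range(i + 1, n):
            if (gene_list[i], gene_list[j]) in sgp:
                hits += 1
    return hits / (n * (n - 1) // 2)


class MatchedSampler:
    """Draws random gene sets matched per-gene on chromosome and length.

    For a target set, each sample contains, per chromosome, exactly as many
    genes as the target has there; each drawn gene's length lies within
    ``tol`` (relative) of its matched target gene's length.  Target genes
    are visited in random order and candidates drawn uniformly without
    replacement within one sample.  If a target gene's candidate pool is
    exhausted its tolerance is doubled (at most twice, logged); a pool
    still empty afterwards raises an error naming chromosome and gene.
    """

    def __init__(self, universe: GeneAnnotation, tol: float = 0.2):
        if tol <= 0:
            raise ValueError("tolerance must be positive")
        self.universe = universe
        self.tol = tol
        self._by_chrom: dict[str, tuple[np.ndarray, list[str]]] = {}
        for chrom, genes in universe.by_chrom.items():
            ordered = sorted(genes, key=lambda g: (g.length, g.gene_id))
            lengths = np.array([g.length for g in ordered], dtype=float)
            ids = [g.gene_id for g in ordered]
            self._by_chrom[chrom] = (lengths, ids)
        self.n_relaxed = 0  # count of per-gene tolerance doublings performed

    def _draw_one(
        self,
        chrom: str,
        target_len: float,
        target_id: str,
        drawn: set[int],
        rng: np.random.Generator,
    ) -> int:
        lengths, _ = self._by_chrom[chrom]
        tol = self.tol
        for attempt in range(MAX_TOLERANCE_DOUBLINGS + 1):
            lo = int(np.searchsorted(lengths, target_len * (1 - tol), side="left"))
            hi = int(np.searchsorted(lengths, target_len * (1 + tol), side="right"))
            width = hi - lo
            if width > 0:
                # rejection sampling against the already-drawn set is almost
                # always immediate; fall back to pool enumeration if unlucky
                pick = -1
                if width > len(drawn):
                    for _ in range(20):
                        k = lo + int(rng.integers(width))
                        if k not in drawn:
                            pick = k
                            break
                if pick < 0:
                    pool = [k for k in range(lo, hi) if k not in drawn]
                    if pool:
                        pick = pool[int(rng.integers(len(pool)))]
                if pick >= 0:
                    if attempt > 0:
                        self.n_relaxed += 1
                        logger.debug(
                            "matched sampling: tolerance relaxed to %.2f for %s on %s",
                            tol, target_id, chrom,
                        )
                    return pick
            tol *= 2
        raise ValueError(
            f"no admissible control gene on {chrom} for target {target_id!r} "
            f"(length {target_len:g}) even after relaxation"
        )

    def sample(
        self,
        target_genes: Sequence[str],
        rng: np.random.Generator,
        exclude: Optional[set[str]] = None,
    ) -> list[str]:
        """One matched control set for ``target_genes`` (IDs in the universe)."""
        by_chrom: dict[str, list[str]] = {}
        for gid in target_genes:
            by_chrom.setdefault(self.universe[gid].chrom, []).append(gid)
        out: list[str] = []
        for chrom in sorted(by_chrom):
            lengths, ids = self._by_chrom.get(chrom, (None, None))
            if lengths is None:
                raise ValueError(f"universe has no genes on {chrom}")
            drawn: set[int] = set()
            if exclude:
                drawn.update(k for k, gid in enumerate(ids) if gid in exclude)
            # length-sorted before shuffling so the draw sequence does not
            # depend on gene labels (exact relabeling invariance when
            # lengths are unique)
            targets = sorted(by_chrom[chrom], key=lambda gid: self.universe[gid].length)
            rng.shuffle(targets)
            for gid in targets:
                k = self._draw_one(chrom, self.universe[gid].length, gid, drawn, rng)
                drawn.add(k)
                out.append(ids[k])
        return out


def sample_matched_set(
    target_genes: Sequence[str],
    universe: GeneAnnotation,
    tol: float = 0.2,
    rng: Optional[np.random.Generator] = None,
) -> list[str]:
    """One chromosome- and length-matched random gene set (see MatchedSampler)."""
    if rng is None:
        rng = np.random.default_rng()
    return MatchedSampler(universe, tol).sample(target_genes, rng)


class _EdgeLookup:
    """Dense boolean adjacency over an indexed gene universe, for fast EF."""

    def __init__(self, universe_ids: Sequence[str], sgp: ProximityGraph):
        self.index = {gid: k for k, gid in enumerate(universe_ids)}
        n = len(universe_ids)
        self.adj = np.zeros((n, n), dtype=bool)
        for a, b in sgp.pairs:
            ia = self.index.get(a)
            ib = self.index.get(b)
            if ia is not None and ib is not None:
                self.adj[ia, ib] = True
                self.adj[ib, ia] = True

    def n_edges(self, gene_ids: Sequence[str]) -> int:
        idx = np.fromiter((self.index[g] for g in gene_ids), dtype=int)
        return int(self.adj[np.ix_(idx, idx)].sum()) // 2

    def n_cross_edges(self, set_a: Sequence[str], set_b: Sequence[str]) -> int:
        ia = np.fromiter((self.index[g] for g in set_a), dtype=int)
        ib = np.fromiter((self.index[g] for g in set_b), dtype=int)
        return int(self.adj[np.ix_(ia, ib)].sum())


@dataclass
class EFResult:
    """A pathway's observed edge fraction with its sampling null."""

    pathway_id: str
    cell_line: str
    n_genes_used: int
    observed_ef: float
    null_mean: float
    null_sd: float
    z: float  # NaN when the null is degenerate (sd == 0)
    empirical_p: float
    n_samples: int
    q: float = math.nan

    @property
    def z_defined(self) -> bool:
        return not math.isnan(self.z)


@dataclass
class InterPathwayResult:
    pathway_a: str
    pathway_b: str
    cell_line: str
    shared_genes_excluded: int
    n_genes_a: int
    n_genes_b: int
    observed_cross_edges: int
    null_mean: float
    null_sd: float
    z: float
    empirical_p: float
    n_samples: int
    overlap_fraction: float
    q: float = math.nan


def _null_summary(observed: float, null_values: np.ndarray) -> tuple[float, float, float, float]:
    """(null mean, null sd, z, add-one empirical p); ties count as >=."""
    mean = float(null_values.mean())
    sd = float(null_values.std(ddof=1)) if len(null_values) > 1 else 0.0
    z = (observed - mean) / sd if sd > 0 else math.nan
    p = (1 + int(np.sum(null_values >= observed))) / (len(null_values) + 1)
    return mean, sd, z, p


def ef_zscore(
    pathway: Pathway,
    sgp: ProximityGraph,
    universe: GeneAnnotation,
    cfg: RunConfig,
    rng: Optional[np.random.Generator] = None,
    cell_line: str = "",
    sampler: Optional[MatchedSampler] = None,
    lookup: Optional[_EdgeLookup] = None,
) -> EFResult:
    """Edge-fraction Z-score of one pathway against its matched-sampling null.

    The pathway must retain at least ``cfg.pathway_min_size`` genes inside
    the universe; observed and null EFs share the same denominator (the
    detected active subset).  Housekeeping genes should be removed from the
    pathway before calling.
    """
    genes_used = sorted(pathway.genes & set(universe))
    if len(genes_used) < cfg.pathway_min_size:
        raise ValueError(
            f"pathway {pathway.pathway_id!r}: only {len(genes_used)} genes in the "
            f"universe (min {cfg.pathway_min_size})"
        )
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if sampler is None:
        sampler = MatchedSampler(universe, cfg.length_tolerance)
    if lookup is None:
        lookup = _EdgeLookup(sorted(universe), sgp)

    n_pairs = len(genes_used) * (len(genes_used) - 1) // 2
    observed = lookup.n_edges(genes_used) / n_pairs
    null = np.empty(cfg.n_null_samples)
    for k in range(cfg.n_null_samples):
        sample = sampler.sample(genes_used, rng)
        null[k] = lookup.n_edges(sample) / n_pairs
    mean, sd, z, p = _null_summary(observed, null)
    return EFResult(
        pathway_id=pathway.pathway_id,
        cell_line=cell_line,
        n_genes_used=len(genes_used),
        observed_ef=observed,
        null_mean=mean,
        null_sd=sd,
        z=z,
        empirical_p=p,
        n_samples=cfg.n_null_samples,
    )


def ef_zscores(
    pathways: Iterable[Pathway],
    sgp: ProximityGraph,
    universe: GeneAnnotation,
    cfg: RunConfig,
    rng: Optional[np.random.Generator] = None,
    cell_line: str = "",
    housekeeping: Optional[set[str]] = None,
) -> list[EFResult]:
    """EF Z-scores for a pathway collection, with BH q-values across the
    collection (one FDR family per cell line).

    Housekeeping genes, if given, are excluded from every pathway first.
    Pathways falling below ``pathway_min_size`` in the universe are skipped
    with a log message.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    sampler = MatchedSampler(universe, cfg.length_tolerance)
    lookup = _EdgeLookup(sorted(universe), sgp)
    results: list[EFResult] = []
    n_skipped = 0
    for p in pathways:
        genes = p.genes - housekeeping if housekeeping else p.genes
        if len(genes & set(universe)) < cfg.pathway_min_size:
            n_skipped += 1
            continue
        trimmed = Pathway(p.pathway_id, p.name, frozenset(genes))
        results.append(
            ef_zscore(trimmed, sgp, universe, cfg, rng=rng, cell_line=cell_line,
                      sampler=sampler, lookup=lookup)
        )
    if n_skipped:
        logger.info("ef_zscores: skipped %d pathways below min size %d",
                    n_skipped, cfg.pathway_min_size)
    if results:
        qvals = bh_fdr([r.empirical_p for r in results])
        for r, q in zip(results, qvals):
            r.q = float(q)
    return results


def inter_pathway_zscore(
    pa: Pathway,
    pb: Pathway,
    sgp: ProximityGraph,
    universe: GeneAnnotation,
    cfg: RunConfig,
    rng: Optional[np.random.Generator] = None,
    cell_line: str = "",
    sampler: Optional[MatchedSampler] = None,
    lookup: Optional[_EdgeLookup] = None,
) -> InterPathwayResult:
    """Cross-pathway proximity: SGP edges between the two pathways after
    excluding shared genes, against a null of two jointly resampled matched
    sets (drawn disjointly within each iteration)."""
    in_universe = set(universe)
    a_all = pa.genes & in_universe
    b_all = pb.genes & in_universe
    shared = a_all & b_all
    a_only = sorted(a_all - shared)
    b_only = sorted(b_all - shared)
    if len(a_only) < 2 or len(b_only) < 2:
        raise ValueError(
            f"inter-pathway test {pa.pathway_id!r} vs {pb.pathway_id!r}: fewer than "
            f"2 exclusive genes on one side ({len(a_only)}, {len(b_only)})"
        )
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if sampler is None:
        sampler = MatchedSampler(universe, cfg.length_tolerance)
    if lookup is None:
        lookup = _EdgeLookup(sorted(universe), sgp)

    observed = lookup.n_cross_edges(a_only, b_only)
    null = np.empty(cfg.n_null_samples)
    for k in range(cfg.n_null_samples):
        sa = sampler.sample(a_only, rng)
        sb = sampler.sample(b_only, rng, exclude=set(sa))
        null[k] = lookup.n_cross_edges(sa, sb)
    mean, sd, z, p = _null_summary(observed, null)
    denom = min(len(a_all), len(b_all))
    overlap = len(shared) / denom if denom else 0.0
    return InterPathwayResult(
        pathway_a=pa.pathway_id,
        pathway_b=pb.pathway_id,
        cell_line=cell_line,
        shared_genes_excluded=len(shared),
        n_genes_a=len(a_only),
        n_genes_b=len(b_only),
        observed_cross_edges=observed,
        null_mean=mean,
        null_sd=sd,
        z=z,
        empirical_p=p,
        n_samples=cfg.n_null_samples,
        overlap_fraction=overlap,
    )


def inter_pathway_zscores(
    pathway_pairs: Iterable[tuple[Pathway, Pathway]],
    sgp: ProximityGraph,
    universe: GeneAnnotation,
    cfg: RunConfig,
    rng: Optional[np.random.Generator] = None,
    cell_line: str = "",
) -> list[InterPathwayResult]:
    """Inter-pathway Z-scores with BH q-values across all tested pairs."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    sampler = MatchedSampler(universe, cfg.length_tolerance)
    lookup = _EdgeLookup(sorted(universe), sgp)
    results = [
        inter_pathway_zscore(pa, pb, sgp, universe, cfg, rng=rng,
                             cell_line=cell_line, sampler=sampler, lookup=lookup)
        for pa, pb in pathway_pairs
    ]
    if results:
        qvals = bh_fdr([r.empirical_p for r in results])
        for r, q in zip(results, qvals):
            r.q = float(q)
    return results


def housekeeping_proximity(
    hk_genes: set[str],
    pathways: Iterable[Pathway],
    sgp: ProximityGraph,
    universe: GeneAnnotation,
    cfg: RunConfig,
    rng: Optional[np.random.Generator] = None,
    cell_line: str = "",
) -> list[InterPathwayResult]:
    """Proximity between the housekeeping set (as a virtual pathway) and each
    pathway, with the same shared-gene exclusion as the inter-pathway test."""
    hk_pathway = Pathway("housekeeping", "housekeeping genes", frozenset(hk_genes))
    pairs = [(hk_pathway, p) for p in pathways]
    return inter_pathway_zscores(pairs, sgp, universe, cfg, rng=rng, cell_line=cell_line)


def filter_intra_chromosomal(sgp: ProximityGraph, cfg: Optional[RunConfig] = None) -> ProximityGraph:
    """The inter-chromosomal-only variant: drop all intra-chromosomal pairs."""
    out = sgp.inter_chromosomal_only()
    logger.info("filter_intra_chromosomal: %d / %d pairs kept", len(out), len(sgp))
    return out
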