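"""Pathway activity scoring and its relation to spatial proximity.

A pathway's activity is the mean expression of its *proximal-intra-pathway*
genes (genes proximal to another gene of the same pathway).  Its
significance comes from the same matched-sampling null as the edge
fraction: random gene sets matched on chromosome and length to the genes
actually averaged.  The proximity-activity relationship is summarized by
the Spearman rank correlation between the two Z-scores over all
(pathway, cell line) entries, with no Z-score thresholding.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .pairclasses import proximal_intra_pathway_genes
from .proximity import EFResult, MatchedSampler, _null_summary
from .types import GeneAnnotation, Pathway, ProximityGraph, RunConfig

logger = logging.getLogger(__name__)


@dataclass
class ActivityResult:
    pathway_id: str
    cell_line: str
    n_genes_used: int
    mean_expression: float
    null_mean: float = math.nan
    null_sd: float = math.nan
    z: float = math.nan
    empirical_p: float = math.nan
    n_samples: int = 0

    @property
    def z_defined(self) -> bool:
        return not math.isnan(self.z)


def pathway_activity(
    pathway: Pathway,
    expression: Mapping[str, float],
    sgp: ProximityGraph,
    cell_line: str = "",
) -> Optional[ActivityResult]:
    """Mean expression over the pathway's proximal-intra-pathway genes.

    Returns None (logged) when the pathway has no such gene with an
    expression value.  Expression values should already be per-gene maxima
    over transcripts.
    """
    genes = sorted(g for g in proximal_intra_pathway_genes(sgp, pathway)
                   if g in expression)
    if not genes:
        logger.info("pathway_activity: %s has no proximal-intra-pathway genes "
                    "with expression; skipped", pathway.pathway_id)
        return None
    values = np.array([expression[g] for g in genes])
    return ActivityResult(
        pathway_id=pathway.pathway_id,
        cell_line=cell_line,
        n_genes_used=len(genes),
        mean_expression=float(values.mean()),
    )


def activity_zscore(
    pathway: Pathway,
    expression: Mapping[str, float],
    sgp: ProximityGraph,
    universe: GeneAnnotation,
    cfg: RunConfig,
    rng: Optional[np.random.Generator] = None,
    cell_line: str = "",
    sampler: Optional[MatchedSampler] = None,
) -> Optional[ActivityResult]:
    """Activity Z-score against matched random gene sets.

    The null re-matches on the proximal subset actually averaged (same
    chromosome counts and per-gene length tolerance), so the statistic is
    exchangeable under the null of no expression effect.  A constant-null
    pathway gets a NaN z flag but still an empirical p.
    """
    result = pathway_activity(pathway, expression, sgp, cell_line=cell_line)
    if result is None:
        return None
    genes = sorted(g for g in proximal_intra_pathway_genes(sgp, pathway)
                   if g in expression)
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if sampler is None:
        sampler = MatchedSampler(universe, cfg.length_tolerance)
    null = np.empty(cfg.n_null_samples)
    for k in range(cfg.n_null_samples):
        sample = sampler.sample(genes, rng)
        vals = [expression[g] for g in sample if g in expression]
        null[k] = float(np.mean(vals)) if vals else math.nan
    null = null[~np.isnan(null)]
    if len(null) == 0:
        return result
    mean, sd, z, p = _null_summary(result.mean_expression, null)
    result.null_mean = mean
    result.null_sd = sd
    result.z = z
    result.empirical_p = p
    result.n_samples = len(null)
    return result


def activity_zscores(
    pathways: Iterable[Pathway],
    expression: Mapping[str, float],
    sgp: ProximityGraph,
    universe: GeneAnnotation,
    cfg: RunConfig,
    rng: Optional[np.random.Generator] = None,
    cell_line: str = "",
) -> list[ActivityResult]:
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    sampler = MatchedSampler(universe, cfg.length_tolerance)
    results = []
    for p in pathways:
        r = activity_zscore(p, expression, sgp, universe, cfg, rng=rng,
                            cell_line=cell_line, sampler=sampler)
        if r is not None:
            results.append(r)
    return results


@dataclass
class CorrelationReport:
    pooled_rho: float
    pooled_p: float
    n_pooled: int
    per_cell_line: dict[str, tuple[float, float, int]]  # rho, p, n


def proximity_activity_correlation(
    ef_results: Sequence[EFResult],
    activity_results: Sequence[ActivityResult],
) -> CorrelationReport:
    """Spearman correlation between proximity and activity Z-scores.

    Entries are joined on (pathway, cell line); no thresholding is applied.
    Requires at least 3 joined pairs.
    """
    act = {(r.pathway_id, r.cell_line): r for r in activity_results
           if r.z_defined}
    pairs: list[tuple[str, float, float]] = []
    for r in ef_results:
        key = (r.pathway_id, r.cell_line)
        if r.z_defined and key in act:
            pairs.append((r.cell_line, r.z, act[key].z))
    if len(pairs) < 3:
        raise ValueError(f"need >= 3 joined (pathway, cell line) pairs, got {len(pairs)}")

    xs = np.array([p[1] for p in pairs])
    ys = np.array([p[2] for p in pairs])
    rho, p = stats.spearmanr(xs, ys)

    per_cell: dict[str, tuple[float, float, int]] = {}
    for cl in sorted({p[0] for p in pairs}):
        sub = [(x, y) for c, x, y in pairs if c == cl]
        if len(sub) >= 3:
            r_cl, p_cl = stats.spearmanr([s[0] for s in sub], [s[1] for s in sub])
            per_cell[cl] = (float(r_cl), float(p_cl), len(sub))
    return CorrelationReport(float(rho), float(p), len(pairs), per_cell)
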