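"""Contact-map normalization, interaction calling, compartments and gene mapping.

The workflow mirrors the standard Hi-C processing stack for binned data:

1. :func:`fit_background` builds a distance-decay / coverage background model
   (expected counts ``e_ij``) from the observed map itself.
2. :func:`call_interactions` tests every observed bin pair against its
   expectation with an upper-tail Poisson test and controls the FDR with
   Benjamini-Hochberg.
3. :func:`assign_compartments` computes the first principal component of the
   per-chromosome observed/expected correlation matrix and labels bins and
   genes A (positive PC1, oriented to the gene-dense side) or B.
4. :func:`map_calls_to_genes` converts significant bin pairs into the set of
   spatially proximal gene pairs (the SGP set).
5. :func:`restrict_to_active` filters genes, pairs and pathways to the
   A compartment.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .types import GeneAnnotation, Pathway, ProximityGraph, RunConfig, canonical_pair

logger = logging.getLogger(__name__)

# number of log-spaced distance-smoothing bins per decade of genomic distance
LOG_BINS_PER_DECADE = 10

# promoter proxy: how far upstream of the gene start a bin may lie and still
# be assigned to the gene
PROMOTER_WINDOW = 2_000


@dataclass
class ContactMatrix:
    """Sparse intra-chromosomal binned contact counts, stored upper-triangular."""

    chrom: str
    resolution: int
    n_bins: int
    counts: dict[tuple[int, int], int] = field(default_factory=dict)

    def add(self, i: int, j: int, count: int) -> None:
        if count < 0:
            raise ValueError("negative contact count")
        if not (0 <= i < self.n_bins and 0 <= j < self.n_bins):
            raise ValueError(
                f"bin out of range for {self.chrom} ({self.n_bins} bins): ({i}, {j})"
            )
        key = (i, j) if i <= j else (j, i)
        self.counts[key] = self.counts.get(key, 0) + count

    def total(self) -> int:
        return sum(self.counts.values())

    def to_dense(self) -> np.ndarray:
        m = np.zeros((self.n_bins, self.n_bins))
        for (i, j), c in self.counts.items():
            m[i, j] = c
            m[j, i] = c
        return m


@dataclass
class InterContactMatrix:
    """Sparse inter-chromosomal counts between two chromosomes (ordered pair)."""

    chrom_a: str
    chrom_b: str
    resolution: int
    n_bins_a: int
    n_bins_b: int
    counts: dict[tuple[int, int], int] = field(default_factory=dict)

    def add(self, i: int, j: int, count: int) -> None:
        if count < 0:
            raise ValueError("negative contact count")
        self.counts[(i, j)] = self.counts.get((i, j), 0) + count

    def total(self) -> int:
        return sum(self.counts.values())


class HiCDataset:
    """A resolution-consistent collection of intra- and inter-chromosomal maps."""

    def __init__(self, resolution: int):
        self.resolution = resolution
        self.intra: dict[str, ContactMatrix] = {}
        self.inter: dict[tuple[str, str], InterContactMatrix] = {}

    def add_intra(self, matrix: ContactMatrix) -> None:
        if matrix.resolution != self.resolution:
            raise ValueError("resolution mismatch")
        self.intra[matrix.chrom] = matrix

    def add_inter(self, matrix: InterContactMatrix) -> None:
        if matrix.resolution != self.resolution:
            raise ValueError("resolution mismatch")
        self.inter[(matrix.chrom_a, matrix.chrom_b)] = matrix

    def n_bins(self, chrom: str) -> int:
        return self.intra[chrom].n_bins

    def total_reads(self) -> int:
        return sum(m.total() for m in self.intra.values()) + sum(
            m.total() for m in self.inter.values()
        )


@dataclass
class BackgroundModel:
    """Expected-count model: per-bin bias x distance decay.

    ``e_ij = b_i * b_j * f(d_ij)`` for intra-chromosomal pairs and
    ``e_ij = b_i * b_j * inter_rate`` for inter-chromosomal pairs, with
    ``f`` the smoothed contact frequency per distance and the bias vector
    ``b`` optimized by fixed-point iteration so that every bin's expected
    marginal matches its observed read coverage (this handles uneven
    sequencing depth and chromosome-edge effects in one step).  Summed over
    all pairs the expected counts then reproduce the total read count N.
    """

    resolution: int
    coverage: dict[tuple[str, int], float]
    total_reads: float
    f_distances: np.ndarray  # distance (bins) grid, ascending
    f_values: np.ndarray  # smoothed frequency at each grid distance
    bias: dict[tuple[str, int], float]
    inter_rate: float  # flat per-(b_i*b_j) inter-chromosomal rate

    def f(self, d_bins: int) -> float:
        """Smoothed contact frequency at a genomic separation of d bins."""
        idx = np.searchsorted(self.f_distances, d_bins)
        idx = min(idx, len(self.f_values) - 1)
        return float(self.f_values[idx])

    def expected_intra(self, chrom: str, i: int, j: int) -> float:
        bi = self.bias.get((chrom, i), 0.0)
        bj = self.bias.get((chrom, j), 0.0)
        return bi * bj * self.f(abs(j - i))

    def expected_inter(self, chrom_a: str, i: int, chrom_b: str, j: int) -> float:
        bi = self.bias.get((chrom_a, i), 0.0)
        bj = self.bias.get((chrom_b, j), 0.0)
        return bi * bj * self.inter_rate


@dataclass
class InteractionCall:
    chrom_a: str
    bin_a: int
    chrom_b: str
    bin_b: int
    observed: int
    expected: float
    p: float
    q: float = math.nan

    @property
    def enrichment(self) -> float:
        return self.observed / self.expected

    @property
    def inter_chromosomal(self) -> bool:
        return self.chrom_a != self.chrom_b


@dataclass
class CompartmentAssignment:
    """Per-bin PC1 values and A/B labels, plus per-gene labels.

    A bin is labelled A iff its (orientation-corrected) PC1 value is
    positive.  A gene is labelled by the sign of the length-weighted mean
    PC1 over the bins it overlaps.  Chromosomes whose observed/expected
    correlation matrix is degenerate are flagged unassigned.
    """

    resolution: int
    bin_pc1: dict[tuple[str, int], float]
    bin_label: dict[tuple[str, int], str]
    gene_pc1: dict[str, float]
    gene_label: dict[str, str]
    unassigned_chroms: set[str] = field(default_factory=set)

    def active_genes(self) -> set[str]:
        return {g for g, lbl in self.gene_label.items() if lbl == "A"}


# distances at or below this (in bins) keep their exact per-distance
# frequency estimate; only longer, sparser distances are log-smoothed
EXACT_DISTANCE_MAX = 20


def _log_distance_bin_edges(max_d: int) -> np.ndarray:
    """Distance-bin edges: every integer up to EXACT_DISTANCE_MAX, then
    log-spaced (LOG_BINS_PER_DECADE per decade) out to max_d."""
    if max_d < 1:
        return np.array([1])
    exact = np.arange(1, min(max_d, EXACT_DISTANCE_MAX) + 1)
    if max_d <= EXACT_DISTANCE_MAX:
        return exact
    lo, hi = math.log10(EXACT_DISTANCE_MAX + 1), math.log10(max_d)
    n_edges = max(int(math.ceil((hi - lo) * LOG_BINS_PER_DECADE)) + 1, 2)
    coarse = np.floor(np.logspace(lo, hi + 1e-9, n_edges)).astype(int)
    return np.unique(np.concatenate([exact, coarse]))


def fit_background(dataset: HiCDataset) -> BackgroundModel:
    """Fit the coverage x distance-decay expected-count model.

    The raw frequency at distance d is (total reads at d) / (number of bin
    pairs at d), pooled over chromosomes, then smoothed by averaging within
    log-spaced distance bins (within-bin totals over within-bin pair counts).
    The diagonal (d=0) keeps its own raw estimate.
    """
    if not dataset.intra or dataset.total_reads() == 0:
        raise ValueError("cannot fit background on an empty/all-zero dataset")

    # per-bin coverage over all maps
    coverage: dict[tuple[str, int], float] = {}
    for chrom, m in dataset.intra.items():
        for b in range(m.n_bins):
            coverage[(chrom, b)] = 0.0
    for chrom, m in dataset.intra.items():
        for (i, j), c in m.counts.items():
            coverage[(chrom, i)] += c
            if j != i:
                coverage[(chrom, j)] += c
    for (ca, cb), m in dataset.inter.items():
        for (i, j), c in m.counts.items():
            coverage[(ca, i)] = coverage.get((ca, i), 0.0) + c
            coverage[(cb, j)] = coverage.get((cb, j), 0.0) + c

    N = float(dataset.total_reads())

    # raw frequency per integer distance
    max_bins = max(m.n_bins for m in dataset.intra.values())
    counts_at_d = np.zeros(max_bins)
    pairs_at_d = np.zeros(max_bins)
    for m in dataset.intra.values():
        for (i, j), c in m.counts.items():
            counts_at_d[j - i] += c
        d = np.arange(m.n_bins)
        pairs_at_d += np.maximum(m.n_bins - d, 0)

    # smooth over log-spaced distance bins (d >= 1); d = 0 kept raw
    max_d = max_bins - 1
    f_distances = [0]
    f_values = [counts_at_d[0] / pairs_at_d[0] if pairs_at_d[0] > 0 else 0.0]
    if max_d >= 1:
        edges = _log_distance_bin_edges(max_d)
        for k in range(len(edges)):
            lo = edges[k]
            hi = edges[k + 1] if k + 1 < len(edges) else max_d + 1
            if lo > max_d:
                break
            sl = slice(lo, min(hi, max_d + 1))
            npairs = pairs_at_d[sl].sum()
            val = counts_at_d[sl].sum() / npairs if npairs > 0 else 0.0
            # record the bin's upper edge; f(d) is looked up by searchsorted
            f_distances.append(min(hi, max_d + 1) - 1)
            f_values.append(val)
    f_distances_arr = np.asarray(f_distances)
    f_values_arr = np.asarray(f_values, dtype=float)

    model = BackgroundModel(
        resolution=dataset.resolution,
        coverage=coverage,
        total_reads=N,
        f_distances=f_distances_arr,
        f_values=f_values_arr,
        bias={},
        inter_rate=0.0,
    )

    # optimize per-bin bias so expected marginals match observed coverage:
    # b_i <- n_i / (sum_j b_j f(d_ij) + inter_rate * sum_{other chroms} b_j)
    chroms = sorted(dataset.intra)
    cov_vecs = {c: np.array([coverage[(c, b)] for b in range(dataset.intra[c].n_bins)])
                for c in chroms}
    f_mats = {}
    for c in chroms:
        nb = dataset.intra[c].n_bins
        d = np.abs(np.subtract.outer(np.arange(nb), np.arange(nb)))
        fd = np.array([model.f(k) for k in range(nb)])
        f_mats[c] = fd[d]
    inter_total = float(sum(m.total() for m in dataset.inter.values()))

    b = {c: np.sqrt(np.maximum(cov_vecs[c], 0.0)) for c in chroms}
    rate = 0.0
    for _ in range(60):
        sums = {c: b[c].sum() for c in chroms}
        if inter_total > 0:
            cross = sum(sums[ca] * sums[cb]
                        for k, ca in enumerate(chroms) for cb in chroms[k + 1:])
            rate = inter_total / cross if cross > 0 else 0.0
        total_b = sum(sums.values())
        for c in chroms:
            denom = f_mats[c] @ b[c] + rate * (total_b - sums[c])
            with np.errstate(divide="ignore", invalid="ignore"):
                new = np.where(denom > 0, cov_vecs[c] / denom, 0.0)
            # geometric-mean damping: the plain update oscillates (period 2)
            b[c] = np.sqrt(b[c] * new)
    if all(np.all(vec == 0) for vec in b.values()):
        raise ValueError("degenerate background: zero expected mass")
    model.inter_rate = rate
    model.bias = {(c, int(i)): float(v) for c in chroms for i, v in enumerate(b[c])}
    return model


def call_interactions(
    dataset: HiCDataset,
    model: BackgroundModel,
    cfg: RunConfig,
    significant_only: bool = True,
) -> list[InteractionCall]:
    """Call significantly enriched bin pairs.

    For every stored pair with observed count m > 0 the p-value is the
    upper-tail Poisson probability P(X >= m) at mean e_ij; q-values are BH
    over all tested pairs; calls satisfy both p <= interaction_p_threshold
    and q <= interaction_fdr.  Pairs with zero expectation are skipped (and
    counted in the log).  With ``significant_only=False`` the full tested
    table is returned instead of just the significant calls.
    """
    tested: list[InteractionCall] = []
    n_skipped = 0

    for chrom, m in dataset.intra.items():
        for (i, j), c in m.counts.items():
            if c <= 0:
                continue
            e = model.expected_intra(chrom, i, j)
            if e <= 0:
                n_skipped += 1
                continue
            tested.append(InteractionCall(chrom, i, chrom, j, c, e, p=math.nan))
    for (ca, cb), m in dataset.inter.items():
        for (i, j), c in m.counts.items():
            if c <= 0:
                continue
            e = model.expected_inter(ca, i, cb, j)
            if e <= 0:
                n_skipped += 1
                continue
            tested.append(InteractionCall(ca, i, cb, j, c, e, p=math.nan))

    if n_skipped:
        logger.info("call_interactions: skipped %d pairs with zero expectation", n_skipped)
    if not tested:
        return []

    obs = np.array([t.observed for t in tested])
    exp = np.array([t.expected for t in tested])
    pvals = stats.poisson.sf(obs - 1, exp)
    from .proximity import bh_fdr  # local import to avoid cycle at import time

    qvals = bh_fdr(np.clip(pvals, np.nextafter(0, 1), 1.0))
    calls = []
    for t, p, q in zip(tested, pvals, qvals):
        t.p = float(p)
        t.q = float(q)
        if p <= cfg.interaction_p_threshold and q <= cfg.interaction_fdr:
            calls.append(t)
    logger.info(
        "call_interactions: %d pairs tested, %d significant (p<=%g, q<=%g)",
        len(tested), len(calls), cfg.interaction_p_threshold, cfg.interaction_fdr,
    )
    return calls if significant_only else tested


def _gene_bins(gene, resolution: int) -> range:
    """Bins overlapped by the gene body extended by the promoter window."""
    start = max(0, gene.start - PROMOTER_WINDOW)
    return range(start // resolution, (gene.end - 1) // resolution + 1)


def _bin_gene_index(annotation: GeneAnnotation, resolution: int) -> dict[tuple[str, int], list[str]]:
    index: dict[tuple[str, int], list[str]] = {}
    for g in annotation.genes():
        for b in _gene_bins(g, resolution):
            index.setdefault((g.chrom, b), []).append(g.gene_id)
    return index


def assign_compartments(
    dataset: HiCDataset,
    annotation: GeneAnnotation,
    cfg: RunConfig,
    model: Optional[BackgroundModel] = None,
    min_bins: int = 10,
) -> CompartmentAssignment:
    """A/B compartment assignment from PC1 of the O/E correlation matrix.

    Per chromosome: observed/expected matrix using the fitted distance
    expectation, Pearson correlation of its columns, leading eigenvector of
    the correlation matrix as PC1.  The sign is oriented so the positive
    side has the higher gene density (genes per covered bin).  Chromosomes
    with fewer than ``min_bins`` covered bins, or a degenerate (constant)
    correlation matrix, are flagged unassigned.
    """
    if model is None:
        model = fit_background(dataset)

    bin_pc1: dict[tuple[str, int], float] = {}
    bin_label: dict[tuple[str, int], str] = {}
    unassigned: set[str] = set()
    gene_index = _bin_gene_index(annotation, dataset.resolution)

    for chrom, m in sorted(dataset.intra.items()):
        covered = [b for b in range(m.n_bins) if model.coverage.get((chrom, b), 0.0) > 0]
        if len(covered) < min_bins:
            unassigned.add(chrom)
            continue
        pos = {b: k for k, b in enumerate(covered)}
        oe = np.zeros((len(covered), len(covered)))
        for (i, j), c in m.counts.items():
            if i in pos and j in pos:
                e = model.expected_intra(chrom, i, j)
                if e > 0:
                    oe[pos[i], pos[j]] = c / e
                    oe[pos[j], pos[i]] = c / e
        col_sd = oe.std(axis=0)
        usable = col_sd > 0
        if usable.sum() < min_bins:
            unassigned.add(chrom)
            continue
        sub = oe[np.ix_(usable, usable)]
        with np.errstate(invalid="ignore"):
            corr = np.corrcoef(sub, rowvar=False)
        corr = np.nan_to_num(corr)
        off_diag = corr[~np.eye(len(corr), dtype=bool)]
        if off_diag.size == 0 or np.allclose(off_diag, off_diag.flat[0], atol=1e-12):
            unassigned.add(chrom)
            continue
        vals, vecs = np.linalg.eigh(corr)
        pc1 = vecs[:, -1]

        usable_bins = [b for b, u in zip(covered, usable) if u]
        # orient: positive PC1 side should be the gene-denser side
        dens_pos: list[int] = []
        dens_neg: list[int] = []
        for b, v in zip(usable_bins, pc1):
            n_genes = len(gene_index.get((chrom, b), []))
            (dens_pos if v > 0 else dens_neg).append(n_genes)
        mean_pos = np.mean(dens_pos) if dens_pos else 0.0
        mean_neg = np.mean(dens_neg) if dens_neg else 0.0
        if mean_neg > mean_pos:
            pc1 = -pc1
        for b, v in zip(usable_bins, pc1):
            bin_pc1[(chrom, b)] = float(v)
            bin_label[(chrom, b)] = "A" if v > 0 else "B"

    # per-gene labels: length-weighted mean PC1 over overlapping bins
    gene_pc1: dict[str, float] = {}
    gene_label: dict[str, str] = {}
    res = dataset.resolution
    for g in annotation.genes():
        if g.chrom in unassigned or g.chrom not in dataset.intra:
            continue
        total_w = 0.0
        acc = 0.0
        for b in _gene_bins(g, res):
            key = (g.chrom, b)
            if key not in bin_pc1:
                continue
            lo = max(g.start, b * res)
            hi = min(g.end, (b + 1) * res)
            w = max(hi - lo, 1)
            acc += w * bin_pc1[key]
            total_w += w
        if total_w > 0:
            v = acc / total_w
            gene_pc1[g.gene_id] = v
            gene_label[g.gene_id] = "A" if v > 0 else "B"

    if unassigned:
        logger.info("assign_compartments: %d chromosomes unassigned: %s",
                    len(unassigned), sorted(unassigned))
    return CompartmentAssignment(
        resolution=dataset.resolution,
        bin_pc1=bin_pc1,
        bin_label=bin_label,
        gene_pc1=gene_pc1,
        gene_label=gene_label,
        unassigned_chroms=unassigned,
    )


def map_calls_to_genes(
    calls: Sequence[InteractionCall],
    annotation: GeneAnnotation,
    cfg: RunConfig,
    tandem_pairs: Optional[set[tuple[str, str]]] = None,
    cell_line: str = "",
) -> ProximityGraph:
    """Map significant bin pairs to the spatially proximal gene-pair set.

    A gene maps to a bin if its body extended 2 kb upstream overlaps the
    bin.  Every significant bin pair contributes all cross pairs between
    its two bins' gene lists; self-pairs are dropped.  With
    ``cfg.exclude_tandem_pairs`` set, pairs found in ``tandem_pairs`` (a
    tandem-duplicate pair list) are removed.
    """
    index = _bin_gene_index(annotation, cfg.resolution)
    graph = ProximityGraph(cell_line=cell_line, resolution=cfg.resolution)
    for call in calls:
        genes_a = index.get((call.chrom_a, call.bin_a), [])
        genes_b = index.get((call.chrom_b, call.bin_b), [])
        for ga in genes_a:
            for gb in genes_b:
                if ga == gb:
                    continue
                inter = annotation[ga].chrom != annotation[gb].chrom
                graph.add_pair(ga, gb, inter)
    n_before = len(graph)
    if cfg.exclude_tandem_pairs and tandem_pairs:
        canon = {canonical_pair(a, b) for a, b in tandem_pairs if a != b}
        for pair in list(graph.pairs):
            if pair in canon:
                del graph.pairs[pair]
        graph._adjacency = None
        logger.info("map_calls_to_genes: removed %d tandem-duplicate pairs",
                    n_before - len(graph))
    logger.info("map_calls_to_genes: %d calls -> %d gene pairs", len(calls), len(graph))
    return graph


@dataclass
class ActiveUniverse:
    """Everything downstream of the A-compartment filter."""

    annotation: GeneAnnotation
    sgp: Optional[ProximityGraph] = None
    pathways: Optional[list[Pathway]] = None


def restrict_to_active(
    compartments: CompartmentAssignment,
    annotation: GeneAnnotation,
    sgp: Optional[ProximityGraph] = None,
    pathways: Optional[Iterable[Pathway]] = None,
) -> ActiveUniverse:
    """Filter the gene universe, SGP pairs and pathway memberships to
    A-compartment genes."""
    active = compartments.active_genes() & set(annotation)
    filtered_annotation = annotation.subset(active)
    logger.info("restrict_to_active: %d / %d genes kept", len(active), len(annotation))

    filtered_sgp = None
    if sgp is not None:
        filtered_sgp = sgp.subset_genes(active)
        logger.info("restrict_to_active: %d / %d SGP pairs kept", len(filtered_sgp), len(sgp))

    filtered_pathways = None
    if pathways is not None:
        filtered_pathways = []
        for p in pathways:
            kept = p.genes & active
            if kept:
                filtered_pathways.append(p.restrict(active))
        logger.info("restrict_to_active: %d pathways retain at least one gene",
                    len(filtered_pathways))
    return ActiveUniverse(filtered_annotation, filtered_sgp, filtered_pathways)
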