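"""Synthetic Hi-C study generator with planted ground truth.

Everything the analysis consumes can be generated here with known truth:

* a genome of non-overlapping genes on a few chromosomes, denser in the
  A-compartment blocks (as active chromatin is in real genomes);
* a binned contact map with power-law distance decay, a two-compartment
  plaid pattern, Poisson count noise, a flat inter-chromosomal background,
  and an excess contact rate planted on bin pairs hosting two genes of the
  same pathway;
* expression elevated for planted-proximal genes with an extra boost for
  proximal genes sharing a pathway;
* protein-protein interaction edges drawn per pair class with class-specific
  enrichment over a background rate;
* layered directed pathway graphs (optionally with cycles) whose upper
  levels preferentially hold the planted-proximal genes.

Each generator is deterministic given the spec's seed; independent
sub-streams keep the stages decoupled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np

from .hic import ContactMatrix, HiCDataset, InterContactMatrix
from .types import Gene, GeneAnnotation, GenePair, Pathway, ProximityGraph, canonical_pair

# sub-stream tags so each generator has its own reproducible stream
_STREAM_GENOME = 1
_STREAM_PATHWAYS = 2
_STREAM_MATRIX = 3
_STREAM_EXPRESSION = 4
_STREAM_PPI = 5
_STREAM_DAG = 6


@dataclass
class SimulationSpec:
    """Parameters of the synthetic study.

    Defaults describe a small three-chromosome genome (10 Mb each, 100 kb
    bins, 200 genes per chromosome with log-normal lengths of median 10 kb)
    carrying 20 disjoint planted pathways whose co-pathway bin pairs
    receive a five-fold contact excess; expression and PPI effects follow
    the planted proximity.  Setting ``proximity_effect`` and
    ``compartment_contrast`` to 1 gives a pure distance-decay null.
    """

    n_chroms: int = 3
    chrom_length: int = 10_000_000
    n_genes_per_chrom: int = 200
    gene_length_log_mean: float = math.log(10_000)
    gene_length_log_sd: float = 0.5
    resolution: int = 100_000
    decay_exponent: float = 1.0
    base_contacts: float = 50.0
    compartment_block_size: int = 20  # bins per A/B block
    compartment_contrast: float = 3.0  # same-compartment contact boost
    gene_density_bias: float = 0.7  # fraction of genes placed in A blocks
    inter_rate_fraction: float = 0.02  # flat inter-chrom rate as fraction of base
    n_pathways: int = 20
    pathway_size_range: tuple[int, int] = (10, 20)
    proximity_effect: Union[float, Mapping[str, float]] = 5.0
    pathway_proximal_fraction: float = 0.6  # fraction of pathway genes planted proximal
    expression_log_mean: float = 1.0
    expression_log_sd: float = 1.0
    expression_proximal_boost: float = 2.0
    expression_intra_pathway_boost: Union[float, Mapping[str, float]] = 1.5
    ppi_background_rate: float = 0.01
    ppi_class_enrichment: dict[str, float] = field(
        default_factory=lambda: {"I": 10.0, "II": 5.0, "III": 4.0, "IV": 2.0, "V": 1.0}
    )
    hierarchy_depth: int = 4
    hierarchy_back_edge_prob: float = 0.1
    hierarchy_proximal_bias: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.resolution <= 0 or self.chrom_length % self.resolution:
            raise ValueError("chrom_length must be a positive multiple of resolution")
        if not (0 <= self.gene_density_bias <= 1):
            raise ValueError("gene_density_bias must be a probability")
        if not (0 <= self.hierarchy_proximal_bias <= 1):
            raise ValueError("hierarchy_proximal_bias must be a probability")
        if not (0 < self.pathway_proximal_fraction <= 1):
            raise ValueError("pathway_proximal_fraction must be in (0, 1]")
        if not (0 < self.ppi_background_rate <= 1):
            raise ValueError("ppi_background_rate must be in (0, 1]")
        effects = (
            self.proximity_effect.values()
            if isinstance(self.proximity_effect, Mapping)
            else [self.proximity_effect]
        )
        if any(e < 1 for e in effects):
            raise ValueError("proximity_effect must be >= 1")
        lo, hi = self.pathway_size_range
        if lo < 1 or hi < lo:
            raise ValueError("invalid pathway_size_range")

    @property
    def n_bins(self) -> int:
        return self.chrom_length // self.resolution

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chroms)]

    def bin_compartment(self, b: int) -> str:
        """True compartment of a bin: alternating blocks starting with A."""
        return "A" if (b // self.compartment_block_size) % 2 == 0 else "B"

    def rng(self, *stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, *stream])

    def pathway_effect(self, pathway_id: str) -> float:
        if isinstance(self.proximity_effect, Mapping):
            return float(self.proximity_effect[pathway_id])
        return float(self.proximity_effect)

    def pathway_expression_boost(self, pathway_id: str) -> float:
        if isinstance(self.expression_intra_pathway_boost, Mapping):
            return float(self.expression_intra_pathway_boost[pathway_id])
        return float(self.expression_intra_pathway_boost)


@dataclass
class SimulationTruth:
    """Planted ground truth produced alongside the contact map."""

    bin_compartment: dict[tuple[str, int], str]
    planted_bin_pairs: dict[tuple[str, int, str, int], float]  # -> planted effect
    gene_bin: dict[str, tuple[str, int]]
    sgp: ProximityGraph  # all gene pairs hosted by a planted bin pair
    intra_pathway_pairs: set[GenePair]  # truth pairs sharing a planted pathway
    planted_members: dict[str, frozenset[str]]  # pathway -> genes planted proximal

    def proximal_genes(self) -> set[str]:
        return self.sgp.genes()

    def intra_pathway_genes(self) -> set[str]:
        out: set[str] = set()
        for a, b in self.intra_pathway_pairs:
            out.add(a)
            out.add(b)
        return out


def _compartment_segments(spec: SimulationSpec) -> dict[str, list[tuple[int, int]]]:
    """Genomic intervals of A and B blocks (identical on every chromosome)."""
    segs: dict[str, list[tuple[int, int]]] = {"A": [], "B": []}
    block_bp = spec.compartment_block_size * spec.resolution
    pos = 0
    label = "A"
    while pos < spec.chrom_length:
        end = min(pos + block_bp, spec.chrom_length)
        segs[label].append((pos, end))
        label = "B" if label == "A" else "A"
        pos = end
    return segs


def _place_in_segments(
    lengths: Sequence[int],
    segments: Sequence[tuple[int, int]],
    rng: np.random.Generator,
) -> list[tuple[int, int]]:
    """Place genes of the given lengths without overlap inside the segments.

    Genes are assigned to segments with probability proportional to the
    remaining free space, then laid out with uniform random gaps.
    Raises if the genes cannot fit.
    """
    free = [end - start for start, end in segments]
    assigned: list[list[int]] = [[] for _ in segments]
    order = rng.permutation(len(lengths))
    for gi in order:
        L = int(lengths[gi])
        weights = np.array([max(f - L, 0) + (1 if f >= L else 0) for f in free], dtype=float)
        if weights.sum() == 0:
            raise ValueError("genes do not fit in chromosome: segment space exhausted")
        seg = int(rng.choice(len(segments), p=weights / weights.sum()))
        assigned[seg].append(gi)
        free[seg] -= L

    placements: list[Optional[tuple[int, int]]] = [None] * len(lengths)
    for seg, gene_idx in enumerate(assigned):
        if not gene_idx:
            continue
        start, end = segments[seg]
        total_len = sum(int(lengths[g]) for g in gene_idx)
        slack = (end - start) - total_len
        # uniform random gaps before each gene
        cuts = np.sort(rng.uniform(0, slack, size=len(gene_idx)))
        gene_idx_sorted = list(gene_idx)
        rng.shuffle(gene_idx_sorted)
        pos = start
        consumed = 0
        for k, gi in enumerate(gene_idx_sorted):
            gstart = start + int(cuts[k]) + consumed
            L = int(lengths[gi])
            placements[gi] = (gstart, gstart + L)
            consumed += L
    return placements  # type: ignore[return-value]


def simulate_genome(spec: SimulationSpec, rng: Optional[np.random.Generator] = None) -> GeneAnnotation:
    """Generate non-overlapping genes, denser in the A blocks.

    Per chromosome, ``gene_density_bias`` of the genes land in A-block
    intervals and the rest in B blocks; lengths are log-normal.  Raises if
    the drawn genes cannot fit into their segments.
    """
    if rng is None:
        rng = spec.rng(_STREAM_GENOME)
    segs = _compartment_segments(spec)
    genes: list[Gene] = []
    for ci, chrom in enumerate(spec.chrom_names()):
        n = spec.n_genes_per_chrom
        lengths = np.maximum(
            rng.lognormal(spec.gene_length_log_mean, spec.gene_length_log_sd, size=n),
            100,
        ).astype(int)
        n_a = int(round(spec.gene_density_bias * n))
        if not segs["B"]:  # short chromosome: a single A block holds everything
            n_a = n
        elif not segs["A"]:
            n_a = 0
        placements = _place_in_segments(lengths[:n_a], segs["A"], rng)
        placements += _place_in_segments(lengths[n_a:], segs["B"], rng)
        order = np.argsort([p[0] for p in placements])
        for serial, k in enumerate(order):
            start, end = placements[k]
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(Gene(f"G{ci + 1}_{serial + 1:04d}", chrom, start, end, strand))
    return GeneAnnotation(genes)


def simulate_pathways(
    annotation: GeneAnnotation,
    spec: SimulationSpec,
    rng: Optional[np.random.Generator] = None,
) -> list[Pathway]:
    """Disjoint planted pathways sampled uniformly from all genes.

    Uniform sampling spreads each pathway over chromosomes in proportion to
    chromosome gene counts, so the chromosome-matched null is non-trivially
    exercised.
    """
    if rng is None:
        rng = spec.rng(_STREAM_PATHWAYS)
    lo, hi = spec.pathway_size_range
    sizes = rng.integers(lo, hi + 1, size=spec.n_pathways)
    if sizes.sum() > len(annotation):
        raise ValueError("not enough genes for the requested disjoint pathways")
    pool = sorted(annotation)
    chosen = rng.choice(len(pool), size=int(sizes.sum()), replace=False)
    pathways = []
    offset = 0
    for k, size in enumerate(sizes):
        ids = frozenset(pool[i] for i in chosen[offset : offset + size])
        offset += size
        pid = f"P{k + 1:02d}"
        pathways.append(Pathway(pid, pid, ids))
    return pathways


def _midpoint_bin(gene: Gene, resolution: int) -> int:
    return ((gene.start + gene.end) // 2) // resolution


def simulate_contact_matrix(
    spec: SimulationSpec,
    annotation: GeneAnnotation,
    pathways: Sequence[Pathway],
    rng: Optional[np.random.Generator] = None,
) -> tuple[HiCDataset, SimulationTruth]:
    """Poisson contact map with distance decay, compartments and planted
    co-pathway contact excess.

    Intra-chromosomal mean at separation d bins is
    ``base_contacts * d^-decay_exponent`` (d=0 uses the d=1 level), times
    ``compartment_contrast`` when the two bins share a true compartment,
    times the pathway's ``proximity_effect`` on bin pairs hosting two genes
    of the same pathway.  Inter-chromosomal pairs use a flat
    ``base_contacts * inter_rate_fraction`` rate (planted effects apply
    there too).  The truth records every planted bin pair, every bin's true
    compartment, and the full set of gene pairs hosted by planted bin
    pairs (the truth SGP set).
    """
    if rng is None:
        rng = spec.rng(_STREAM_MATRIX)
    for p in pathways:
        missing = p.genes - set(annotation)
        if missing:
            raise ValueError(f"pathway {p.pathway_id!r} genes absent from annotation: "
                             f"{sorted(missing)[:3]}...")

    chroms = spec.chrom_names()
    n_bins = spec.n_bins
    gene_bin = {g.gene_id: (g.chrom, _midpoint_bin(g, spec.resolution))
                for g in annotation.genes()}
    bin_comp = {(c, b): spec.bin_compartment(b) for c in chroms for b in range(n_bins)}

    # planted bin pairs: max effect across pathways planting the same pair;
    # only a per-pathway subset of genes (pathway_proximal_fraction) takes
    # part, so non-proximal within-pathway pairs exist as in real studies
    planted: dict[tuple[str, int, str, int], float] = {}
    planted_members: dict[str, frozenset[str]] = {}
    chrom_order = {c: k for k, c in enumerate(chroms)}
    for p in pathways:
        effect = spec.pathway_effect(p.pathway_id)
        all_members = sorted(p.genes)
        n_prox = max(2, int(round(spec.pathway_proximal_fraction * len(all_members))))
        chosen = rng.choice(len(all_members), size=min(n_prox, len(all_members)),
                            replace=False)
        members = sorted(all_members[i] for i in chosen)
        planted_members[p.pathway_id] = frozenset(members)
        if effect == 1.0:
            continue
        for ai in range(len(members)):
            for bi in range(ai + 1, len(members)):
                ca, ba = gene_bin[members[ai]]
                cb, bb = gene_bin[members[bi]]
                if (ca, ba) == (cb, bb):
                    continue  # same-bin co-location needs no planted excess
                if (chrom_order[ca], ba) > (chrom_order[cb], bb):
                    ca, ba, cb, bb = cb, bb, ca, ba
                key = (ca, ba, cb, bb)
                planted[key] = max(planted.get(key, 1.0), effect)

    dataset = HiCDataset(spec.resolution)
    comp_sign = {
        (c, b): 1 if lbl == "A" else -1 for (c, b), lbl in bin_comp.items()
    }
    for chrom in chroms:
        signs = np.array([comp_sign[(chrom, b)] for b in range(n_bins)])
        same_comp = np.equal.outer(signs, signs)
        d = np.abs(np.subtract.outer(np.arange(n_bins), np.arange(n_bins)))
        lam = spec.base_contacts * np.power(np.maximum(d, 1), -spec.decay_exponent)
        lam = np.where(same_comp, lam * spec.compartment_contrast, lam)
        matrix = ContactMatrix(chrom, spec.resolution, n_bins)
        iu, ju = np.triu_indices(n_bins)
        lam_u = lam[iu, ju].copy()
        for k in range(len(iu)):
            key = (chrom, int(iu[k]), chrom, int(ju[k]))
            if key in planted:
                lam_u[k] *= planted[key]
        draws = rng.poisson(lam_u)
        for k in np.nonzero(draws)[0]:
            matrix.counts[(int(iu[k]), int(ju[k]))] = int(draws[k])
        dataset.add_intra(matrix)

    inter_lam = spec.base_contacts * spec.inter_rate_fraction
    for a in range(len(chroms)):
        for b in range(a + 1, len(chroms)):
            ca, cb = chroms[a], chroms[b]
            lam = np.full((n_bins, n_bins), inter_lam)
            for (pca, pba, pcb, pbb), effect in planted.items():
                if pca == ca and pcb == cb:
                    lam[pba, pbb] *= effect
            draws = rng.poisson(lam)
            matrix = InterContactMatrix(ca, cb, spec.resolution, n_bins, n_bins)
            ii, jj = np.nonzero(draws)
            for i, j in zip(ii, jj):
                matrix.counts[(int(i), int(j))] = int(draws[i, j])
            dataset.add_inter(matrix)

    # truth SGP: all gene pairs hosted by a planted bin pair
    bin_genes: dict[tuple[str, int], list[str]] = {}
    for gid, key in gene_bin.items():
        bin_genes.setdefault(key, []).append(gid)
    truth_sgp = ProximityGraph(cell_line="truth", resolution=spec.resolution)
    for (ca, ba, cb, bb) in planted:
        for ga in bin_genes.get((ca, ba), []):
            for gb in bin_genes.get((cb, bb), []):
                if ga != gb:
                    truth_sgp.add_pair(ga, gb, ca != cb)

    membership: dict[str, set[str]] = {}
    for p in pathways:
        for g in p.genes:
            membership.setdefault(g, set()).add(p.pathway_id)
    intra_pairs = {
        pair for pair in truth_sgp.pairs
        if membership.get(pair[0], set()) & membership.get(pair[1], set())
    }

    truth = SimulationTruth(
        bin_compartment=bin_comp,
        planted_bin_pairs=planted,
        gene_bin=gene_bin,
        sgp=truth_sgp,
        intra_pathway_pairs=intra_pairs,
        planted_members=planted_members,
    )
    return dataset, truth


def simulate_expression(
    annotation: GeneAnnotation,
    sgp_truth: ProximityGraph,
    pathways: Sequence[Pathway],
    spec: SimulationSpec,
    rng: Optional[np.random.Generator] = None,
) -> dict[str, float]:
    """Log-normal expression, boosted for planted-proximal genes and boosted
    again for proximal genes sharing a pathway with a proximal partner."""
    if rng is None:
        rng = spec.rng(_STREAM_EXPRESSION)
    membership: dict[str, set[str]] = {}
    for p in pathways:
        for g in p.genes:
            membership.setdefault(g, set()).add(p.pathway_id)

    proximal = sgp_truth.genes()
    intra_gene_pathway: dict[str, str] = {}
    for a, b in sgp_truth.pairs:
        shared = membership.get(a, set()) & membership.get(b, set())
        if shared:
            pid = sorted(shared)[0]
            intra_gene_pathway.setdefault(a, pid)
            intra_gene_pathway.setdefault(b, pid)

    expression: dict[str, float] = {}
    for gid in sorted(annotation):
        value = rng.lognormal(spec.expression_log_mean, spec.expression_log_sd)
        if gid in proximal:
            value *= spec.expression_proximal_boost
        if gid in intra_gene_pathway:
            value *= spec.pathway_expression_boost(intra_gene_pathway[gid])
        expression[gid] = float(value)
    return expression


def simulate_ppi(
    pair_classes: Mapping[str, Iterable[GenePair]],
    spec: SimulationSpec,
    rng: Optional[np.random.Generator] = None,
) -> set[GenePair]:
    """Independent PPI edges per pair with class-specific enrichment.

    ``pair_classes`` maps roman class labels (I..V) to pair collections;
    the edge probability is ``ppi_background_rate`` times the class
    multiplier and must not exceed 1.
    """
    if rng is None:
        rng = spec.rng(_STREAM_PPI)
    edges: set[GenePair] = set()
    for label in sorted(pair_classes):
        mult = spec.ppi_class_enrichment.get(label, 1.0)
        prob = spec.ppi_background_rate * mult
        if prob > 1:
            raise ValueError(f"class {label}: edge probability {prob} exceeds 1")
        for a, b in sorted(pair_classes[label]):
            if rng.random() < prob:
                edges.add(canonical_pair(a, b))
    return edges


def simulate_pathway_dag(
    pathway: Pathway,
    spec: SimulationSpec,
    rng: Optional[np.random.Generator] = None,
    proximal_genes: Optional[set[str]] = None,
    stream: int = 0,
) -> tuple[list[tuple[str, str]], dict[str, int]]:
    """A layered directed pathway graph plus the true per-gene SPL.

    Genes are spread over ``hierarchy_depth`` layers; planted-proximal
    genes land in the top two layers with probability
    ``hierarchy_proximal_bias``.  Each deeper gene receives a parent from
    the layer above, and back-edges (which may create cycles) point from
    deeper layers to layer >= 2 so that the layer index remains the exact
    shortest path length from the synthetic root.
    """
    depth = spec.hierarchy_depth
    if depth < 2:
        raise ValueError("hierarchy_depth must be >= 2")
    genes = sorted(pathway.genes)
    if len(genes) < depth:
        raise ValueError(f"pathway {pathway.pathway_id!r}: need >= {depth} genes")
    if rng is None:
        rng = spec.rng(_STREAM_DAG, stream)
    proximal_genes = proximal_genes or set()

    layer_of: dict[str, int] = {}
    for g in genes:
        if g in proximal_genes and rng.random() < spec.hierarchy_proximal_bias:
            layer_of[g] = int(rng.integers(1, min(2, depth) + 1))
        else:
            layer_of[g] = int(rng.integers(1, depth + 1))

    # every layer must be populated so parents exist; move genes from the
    # fullest layer into any empty one
    layers: dict[int, list[str]] = {k: [] for k in range(1, depth + 1)}
    for g, k in layer_of.items():
        layers[k].append(g)
    for k in range(1, depth + 1):
        while not layers[k]:
            donor = max(layers, key=lambda kk: len(layers[kk]))
            moved = layers[donor].pop(int(rng.integers(len(layers[donor]))))
            layers[k].append(moved)
            layer_of[moved] = k

    edges: list[tuple[str, str]] = []
    for k in range(2, depth + 1):
        for g in layers[k]:
            parents = layers[k - 1]
            edges.append((parents[int(rng.integers(len(parents)))], g))
            if len(parents) > 1 and rng.random() < 0.3:
                second = parents[int(rng.integers(len(parents)))]
                if (second, g) not in edges:
                    edges.append((second, g))
    # back-edges: deeper gene -> strictly shallower target at layer >= 2
    for k in range(3, depth + 1):
        for g in layers[k]:
            if rng.random() < spec.hierarchy_back_edge_prob:
                target_layer = int(rng.integers(2, k))
                targets = layers[target_layer]
                edges.append((g, targets[int(rng.integers(len(targets)))]))

    return edges, dict(layer_of)


def random_pseudo_pathways(
    universe: GeneAnnotation,
    n: int,
    size: int,
    rng: np.random.Generator,
) -> list[Pathway]:
    """Uniform random gene sets, used as null pseudo-pathways in calibration."""
    pool = sorted(universe)
    if size > len(pool):
        raise ValueError("pseudo-pathway size exceeds universe")
    out = []
    for k in range(n):
        ids = frozenset(pool[i] for i in rng.choice(len(pool), size=size, replace=False))
        out.append(Pathway(f"R{k + 1:03d}", f"R{k + 1:03d}", ids))
    return out
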