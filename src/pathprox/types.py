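"""Core domain types shared across the package.

All genomic intervals are 0-based half-open, BED style, regardless of the
dialect of the input file; readers convert at the boundary.  Gene pairs are
always stored unordered as a sorted ``(gene_a, gene_b)`` tuple because both
chromatin contacts and protein-protein interactions are symmetric.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Iterator, Mapping
from dataclasses import dataclass, field
from typing import Optional

import yaml

VALID_STRANDS = {"+", "-", "."}

GenePair = tuple[str, str]


def canonical_pair(a: str, b: str) -> GenePair:
    """Return the unordered canonical form of a gene pair.

    Raises ``ValueError`` for self-pairs; callers that merely want to skip
    them should test ``a == b`` first.
    """
    if a == b:
        raise ValueError(f"self-pair not allowed: {a!r}")
    return (a, b) if a < b else (b, a)


@dataclass(frozen=True, slots=True)
class Gene:
    """A gene interval on a chromosome (0-based half-open)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"gene {self.gene_id!r}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"gene {self.gene_id!r}: invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


class GeneAnnotation(Mapping[str, Gene]):
    """An immutable collection of genes indexed by unique ``gene_id``.

    Serves as the sampling universe for the matched-control null: it knows
    per-chromosome membership and gene lengths.
    """

    def __init__(self, genes: Iterable[Gene]):
        self._genes: dict[str, Gene] = {}
        for g in genes:
            if g.gene_id in self._genes:
                raise ValueError(f"duplicate gene_id {g.gene_id!r}")
            self._genes[g.gene_id] = g
        self._by_chrom: Optional[dict[str, list[Gene]]] = None

    def __getitem__(self, gene_id: str) -> Gene:
        return self._genes[gene_id]

    def __iter__(self) -> Iterator[str]:
        return iter(self._genes)

    def __len__(self) -> int:
        return len(self._genes)

    @property
    def by_chrom(self) -> dict[str, list[Gene]]:
        if self._by_chrom is None:
            grouped: dict[str, list[Gene]] = {}
            for g in self._genes.values():
                grouped.setdefault(g.chrom, []).append(g)
            for genes in grouped.values():
                genes.sort(key=lambda g: (g.start, g.gene_id))
            self._by_chrom = grouped
        return self._by_chrom

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self.by_chrom)

    def chrom_counts(self, gene_ids: Iterable[str]) -> dict[str, int]:
        """Number of the given genes on each chromosome."""
        counts: dict[str, int] = {}
        for gid in gene_ids:
            c = self._genes[gid].chrom
            counts[c] = counts.get(c, 0) + 1
        return counts

    def subset(self, gene_ids: Iterable[str]) -> "GeneAnnotation":
        keep = set(gene_ids)
        return GeneAnnotation(g for gid, g in self._genes.items() if gid in keep)

    def genes(self) -> list[Gene]:
        return list(self._genes.values())


@dataclass(frozen=True)
class Pathway:
    """A named gene set, optionally with directed regulatory edges."""

    pathway_id: str
    name: str
    genes: frozenset[str]
    directed_edges: Optional[tuple[tuple[str, str], ...]] = None

    def __post_init__(self) -> None:
        if len(self.genes) < 1:
            raise ValueError(f"pathway {self.pathway_id!r} has no genes")
        if self.directed_edges:
            for s, t in self.directed_edges:
                if s not in self.genes or t not in self.genes:
                    raise ValueError(
                        f"pathway {self.pathway_id!r}: edge ({s}, {t}) references "
                        "a non-member gene"
                    )

    def restrict(self, gene_ids: Iterable[str]) -> "Pathway":
        """Pathway restricted to a gene universe (edges restricted too)."""
        keep = self.genes & set(gene_ids)
        edges = None
        if self.directed_edges is not None:
            edges = tuple(
                (s, t) for s, t in self.directed_edges if s in keep and t in keep
            )
        return dataclasses.replace(self, genes=frozenset(keep), directed_edges=edges)


@dataclass
class PairEvidence:
    """Supporting evidence for one spatially proximal gene pair."""

    inter_chromosomal: bool
    n_supports: int = 1


class ProximityGraph:
    """The set of significant spatially proximal gene pairs (SGP set).

    Pairs are unordered and unique; self-pairs are rejected.  Each pair
    carries the number of supporting significant bin pairs and whether the
    two genes lie on different chromosomes.
    """

    def __init__(self, cell_line: str = "", resolution: Optional[int] = None):
        self.cell_line = cell_line
        self.resolution = resolution
        self._pairs: dict[GenePair, PairEvidence] = {}
        self._adjacency: Optional[dict[str, set[str]]] = None

    def add_pair(self, a: str, b: str, inter_chromosomal: bool) -> None:
        key = canonical_pair(a, b)
        ev = self._pairs.get(key)
        if ev is None:
            self._pairs[key] = PairEvidence(inter_chromosomal)
        else:
            ev.n_supports += 1
        self._adjacency = None

    @classmethod
    def from_pairs(
        cls,
        pairs: Iterable[GenePair],
        annotation: Optional[GeneAnnotation] = None,
        cell_line: str = "",
        resolution: Optional[int] = None,
    ) -> "ProximityGraph":
        graph = cls(cell_line=cell_line, resolution=resolution)
        for a, b in pairs:
            inter = False
            if annotation is not None and a in annotation and b in annotation:
                inter = annotation[a].chrom != annotation[b].chrom
            graph.add_pair(a, b, inter)
        return graph

    def __contains__(self, pair: GenePair) -> bool:
        a, b = pair
        if a == b:
            return False
        return canonical_pair(a, b) in self._pairs

    def __len__(self) -> int:
        return len(self._pairs)

    @property
    def pairs(self) -> dict[GenePair, PairEvidence]:
        return self._pairs

    def pair_set(self) -> set[GenePair]:
        return set(self._pairs)

    def genes(self) -> set[str]:
        out: set[str] = set()
        for a, b in self._pairs:
            out.add(a)
            out.add(b)
        return out

    @property
    def adjacency(self) -> dict[str, set[str]]:
        if self._adjacency is None:
            adj: dict[str, set[str]] = {}
            for a, b in self._pairs:
                adj.setdefault(a, set()).add(b)
                adj.setdefault(b, set()).add(a)
            self._adjacency = adj
        return self._adjacency

    def partners(self, gene_id: str) -> set[str]:
        return self.adjacency.get(gene_id, set())

    def subset_genes(self, gene_ids: Iterable[str]) -> "ProximityGraph":
        """Keep only pairs with both endpoints in ``gene_ids``."""
        keep = set(gene_ids)
        out = ProximityGraph(cell_line=self.cell_line, resolution=self.resolution)
        for (a, b), ev in self._pairs.items():
            if a in keep and b in keep:
                out._pairs[(a, b)] = PairEvidence(ev.inter_chromosomal, ev.n_supports)
        return out

    def inter_chromosomal_only(self) -> "ProximityGraph":
        out = ProximityGraph(cell_line=self.cell_line, resolution=self.resolution)
        for (a, b), ev in self._pairs.items():
            if ev.inter_chromosomal:
                out._pairs[(a, b)] = PairEvidence(True, ev.n_supports)
        return out


@dataclass
class RunConfig:
    """Tunable thresholds of the analysis pipeline.

    resolution
        Bin size of the contact map in bp.
    interaction_p_threshold, interaction_fdr
        Per-pair Poisson p-value cutoff (default 0.001) and BH FDR cutoff
        (default 0.1) for calling a bin pair significantly interacting.
    n_null_samples
        Number of matched random gene sets drawn for every permutation null
        (default 1000).
    length_tolerance
        Relative gene-length window for matched sampling (default 0.2,
        i.e. a control gene within +/-20% of its target's length).
    z_threshold
        Reporting threshold on permutation Z-scores (default 2).
    pathway_min_size
        Minimum number of pathway genes, after restriction to the active
        universe, for the pathway to be tested (default 10).
    """

    resolution: int = 100_000
    interaction_p_threshold: float = 0.001
    interaction_fdr: float = 0.1
    n_null_samples: int = 1000
    length_tolerance: float = 0.2
    z_threshold: float = 2.0
    pathway_min_size: int = 10
    seed: int = 0
    inter_chromosomal_only: bool = False
    exclude_tandem_pairs: bool = False

    def __post_init__(self) -> None:
        for name in ("interaction_p_threshold", "interaction_fdr"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.n_null_samples < 1:
            raise ValueError("n_null_samples must be >= 1")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if self.length_tolerance <= 0:
            raise ValueError("length_tolerance must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)
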