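"""Readers and writers for the external text formats.

All intervals become 0-based half-open at the reader boundary; gene pairs
are canonicalized unordered; every filtering step logs counts in and out.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

from .hic import ContactMatrix, HiCDataset, InterContactMatrix
from .types import Gene, GeneAnnotation, GenePair, Pathway, RunConfig, canonical_pair

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]


def read_gene_annotation(path: PathLike) -> GeneAnnotation:
    """Read a BED file (>= 6 columns) into a gene annotation.

    Malformed lines are rejected with their line numbers; duplicate gene
    names and empty intervals are errors.
    """
    genes: list[Gene] = []
    errors: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                errors.append(f"line {lineno}: expected >= 6 columns, got {len(fields)}")
                continue
            chrom, start_s, end_s, name, _score, strand = fields[:6]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                errors.append(f"line {lineno}: non-integer coordinates")
                continue
            if start >= end:
                errors.append(f"line {lineno}: start >= end for {name!r}")
                continue
            try:
                genes.append(Gene(name, chrom, start, end, strand))
            except ValueError as exc:
                errors.append(f"line {lineno}: {exc}")
    if errors:
        raise ValueError("malformed BED input:\n  " + "\n  ".join(errors))
    annotation = GeneAnnotation(genes)  # raises on duplicate gene ids
    logger.info("read_gene_annotation: %d genes from %s", len(annotation), path)
    return annotation


def write_gene_annotation(annotation: GeneAnnotation, path: PathLike) -> None:
    with open(path, "w") as fh:
        for g in sorted(annotation.genes(), key=lambda g: (g.chrom, g.start, g.gene_id)):
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")


def read_gene_sets(path: PathLike) -> list[Pathway]:
    """Read GMT gene sets (name, description, tab-separated gene IDs)."""
    pathways: list[Pathway] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3 or not fields[0]:
                raise ValueError(f"line {lineno}: GMT needs a name, description and "
                                 "at least one gene")
            name, desc = fields[0], fields[1]
            genes = frozenset(g for g in fields[2:] if g)
            if not genes:
                raise ValueError(f"line {lineno}: gene set {name!r} has no genes")
            pathways.append(Pathway(name, desc or name, genes))
    logger.info("read_gene_sets: %d sets from %s", len(pathways), path)
    return pathways


def write_gene_sets(pathways: Iterable[Pathway], path: PathLike) -> None:
    with open(path, "w") as fh:
        for p in pathways:
            fh.write("\t".join([p.pathway_id, p.name, *sorted(p.genes)]) + "\n")


def read_pair_list(path: PathLike) -> set[GenePair]:
    """Read a two-column TSV of gene pairs, canonicalized unordered.

    Self-pairs are dropped (and counted in the log).  Used for PPI edge
    lists, tandem-duplicate pairs and precomputed SGP sets.
    """
    pairs: set[GenePair] = set()
    n_self = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"line {lineno}: expected two columns")
            a, b = fields[0], fields[1]
            if a == b:
                n_self += 1
                continue
            pairs.add(canonical_pair(a, b))
    if n_self:
        logger.info("read_pair_list: dropped %d self-pairs from %s", n_self, path)
    logger.info("read_pair_list: %d pairs from %s", len(pairs), path)
    return pairs


def write_pair_list(pairs: Iterable[GenePair], path: PathLike) -> None:
    with open(path, "w") as fh:
        for a, b in sorted(canonical_pair(*p) for p in pairs):
            fh.write(f"{a}\t{b}\n")


def read_directed_edges(path: PathLike) -> list[tuple[str, str]]:
    """Read a directed edge list TSV with header ``source\\ttarget``."""
    edges: list[tuple[str, str]] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if header.split("\t")[:2] != ["source", "target"]:
            raise ValueError(f"expected header 'source\\ttarget', got {header!r}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"line {lineno}: expected two columns")
            edges.append((fields[0], fields[1]))
    return edges


def write_directed_edges(edges: Iterable[tuple[str, str]], path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("source\ttarget\n")
        for s, t in edges:
            fh.write(f"{s}\t{t}\n")


def read_expression(path: PathLike) -> dict[str, float]:
    """Read a two-column expression TSV (``gene_id\\tvalue``).

    Repeated gene rows (e.g. one per transcript) collapse to the maximum
    value per gene.
    """
    expression: dict[str, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"line {lineno}: expected two columns")
            gid, value_s = fields[0], fields[1]
            if lineno == 1 and gid == "gene_id":
                continue
            try:
                value = float(value_s)
            except ValueError:
                raise ValueError(f"line {lineno}: non-numeric expression {value_s!r}")
            if gid in expression:
                expression[gid] = max(expression[gid], value)
            else:
                expression[gid] = value
    logger.info("read_expression: %d genes from %s", len(expression), path)
    return expression


def write_expression(expression: Mapping[str, float], path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tvalue\n")
        for gid in sorted(expression):
            fh.write(f"{gid}\t{expression[gid]:.6g}\n")


def read_gene_list(path: PathLike) -> set[str]:
    """One gene ID per line (e.g. the housekeeping list)."""
    genes: set[str] = set()
    with open(path) as fh:
        for line in fh:
            gid = line.strip()
            if gid and not gid.startswith("#"):
                genes.add(gid)
    logger.info("read_gene_list: %d genes from %s", len(genes), path)
    return genes


def write_gene_list(genes: Iterable[str], path: PathLike) -> None:
    with open(path, "w") as fh:
        for gid in sorted(genes):
            fh.write(gid + "\n")


def read_contacts(path: PathLike, resolution: int, n_bins: Mapping[str, int]) -> HiCDataset:
    """Read sparse contact triplets/quadruplets.

    Intra-chromosomal lines are ``chrom\\tbin_i\\tbin_j\\tcount``;
    inter-chromosomal lines are ``chromA\\tbinA\\tchromB\\tbinB\\tcount``.
    ``n_bins`` gives the bin extent of each chromosome.
    """
    dataset = HiCDataset(resolution)
    for chrom, nb in n_bins.items():
        dataset.add_intra(ContactMatrix(chrom, resolution, nb))
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                if len(fields) == 4:
                    chrom, i, j, c = fields[0], int(fields[1]), int(fields[2]), int(fields[3])
                    dataset.intra[chrom].add(i, j, c)
                elif len(fields) == 5:
                    ca, i, cb, j, c = (fields[0], int(fields[1]), fields[2],
                                       int(fields[3]), int(fields[4]))
                    key = (ca, cb)
                    if key not in dataset.inter:
                        dataset.add_inter(InterContactMatrix(
                            ca, cb, resolution, n_bins[ca], n_bins[cb]))
                    dataset.inter[key].add(i, j, c)
                else:
                    raise ValueError(f"expected 4 or 5 columns, got {len(fields)}")
            except (ValueError, KeyError) as exc:
                raise ValueError(f"line {lineno}: {exc}") from exc
    logger.info("read_contacts: %d reads from %s", dataset.total_reads(), path)
    return dataset


def write_contacts(dataset: HiCDataset, path: PathLike) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(dataset.intra):
            m = dataset.intra[chrom]
            for (i, j) in sorted(m.counts):
                fh.write(f"{chrom}\t{i}\t{j}\t{m.counts[(i, j)]}\n")
        for (ca, cb) in sorted(dataset.inter):
            m = dataset.inter[(ca, cb)]
            for (i, j) in sorted(m.counts):
                fh.write(f"{ca}\t{i}\t{cb}\t{j}\t{m.counts[(i, j)]}\n")


def write_manifest(
    path: PathLike,
    config: RunConfig,
    inputs: Mapping[str, str],
    extra: Optional[Mapping[str, object]] = None,
) -> None:
    """JSON run manifest: inputs, configuration, seed and package version."""
    from . import __version__

    manifest = {
        "package": "pathprox",
        "version": __version__,
        "config": asdict(config),
        "inputs": dict(inputs),
    }
    if extra:
        manifest.update(extra)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
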