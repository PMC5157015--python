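"""Write a simulated study to the on-disk text formats and read it back.

Shows the external interfaces: BED annotation, GMT gene sets, sparse
contact triplets/quadruplets, expression TSV, pair lists, and the JSON
run manifest.
"""

import tempfile
from pathlib import Path

import pathprox as pp
from pathprox import io as ppio

spec = pp.SimulationSpec(seed=1, n_chroms=2, chrom_length=3_000_000,
                         n_genes_per_chrom=60, n_pathways=4,
                         pathway_size_range=(8, 10))
study = pp.simulate_study(spec)

out = Path(tempfile.mkdtemp(prefix="pathprox_example_"))
ppio.write_gene_annotation(study.annotation, out / "genes.bed")
ppio.write_gene_sets(study.pathways, out / "pathways.gmt")
ppio.write_contacts(study.dataset, out / "contacts.tsv")
ppio.write_expression(study.expression, out / "expression.tsv")
ppio.write_pair_list(study.truth.sgp.pair_set(), out / "truth_sgp.tsv")
cfg = pp.RunConfig(seed=1)
ppio.write_manifest(out / "manifest.json", cfg,
                    {name: str(out / name) for name in
                     ("genes.bed", "pathways.gmt", "contacts.tsv")})

ann = ppio.read_gene_annotation(out / "genes.bed")
pathways = ppio.read_gene_sets(out / "pathways.gmt")
n_bins = {c: m.n_bins for c, m in study.dataset.intra.items()}
contacts = ppio.read_contacts(out / "contacts.tsv", spec.resolution, n_bins)
expr = ppio.read_expression(out / "expression.tsv")
sgp_pairs = ppio.read_pair_list(out / "truth_sgp.tsv")

print(f"wrote and re-read: {len(ann)} genes, {len(pathways)} pathways, "
      f"{contacts.total_reads()} reads, {len(expr)} expression values, "
      f"{len(sgp_pairs)} SGP pairs")
print(f"files under {out}")
assert set(ann) == set(study.annotation)
assert contacts.total_reads() == study.dataset.total_reads()
print("round trip exact")
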