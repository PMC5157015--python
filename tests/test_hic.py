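import itertools
import math

import numpy as np
import pytest
from scipy import stats

import pathprox as pp
from pathprox.hic import ContactMatrix, HiCDataset, _gene_bins, fit_background


def uniform_dataset(n_bins=30, count=3, resolution=100_000):
    ds = HiCDataset(resolution)
    m = ContactMatrix("chr1", resolution, n_bins)
    for i in range(n_bins):
        for j in range(i, n_bins):
            m.counts[(i, j)] = count
    ds.add_intra(m)
    return ds


class TestFitBackground:
    def test_uniform_matrix_gives_equal_expectations(self):
        ds = uniform_dataset()
        model = fit_background(ds)
        e = [model.expected_intra("chr1", i, j)
             for i in range(30) for j in range(i, 30)]
        assert np.allclose(e, e[0], rtol=1e-6)
        assert e[0] == pytest.approx(3.0, rel=0.01)

    def test_power_law_decay_recovered(self):
        # fitted f(d) should follow the generator's closed-form d^-1 decay
        # within 10% over a decade of distances
        spec = pp.SimulationSpec(seed=4, proximity_effect=1.0,
                                 compartment_contrast=1.0, base_contacts=80.0)
        study = pp.simulate_study(spec)
        model = fit_background(study.dataset)
        f1 = model.f(1)
        for d in (2, 3, 5, 8, 10):
            assert model.f(d) / f1 == pytest.approx(1.0 / d, rel=0.1)

    def test_doubling_counts_doubles_expectations(self):
        ds = uniform_dataset(count=4)
        ds2 = uniform_dataset(count=8)
        m1 = fit_background(ds)
        m2 = fit_background(ds2)
        for i, j in [(0, 5), (3, 17), (10, 10)]:
            assert m2.expected_intra("chr1", i, j) == pytest.approx(
                2 * m1.expected_intra("chr1", i, j), rel=1e-6)

    def test_expected_counts_sum_to_total(self):
        spec = pp.SimulationSpec(seed=9)
        study = pp.simulate_study(spec)
        model = fit_background(study.dataset)
        total = 0.0
        for chrom, m in study.dataset.intra.items():
            for i in range(m.n_bins):
                for j in range(i, m.n_bins):
                    total += model.expected_intra(chrom, i, j)
        for (ca, cb), m in study.dataset.inter.items():
            for i in range(m.n_bins_a):
                for j in range(m.n_bins_b):
                    total += model.expected_inter(ca, i, cb, j)
        assert total == pytest.approx(study.dataset.total_reads(), rel=0.01)

    def test_all_zero_matrix_rejected(self):
        ds = HiCDataset(100_000)
        ds.add_intra(ContactMatrix("chr1", 100_000, 10))
        with pytest.raises(ValueError):
            fit_background(ds)


class TestCallInteractions:
    def test_poisson_tail_for_count_at_expectation(self):
        # every pair observed at its expectation: p = P(Poisson(3) >= 3),
        # hand-computed 1 - e^-3 (1 + 3 + 4.5) = 0.576810; nothing is called
        ds = uniform_dataset(count=3)
        cfg = pp.RunConfig()
        model = fit_background(ds)
        tested = pp.call_interactions(ds, model, cfg, significant_only=False)
        assert tested
        for t in tested:
            assert t.p == pytest.approx(0.576810, abs=0.002)
        assert pp.call_interactions(ds, model, cfg) == []

    def test_zero_counts_not_tested(self):
        ds = uniform_dataset(count=2)
        del ds.intra["chr1"].counts[(0, 1)]
        model = fit_background(ds)
        tested = pp.call_interactions(ds, model, pp.RunConfig(), significant_only=False)
        assert all((t.bin_a, t.bin_b) != (0, 1) for t in tested)

    def test_enrichment_and_q_monotonicity(self):
        ds = uniform_dataset(count=3)
        ds.intra["chr1"].counts[(2, 20)] = 40  # a strongly enriched pair
        model = fit_background(ds)
        calls = pp.call_interactions(ds, model, pp.RunConfig())
        assert len(calls) == 1
        call = calls[0]
        assert (call.bin_a, call.bin_b) == (2, 20)
        # the spike inflates its own background in this tiny matrix, so the
        # enrichment is below the naive 40/3 but still well above 1
        assert call.enrichment > 2
        assert call.q >= call.p

    def test_call_set_invariant_under_bin_relabeling(self):
        # reversing the bin order reverses the called coordinates exactly
        spec = pp.SimulationSpec(seed=6, n_chroms=1, chrom_length=5_000_000,
                                 n_genes_per_chrom=80, n_pathways=3,
                                 pathway_size_range=(8, 8))
        study = pp.simulate_study(spec)
        ds = study.dataset
        nb = ds.intra["chr1"].n_bins
        rev = HiCDataset(ds.resolution)
        rm = ContactMatrix("chr1", ds.resolution, nb)
        for (i, j), c in ds.intra["chr1"].counts.items():
            ri, rj = nb - 1 - j, nb - 1 - i
            rm.counts[(ri, rj)] = c
        rev.add_intra(rm)
        cfg = pp.RunConfig()
        calls = {(c.bin_a, c.bin_b)
                 for c in pp.call_interactions(ds, fit_background(ds), cfg)}
        rcalls = {(nb - 1 - c.bin_b, nb - 1 - c.bin_a)
                  for c in pp.call_interactions(rev, fit_background(rev), cfg)}
        assert calls == rcalls


class TestAssignCompartments:
    def test_two_block_structure_recovered(self, planted_study, planted_calls):
        comp = planted_calls.compartments
        truth = planted_study.truth.bin_compartment
        labelled = [(k, lbl) for k, lbl in comp.bin_label.items()]
        acc = sum(1 for k, lbl in labelled if truth[k] == lbl) / len(labelled)
        assert acc >= 0.95

    def test_single_block_flagged_unassigned(self, toy_annotation):
        ds = uniform_dataset(n_bins=20)
        comp = pp.assign_compartments(ds, toy_annotation, pp.RunConfig())
        assert comp.unassigned_chroms == {"chr1"}
        assert comp.bin_label == {}

    def test_every_covered_gene_labelled(self, planted_study, planted_calls):
        comp = planted_calls.compartments
        for g in planted_study.annotation.genes():
            if g.chrom not in comp.unassigned_chroms:
                assert g.gene_id in comp.gene_label


class TestMapCallsToGenes:
    def test_cross_product_of_bin_gene_lists(self):
        genes = [pp.Gene("G1", "chr1", 10_000, 20_000),
                 pp.Gene("G2", "chr1", 510_000, 520_000),
                 pp.Gene("G3", "chr1", 530_000, 540_000)]
        ann = pp.GeneAnnotation(genes)
        cfg = pp.RunConfig(resolution=100_000)
        call = pp.InteractionCall("chr1", 0, "chr1", 5, 10, 1.0, 1e-6, 1e-5)
        sgp = pp.map_calls_to_genes([call], ann, cfg)
        assert sgp.pair_set() == {("G1", "G2"), ("G1", "G3")}

    def test_single_sided_bin_pair_yields_nothing(self):
        ann = pp.GeneAnnotation([pp.Gene("G1", "chr1", 10_000, 20_000)])
        cfg = pp.RunConfig(resolution=100_000)
        call = pp.InteractionCall("chr1", 0, "chr1", 5, 10, 1.0, 1e-6, 1e-5)
        assert len(pp.map_calls_to_genes([call], ann, cfg)) == 0

    def test_matches_brute_force_overlap_enumeration(self):
        rng = np.random.default_rng(12)
        genes = []
        for k in range(25):
            start = int(rng.integers(0, 900_000))
            genes.append(pp.Gene(f"G{k}", "chr1", start,
                                 start + int(rng.integers(5_000, 120_000))))
        ann = pp.GeneAnnotation(genes)
        cfg = pp.RunConfig(resolution=100_000)
        calls = [pp.InteractionCall("chr1", int(i), "chr1", int(j), 5, 1.0, 1e-5, 1e-4)
                 for i, j in [(0, 4), (2, 7), (3, 9)]]
        sgp = pp.map_calls_to_genes(calls, ann, cfg)

        def overlaps(gene, b):  # brute-force oracle: promoter-extended overlap
            lo, hi = b * cfg.resolution, (b + 1) * cfg.resolution
            return max(gene.start - 2_000, 0) < hi and gene.end > lo

        expected = set()
        for c in calls:
            for ga, gb in itertools.product(genes, genes):
                if ga.gene_id != gb.gene_id and overlaps(ga, c.bin_a) and overlaps(gb, c.bin_b):
                    expected.add(pp.canonical_pair(ga.gene_id, gb.gene_id))
        assert sgp.pair_set() == expected

    def test_tandem_pairs_removed_when_configured(self):
        genes = [pp.Gene("G1", "chr1", 10_000, 20_000),
                 pp.Gene("G2", "chr1", 510_000, 520_000)]
        ann = pp.GeneAnnotation(genes)
        cfg = pp.RunConfig(resolution=100_000, exclude_tandem_pairs=True)
        call = pp.InteractionCall("chr1", 0, "chr1", 5, 10, 1.0, 1e-6, 1e-5)
        sgp = pp.map_calls_to_genes([call], ann, cfg, tandem_pairs={("G2", "G1")})
        assert len(sgp) == 0


class TestRestrictToActive:
    def test_mixed_labels_filtered_like_manual_set_arithmetic(self, toy_annotation, toy_sgp):
        labels = {g: ("B" if g in {"g2", "g4", "g7", "g10"} else "A")
                  for g in toy_annotation}
        comp = pp.CompartmentAssignment(100_000, {}, {}, {}, labels)
        pathways = [pp.Pathway("P1", "P1", frozenset({"g1", "g2", "g3"}))]
        active = pp.restrict_to_active(comp, toy_annotation, sgp=toy_sgp,
                                       pathways=pathways)
        assert set(active.annotation) == {"g1", "g3", "g5", "g6", "g8", "g9"}
        assert active.sgp.pair_set() == {("g1", "g6")}
        assert active.pathways[0].genes == {"g1", "g3"}

    def test_all_active_is_identity(self, toy_annotation, toy_sgp):
        labels = {g: "A" for g in toy_annotation}
        comp = pp.CompartmentAssignment(100_000, {}, {}, {}, labels)
        active = pp.restrict_to_active(comp, toy_annotation, sgp=toy_sgp)
        assert set(active.annotation) == set(toy_annotation)
        assert active.sgp.pair_set() == toy_sgp.pair_set()
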