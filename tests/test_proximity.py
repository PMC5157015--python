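import itertools
import logging

import numpy as np
import pytest
from scipy import stats

import pathprox as pp
from pathprox.proximity import MatchedSampler


class TestEdgeFraction:
    def test_complete_graph_is_one(self):
        genes = [f"g{i}" for i in range(5)]
        sgp = pp.ProximityGraph.from_pairs(itertools.combinations(genes, 2))
        assert pp.edge_fraction(genes, sgp) == 1.0

    def test_two_of_six_pairs(self):
        sgp = pp.ProximityGraph.from_pairs([("g1", "g2"), ("g3", "g4")])
        assert pp.edge_fraction(["g1", "g2", "g3", "g4"], sgp) == pytest.approx(1 / 3)

    def test_no_pairs_is_zero(self):
        sgp = pp.ProximityGraph()
        assert pp.edge_fraction(["a", "b", "c"], sgp) == 0.0

    def test_fewer_than_two_genes_rejected(self):
        with pytest.raises(ValueError):
            pp.edge_fraction(["a"], pp.ProximityGraph())


class TestMatchedSampling:
    def test_per_chromosome_counts_exact(self, toy_annotation):
        rng = np.random.default_rng(0)
        targets = ["g1", "g2", "g3", "g6", "g7"]  # 3 on chr1, 2 on chr2
        for _ in range(50):
            sample = pp.sample_matched_set(targets, toy_annotation, rng=rng)
            assert toy_annotation.chrom_counts(sample) == {"chr1": 3, "chr2": 2}

    def test_candidate_outside_tolerance_never_drawn(self):
        # target length 1000: candidate 1250 exceeds the 20% window (1250 > 1200)
        genes = [pp.Gene("t", "chr1", 0, 1000),
                 pp.Gene("ok", "chr1", 2000, 3150),  # 1150 admissible
                 pp.Gene("far", "chr1", 5000, 6250)]  # 1250 excluded
        ann = pp.GeneAnnotation(genes)
        rng = np.random.default_rng(1)
        draws = {pp.sample_matched_set(["t"], ann, rng=rng)[0] for _ in range(200)}
        assert "far" not in draws
        assert draws <= {"t", "ok"}

    def test_uniform_draw_over_equal_length_candidates(self):
        # all candidates share the target's length: draws should be uniform
        genes = [pp.Gene(f"g{i}", "chr1", 10_000 * i, 10_000 * i + 1000)
                 for i in range(10)]
        ann = pp.GeneAnnotation(genes)
        rng = np.random.default_rng(2)
        counts = {g: 0 for g in ann}
        n = 10_000
        for _ in range(n):
            counts[pp.sample_matched_set(["g0"], ann, rng=rng)[0]] += 1
        chi2 = sum((c - n / 10) ** 2 / (n / 10) for c in counts.values())
        assert stats.chi2.sf(chi2, df=9) > 0.001

    def test_tolerance_relaxation_then_error(self):
        rng = np.random.default_rng(3)
        # candidate at 1.7x target length: admissible only after doubling
        # the 20% window twice (0.2 -> 0.4 -> 0.8)
        ann = pp.GeneAnnotation([pp.Gene("t", "chr1", 0, 1000),
                                 pp.Gene("near", "chr1", 5000, 6700)])
        sampler = MatchedSampler(ann, tol=0.2)
        assert sampler.sample(["t"], rng, exclude={"t"}) == ["near"]
        assert sampler.n_relaxed == 1
        # candidate at 1.9x: outside even the twice-doubled window -> error
        ann2 = pp.GeneAnnotation([pp.Gene("t", "chr1", 0, 1000),
                                  pp.Gene("far", "chr1", 5000, 6900)])
        sampler2 = MatchedSampler(ann2, tol=0.2)
        with pytest.raises(ValueError, match="chr1.*'t'"):
            sampler2.sample(["t"], rng, exclude={"t"})

    def test_sampling_constraints_hold_for_every_emitted_sample(self, planted_study):
        # 100% of samples satisfy per-chromosome counts and the 20% window
        ann = planted_study.annotation
        sampler = MatchedSampler(ann, tol=0.2)
        rng = np.random.default_rng(4)
        targets = sorted(planted_study.pathways[0].genes)
        target_counts = ann.chrom_counts(targets)
        for _ in range(100):
            sample = sampler.sample(targets, rng)
            assert ann.chrom_counts(sample) == target_counts
        assert sampler.n_relaxed == 0


class TestEfZscore:
    def test_empty_sgp_degenerate_null(self, toy_annotation, fast_cfg):
        pathway = pp.Pathway("P1", "P1", frozenset({"g1", "g2", "g3", "g6"}))
        res = pp.ef_zscore(pathway, pp.ProximityGraph(), toy_annotation, fast_cfg)
        assert res.observed_ef == 0.0
        assert not res.z_defined
        assert res.empirical_p == 1.0

    def test_deterministic_under_seed(self, planted_study, planted_calls):
        cfg = pp.RunConfig(n_null_samples=100, seed=5)
        p = planted_study.pathways[0]
        r1 = pp.ef_zscore(p, planted_calls.sgp, planted_study.annotation, cfg)
        r2 = pp.ef_zscore(p, planted_calls.sgp, planted_study.annotation, cfg)
        assert r1 == r2

    def test_pathway_below_min_size_rejected(self, toy_annotation, fast_cfg):
        pathway = pp.Pathway("P1", "P1", frozenset({"g1", "g2"}))
        with pytest.raises(ValueError, match="min"):
            pp.ef_zscore(pathway, pp.ProximityGraph(), toy_annotation, fast_cfg)

    def test_zscore_invariant_to_gene_relabeling(self, planted_study, planted_calls):
        # relabeling all gene IDs (lengths unique) leaves z unchanged
        ann = planted_study.annotation
        mapping = {gid: f"X{idx:04d}" for idx, gid in enumerate(sorted(ann))}
        relabelled = pp.GeneAnnotation(
            pp.Gene(mapping[g.gene_id], g.chrom, g.start, g.end, g.strand)
            for g in ann.genes())
        sgp2 = pp.ProximityGraph.from_pairs(
            [(mapping[a], mapping[b]) for a, b in planted_calls.sgp.pairs],
            annotation=relabelled)
        p = planted_study.pathways[3]
        p2 = pp.Pathway(p.pathway_id, p.name, frozenset(mapping[g] for g in p.genes))
        cfg = pp.RunConfig(n_null_samples=200, seed=6)
        r1 = pp.ef_zscore(p, planted_calls.sgp, ann, cfg)
        r2 = pp.ef_zscore(p2, sgp2, relabelled, cfg)
        assert r1.observed_ef == r2.observed_ef
        assert r1.z == pytest.approx(r2.z, abs=1e-12)

    def test_housekeeping_genes_excluded_before_scoring(self, planted_study, planted_calls):
        cfg = pp.RunConfig(n_null_samples=50, seed=1, pathway_min_size=5)
        p = planted_study.pathways[0]
        hk = set(sorted(p.genes)[:5])
        res = pp.ef_zscores([p], planted_calls.sgp, planted_study.annotation,
                            cfg, housekeeping=hk)
        assert res[0].n_genes_used == len(p.genes) - 5


class TestInterPathway:
    def test_cross_edge_count_brute_force(self, toy_annotation, fast_cfg):
        pa = pp.Pathway("A", "A", frozenset({"g1", "g2", "g3"}))
        pb = pp.Pathway("B", "B", frozenset({"g6", "g7", "g9"}))
        sgp = pp.ProximityGraph.from_pairs(
            [("g1", "g6"), ("g2", "g9"), ("g1", "g2"), ("g6", "g7")])
        res = pp.inter_pathway_zscore(pa, pb, sgp, toy_annotation, fast_cfg)
        # brute force: cross pairs present = (g1,g6) and (g2,g9)
        assert res.observed_cross_edges == 2
        assert res.shared_genes_excluded == 0

    def test_subset_pathway_rejected(self, toy_annotation, fast_cfg):
        pa = pp.Pathway("A", "A", frozenset({"g1", "g2"}))
        pb = pp.Pathway("B", "B", frozenset({"g1", "g2", "g3"}))
        with pytest.raises(ValueError):
            pp.inter_pathway_zscore(pa, pb, pp.ProximityGraph(), toy_annotation, fast_cfg)

    def test_overlap_fraction_intersection_over_min(self, toy_annotation, fast_cfg):
        pa = pp.Pathway("A", "A", frozenset({"g1", "g2", "g3", "g6"}))
        pb = pp.Pathway("B", "B", frozenset({"g3", "g6", "g7", "g8", "g9"}))
        res = pp.inter_pathway_zscore(pa, pb, pp.ProximityGraph.from_pairs([("g1", "g7")]),
                                      toy_annotation, fast_cfg)
        assert res.overlap_fraction == pytest.approx(2 / 4)

    def test_housekeeping_pathway_fully_inside_hk_rejected(self, toy_annotation, fast_cfg):
        hk = {"g1", "g2", "g3", "g4"}
        pathway = pp.Pathway("P", "P", frozenset({"g1", "g2"}))
        with pytest.raises(ValueError):
            pp.housekeeping_proximity(hk, [pathway], pp.ProximityGraph(),
                                      toy_annotation, fast_cfg)

    def test_planted_housekeeping_enrichment_detected(self, planted_study, planted_calls):
        # two planted pathways merged at generation time: treat one as the
        # housekeeping set, the other as a pathway -> strong cross proximity
        # is already present in the called SGP via their planted bin pairs
        study = planted_study
        cfg = pp.RunConfig(n_null_samples=200, seed=2, pathway_min_size=5)
        pa, pb = study.pathways[0], study.pathways[1]
        # cross edges between two planted pathways are NOT planted -> null-ish
        null_res = pp.inter_pathway_zscore(pa, pb, planted_calls.sgp,
                                           study.annotation, cfg)
        # but a pathway against itself split in halves IS enriched
        genes = sorted(study.truth.planted_members[pa.pathway_id] & pa.genes)
        half = len(genes) // 2
        a = pp.Pathway("hkA", "hkA", frozenset(genes[:half]))
        b = pp.Pathway("hkB", "hkB", frozenset(genes[half:]))
        res = pp.inter_pathway_zscore(a, b, planted_calls.sgp, study.annotation, cfg)
        assert res.z > 2
        assert res.z > (null_res.z if null_res.z == null_res.z else 0)


class TestBhFdr:
    def test_worked_step_up_example(self):
        q = pp.bh_fdr([0.01, 0.02, 0.03, 0.5])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.5])

    def test_all_ones(self):
        assert np.allclose(pp.bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_single_p_unchanged(self):
        assert pp.bh_fdr([0.2]) == pytest.approx([0.2])

    @pytest.mark.parametrize("bad", [[0.0], [1.5], [-0.1], [float("nan")]])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            pp.bh_fdr(bad)


class TestFilterIntraChromosomal:
    def test_all_intra_gives_empty(self, toy_annotation):
        sgp = pp.ProximityGraph.from_pairs([("g1", "g2"), ("g3", "g4")],
                                           annotation=toy_annotation)
        assert len(pp.filter_intra_chromosomal(sgp)) == 0

    def test_mixed_keeps_inter_only(self, toy_sgp):
        out = pp.filter_intra_chromosomal(toy_sgp)
        assert out.pair_set() == {("g1", "g6"), ("g2", "g9")}

    def test_idempotent(self, toy_sgp):
        once = pp.filter_intra_chromosomal(toy_sgp)
        twice = pp.filter_intra_chromosomal(once)
        assert once.pair_set() == twice.pair_set()


class TestPowerMonotonicity:
    def test_detection_rate_nondecreasing_in_effect(self):
        # stronger planted contact excess can only help detection
        rates = []
        for effect in (1.0, 2.0, 5.0):
            detected = 0
            total = 0
            for seed in (21, 22):
                spec = pp.SimulationSpec(seed=seed, proximity_effect=effect,
                                         pathway_size_range=(15, 15))
                study = pp.simulate_study(spec)
                cfg = pp.RunConfig(n_null_samples=200, seed=seed)
                pr = pp.call_proximity_graph(study.dataset, study.annotation, cfg)
                res = pp.ef_zscores(study.pathways, pr.sgp, study.annotation, cfg)
                detected += sum(1 for r in res if r.z_defined and r.z > 2)
                total += len(res)
            rates.append(detected / total if total else 0.0)
        assert rates[0] <= rates[1] <= rates[2]
        assert rates[2] > 0.9
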