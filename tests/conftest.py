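import numpy as np
import pytest

import pathprox as pp


@pytest.fixture
def toy_annotation():
    """Ten genes on two chromosomes with varied lengths."""
    genes = [
        pp.Gene("g1", "chr1", 1_000, 11_000, "+"),
        pp.Gene("g2", "chr1", 20_000, 32_000, "-"),
        pp.Gene("g3", "chr1", 50_000, 58_000, "+"),
        pp.Gene("g4", "chr1", 70_000, 90_000, "+"),
        pp.Gene("g5", "chr1", 100_000, 109_000, "-"),
        pp.Gene("g6", "chr2", 5_000, 15_500, "+"),
        pp.Gene("g7", "chr2", 30_000, 41_000, "-"),
        pp.Gene("g8", "chr2", 60_000, 69_000, "+"),
        pp.Gene("g9", "chr2", 80_000, 100_000, "."),
        pp.Gene("g10", "chr2", 120_000, 131_500, "+"),
    ]
    return pp.GeneAnnotation(genes)


@pytest.fixture
def toy_sgp(toy_annotation):
    pairs = [("g1", "g2"), ("g3", "g4"), ("g1", "g6"), ("g7", "g8"), ("g2", "g9")]
    return pp.ProximityGraph.from_pairs(pairs, annotation=toy_annotation)


@pytest.fixture
def fast_cfg():
    """Small-sample config for quick permutation tests."""
    return pp.RunConfig(resolution=100_000, n_null_samples=50, pathway_min_size=3, seed=0)


@pytest.fixture(scope="session")
def planted_study():
    """One default planted study shared by the slower analysis tests."""
    spec = pp.SimulationSpec(seed=7, pathway_size_range=(15, 15))
    return pp.simulate_study(spec)


@pytest.fixture(scope="session")
def planted_calls(planted_study):
    """Background fit, interaction calls and SGP set for the planted study."""
    cfg = pp.RunConfig(resolution=planted_study.spec.resolution, seed=7)
    return pp.call_proximity_graph(
        planted_study.dataset, planted_study.annotation, cfg, with_compartments=True
    )


def make_rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)
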