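"""Convenience wrappers chaining the standard stages of the analysis."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .hic import (
    BackgroundModel,
    CompartmentAssignment,
    HiCDataset,
    InteractionCall,
    assign_compartments,
    call_interactions,
    fit_background,
    map_calls_to_genes,
)
from .simulate import (
    SimulationSpec,
    SimulationTruth,
    simulate_contact_matrix,
    simulate_expression,
    simulate_genome,
    simulate_pathways,
)
from .types import GeneAnnotation, Pathway, ProximityGraph, RunConfig


@dataclass
class SimulatedStudy:
    """A complete synthetic study: inputs plus planted truth."""

    spec: SimulationSpec
    annotation: GeneAnnotation
    pathways: list[Pathway]
    dataset: HiCDataset
    truth: SimulationTruth
    expression: dict[str, float]


def simulate_study(spec: SimulationSpec) -> SimulatedStudy:
    """Genome, pathways, contact map and expression in one call."""
    annotation = simulate_genome(spec)
    pathways = simulate_pathways(annotation, spec)
    dataset, truth = simulate_contact_matrix(spec, annotation, pathways)
    expression = simulate_expression(annotation, truth.sgp, pathways, spec)
    return SimulatedStudy(spec, annotation, pathways, dataset, truth, expression)


@dataclass
class ProximityCallResult:
    model: BackgroundModel
    calls: list[InteractionCall]
    sgp: ProximityGraph
    compartments: Optional[CompartmentAssignment] = None


def call_proximity_graph(
    dataset: HiCDataset,
    annotation: GeneAnnotation,
    cfg: RunConfig,
    with_compartments: bool = False,
    cell_line: str = "",
) -> ProximityCallResult:
    """Background fit, interaction calling and gene mapping in one call."""
    model = fit_background(dataset)
    calls = call_interactions(dataset, model, cfg)
    sgp = map_calls_to_genes(calls, annotation, cfg, cell_line=cell_line)
    compartments = None
    if with_compartments:
        compartments = assign_compartments(dataset, annotation, cfg, model=model)
    return ProximityCallResult(model, calls, sgp, compartments)
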