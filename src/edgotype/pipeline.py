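"""End-to-end analysis: world (or files) -> structural interactome ->
mapped mutations -> edgotype calls -> dispensable-content estimate.

The stages are the same whether the inputs come from a synthetic world or
from files on disk; this module wires them together in memory.
"""

from __future__ import annotations

from dataclasses import dataclass

from .dispensability import (
    DEFAULT_PRIORS,
    DispensabilityModel,
    DispensabilityResults,
    FitnessPriors,
)
from .edgotypes import (
    EdgeticCounts,
    EdgotypeCall,
    call_edgotypes,
    estimate_gamma,
    tally_counts,
)
from .interactome import StructuralPPI, build_structural_interactome
from .mutations import MappedMutation, filter_disease, filter_nondisease, map_mutations
from .structures import compute_interface
from .synthetic import SyntheticWorld

__all__ = ["WorldAnalysis", "build_si_from_world", "map_world_mutations", "analyze_world"]


@dataclass
class WorldAnalysis:
    si: list[StructuralPPI]
    mapped: list[MappedMutation]
    calls: list[EdgotypeCall]
    counts: EdgeticCounts
    gamma: dict[str, tuple[float, float]]  # class -> (estimate, SE)
    results: DispensabilityResults

    @property
    def rate_N(self) -> float:
        return self.counts.rate_N

    @property
    def rate_M(self) -> float:
        return self.counts.rate_M


def build_si_from_world(world: SyntheticWorld) -> list[StructuralPPI]:
    """Interface detection on every generated chain pair, then the full
    alignment/coverage filter chain."""
    catalog = {}
    for chain_a, chain_b in world.structures:
        pair = compute_interface(chain_a, chain_b)
        catalog[(chain_a.structure_id, chain_a.chain_id, chain_b.chain_id)] = (
            pair.interface_a,
            pair.interface_b,
        )
    return build_structural_interactome(world.interactome, world.alignments, catalog)


def map_world_mutations(world: SyntheticWorld) -> list[MappedMutation]:
    """Curation filters followed by flank-verified mapping."""
    disease = filter_disease([m for m in world.mutations if m.mutation_class == "disease"])
    mapped_disease = map_mutations(disease, world.protein_sequences)
    disease_positions = {(m.protein_id, m.protein_position) for m in mapped_disease}
    nondisease = filter_nondisease(
        [m for m in world.mutations if m.mutation_class == "non_disease"],
        disease_positions,
    )
    mapped_nondisease = map_mutations(nondisease, world.protein_sequences)
    return mapped_disease + mapped_nondisease


def analyze_world(
    world: SyntheticWorld,
    method: str = "geometry",
    priors: FitnessPriors = DEFAULT_PRIORS,
    threshold: float = 0.5,
) -> WorldAnalysis:
    """Run the whole pipeline on a synthetic world and fit the model."""
    si = build_si_from_world(world)
    mapped = map_world_mutations(world)
    calls = call_edgotypes(mapped, si, method=method, ddg_table=world.ddg_table, threshold=threshold)
    counts = tally_counts(calls)
    gamma = {}
    if world.ddg_table:
        for cls in ("disease", "non_disease"):
            try:
                gamma[cls] = estimate_gamma(world.ddg_table, mapped, cls, threshold)
            except ValueError:
                pass
    results = DispensabilityModel(counts, priors).fit()
    return WorldAnalysis(si, mapped, calls, counts, gamma, results)
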