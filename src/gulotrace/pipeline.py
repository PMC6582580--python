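"""End-to-end orchestration: search -> flank -> grow -> annotate -> call.

One call analyses one genome assembly against a query protein, optionally
screening reconstructed CDSs against a labelled reference panel for
bacterial contamination, and returns the per-species call together with
all intermediate evidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from gulotrace.core_io import NucSeq, ProtSeq
from gulotrace.genemodel import AnnotateParams, GeneModel, annotate_region
from gulotrace.growmerge import GenomicRegion, grow_sequences
from gulotrace.orthocall import SpeciesCall, call_species, screen_contamination
from gulotrace.tsearch import HSP, SearchParams, extract_flanked_regions, search_genome


@dataclass
class PipelineResult:
    species: str
    hsps: list[HSP]
    regions: list[GenomicRegion]
    models: list[GeneModel]
    call: SpeciesCall
    contamination: list[dict] = field(default_factory=list)


def analyze_genome(query: ProtSeq, scaffolds: list[NucSeq], species: str = "sample",
                   search_params: SearchParams | None = None,
                   annot_params: AnnotateParams | None = None,
                   reference_panel: dict[str, list[NucSeq]] | None = None,
                   min_overlap: int = 2500) -> PipelineResult:
    """Run the full detection pipeline on one assembly."""
    search_params = search_params or SearchParams()
    annot_params = annot_params or AnnotateParams()
    hsps = search_genome(query, scaffolds, search_params)
    regions: list[GenomicRegion] = []
    models: list[GeneModel] = []
    verdicts: list[dict] = []
    if hsps:
        regions = extract_flanked_regions(hsps, scaffolds, search_params.flank)
        regions = grow_sequences(regions, min_overlap)
        for region in regions:
            model = annotate_region(region, query, annot_params)
            if model is None:
                continue
            if reference_panel is not None:
                verdict = screen_contamination(model.cds, reference_panel)
                model.contaminated = verdict["positive"]
                verdicts.append({"region": region.region_id, **verdict})
            models.append(model)
    call = call_species(species, models, hsps, len(query))
    return PipelineResult(species, hsps, regions, models, call, verdicts)
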