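"""Shared fixtures: the synthetic query/reference panel and a seeded corpus
of genomes (intact / fragmented / contaminated / absent) analysed once per
session and reused by recovery, classification and call tests."""

from __future__ import annotations

from dataclasses import dataclass

import pytest

from gulotrace.core_io import ProtSeq
from gulotrace.pipeline import PipelineResult, analyze_genome
from gulotrace.synthgen import (
    GenomeTruth, PlantSpec, contaminate, default_query, fragment_assembly,
    make_reference_panel, synth_absent_genome, synth_genome,
)

N_INTACT = 50
N_PER_MODE = 10


@pytest.fixture(scope="session")
def query() -> ProtSeq:
    return default_query()


@pytest.fixture(scope="session")
def panel():
    return make_reference_panel()


def intact_spec(query: ProtSeq, seed: int) -> PlantSpec:
    """The standard corpus conditions: 1-5 exons, 50-2000 nt introns, both
    strands, every third plant with a lone-ATG first exon."""
    return PlantSpec(
        protein=query,
        exon_count=seed % 5 + 1,
        intron_length_range=(50, 2000),
        strand="-" if seed % 2 else "+",
        lone_atg_first=bool(seed % 3 == 0),
    )


@dataclass
class CorpusEntry:
    seed: int
    truth: GenomeTruth
    result: PipelineResult


@pytest.fixture(scope="session")
def intact_corpus(query, panel) -> list[CorpusEntry]:
    out = []
    for seed in range(N_INTACT):
        gt = synth_genome(intact_spec(query, seed), background_length=12000,
                          gc=0.45, seed=seed)
        res = analyze_genome(query, gt.scaffolds, f"intact_{seed}",
                             reference_panel=panel)
        out.append(CorpusEntry(seed, gt, res))
    return out


@pytest.fixture(scope="session")
def fragmented_corpus(query, panel) -> list[CorpusEntry]:
    out = []
    for seed in range(N_PER_MODE):
        spec = intact_spec(query, seed)
        spec.exon_count = seed % 3 + 3  # need >= 3 exons to scatter
        gt = synth_genome(spec, background_length=12000, gc=0.45, seed=seed)
        fr = fragment_assembly(gt, pieces=3, seed=seed)
        res = analyze_genome(query, fr.scaffolds, f"frag_{seed}",
                             reference_panel=panel)
        out.append(CorpusEntry(seed, fr, res))
    return out


@pytest.fixture(scope="session")
def contaminated_corpus(query, panel) -> list[CorpusEntry]:
    out = []
    for seed in range(N_PER_MODE):
        ab = synth_absent_genome(8000, gc=0.45, seed=1000 + seed)
        ct = contaminate(ab, panel["bacterial"][seed % 2], seed=seed)
        res = analyze_genome(query, ct.scaffolds, f"contam_{seed}",
                             reference_panel=panel)
        out.append(CorpusEntry(seed, ct, res))
    return out


@pytest.fixture(scope="session")
def absent_corpus(query, panel) -> list[CorpusEntry]:
    out = []
    for seed in range(N_PER_MODE):
        gt = synth_absent_genome(10000, gc=0.45, seed=2000 + seed)
        res = analyze_genome(query, gt.scaffolds, f"absent_{seed}",
                             reference_panel=panel)
        out.append(CorpusEntry(seed, gt, res))
    return out
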