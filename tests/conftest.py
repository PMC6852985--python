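"""Shared fixtures: one seeded synthetic study reused across the suite."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List

import pytest
from hypothesis import settings

from mirseed import preprocess
from mirseed.conserved_annotation import annotate_tags
from mirseed.core import SequenceTag, merge_tags, tag_count_frame
from mirseed.differential_expression import run_de
from mirseed.novel_discovery import DiscoveryResult, discover
from mirseed.reference_filter import DepurationReport, depure
from mirseed.synthetic_data import (
    LIBRARIES,
    SimulationConfig,
    TruthTable,
    make_libraries,
    make_references,
)

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")

LIB_NAMES = [lib for lib, _g, _r in LIBRARIES]
GROUPS = {lib: geno for lib, geno, _r in LIBRARIES}


@pytest.fixture(scope="session")
def sim_config() -> SimulationConfig:
    return SimulationConfig(seed=11, n_reads_per_library=35_000)


@pytest.fixture(scope="session")
def sim(sim_config):
    refs, truth = make_references(sim_config)
    libraries = make_libraries(sim_config, refs, truth)
    return refs, truth, libraries


@dataclass
class Analysis:
    """All intermediate products of the in-memory pipeline run."""

    config: SimulationConfig
    refs: Dict[str, object]
    truth: TruthTable
    clean: Dict[str, List[str]]
    stats: Dict[str, preprocess.TrimStats]
    per_lib_tags: Dict[str, List[SequenceTag]]
    kept: Dict[str, List[SequenceTag]]
    discarded_reads: Dict[str, int]
    merged: List[SequenceTag]
    depured: List[SequenceTag]
    depuration: DepurationReport
    assignments: dict
    discovery: DiscoveryResult
    de: object


@pytest.fixture(scope="session")
def analysis(sim_config, sim) -> Analysis:
    refs, truth, libraries = sim
    clean, stats, per_lib_tags, kept, discarded = {}, {}, {}, {}, {}
    surviving = set()
    for lib in LIB_NAMES:
        c, s = preprocess.clean_library(iter(libraries[lib]), lib, sim_config.adapter)
        tags = preprocess.collapse(c, lib)
        k, d, _pct = preprocess.filter_min_count(tags)
        clean[lib], stats[lib], per_lib_tags[lib], kept[lib], discarded[lib] = c, s, tags, k, d
        surviving.update(t.sequence for t in k)
    merged = [t for t in merge_tags(per_lib_tags.values()) if t.sequence in surviving]
    depured, report = depure(
        merged, refs["mitochondria"], refs["chloroplast"], refs["ncrna"]
    )
    assignments = annotate_tags(depured, refs["mirna_mature"], refs["mirna_hairpin"])
    non_conserved = [t for t in depured if t.sequence not in assignments]
    discovery = discover(non_conserved, refs["transcriptome"], refs["mirna_mature"])
    counts = tag_count_frame(depured, LIB_NAMES)
    sizes = {lib: int(counts[lib].sum()) for lib in LIB_NAMES}
    de = run_de(counts, sizes, GROUPS, "T", "O")
    return Analysis(
        config=sim_config,
        refs=refs,
        truth=truth,
        clean=clean,
        stats=stats,
        per_lib_tags=per_lib_tags,
        kept=kept,
        discarded_reads=discarded,
        merged=merged,
        depured=depured,
        depuration=report,
        assignments=assignments,
        discovery=discovery,
        de=de,
    )
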