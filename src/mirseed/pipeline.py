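"""End-to-end orchestration: FASTQ libraries in, table-shaped reports out.

Stage order: per-library cleanup and collapapsing, minimum-count
filter, merge, organellar/ncRNA depuration, conserved-miRNA
annotation, degradation-aware novel discovery, differential
expression, target scanning.  Every report file carries a header
comment recording the tool version and the thresholds used.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import pandas as pd
import yaml

from . import __version__
from .core import ConfigurationError, ReferenceSet, merge_tags, tag_count_frame
from . import preprocess
from .io import iter_fastq, read_reference
from .reference_filter import depure
from .conserved_annotation import annotate_tags, consensus_name, summarize_families
from .novel_discovery import discover
from .differential_expression import DeThresholds, run_de
from .target_scoring import ScoringParams, gc_open_energy, link_expression, scan_transcript


@dataclass
class LibrarySpec:
    path: str
    name: str
    genotype: str
    replicate: int


@dataclass
class Thresholds:
    """Every stage threshold in one place (defaults = published values)."""

    min_count: int = 3
    min_length: int = 17
    max_length: int = 33
    quality_cutoff: int = 20
    adapter_min_overlap: int = 8
    subtraction_max_mismatch: int = 0
    conserved_max_mismatch: int = 2
    conserved_min_coverage: float = 0.90
    breadth_threshold: float = 0.8
    max_loci: int = 2
    max_locus_width: int = 30
    merge_gap: int = 5
    max_expectation: float = 2.5
    upe_max: float = 20.0
    p_threshold: float = 0.01
    fc_threshold: float = 2.0


@dataclass
class PipelineConfig:
    libraries: List[LibrarySpec]
    references: Dict[str, str]  # class key -> FASTA path
    outdir: str
    adapter: str
    seed: int = 1
    thresholds: Thresholds = field(default_factory=Thresholds)
    species_prefix: str = "ecu"
    use_accessibility: bool = False
    transcript_presence: Optional[str] = None  # optional TSV: transcript_id <TAB> genotypes

    REQUIRED_REFS = (
        "mitochondria",
        "chloroplast",
        "ncrna",
        "mirna_mature",
        "mirna_hairpin",
        "transcriptome",
    )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        libs = [LibrarySpec(**entry) for entry in raw["libraries"]]
        thresholds = Thresholds(**raw.get("thresholds", {}))
        return cls(
            libraries=libs,
            references=dict(raw["references"]),
            outdir=raw["outdir"],
            adapter=raw["adapter"],
            seed=int(raw.get("seed", 1)),
            thresholds=thresholds,
            species_prefix=raw.get("species_prefix", "ecu"),
            use_accessibility=bool(raw.get("use_accessibility", False)),
            transcript_presence=raw.get("transcript_presence"),
        )

    def validate(self) -> None:
        if len(self.libraries) < 2:
            raise ConfigurationError("at least two libraries are required")
        genotypes = {lib.genotype for lib in self.libraries}
        if len(genotypes) != 2:
            raise ConfigurationError(f"exactly two genotypes expected, got {sorted(genotypes)}")
        for lib in self.libraries:
            if not Path(lib.path).exists():
                raise ConfigurationError(f"missing library file: {lib.path}")
        for key in self.REQUIRED_REFS:
            if key not in self.references:
                raise ConfigurationError(f"missing reference set: {key}")
            if not Path(self.references[key]).exists():
                raise ConfigurationError(f"missing reference file: {self.references[key]}")


@dataclass
class PipelineResult:
    library_description: pd.DataFrame
    length_histogram: pd.DataFrame
    depuration: pd.DataFrame
    conserved_summary: pd.DataFrame
    families: pd.DataFrame
    novel_candidates: pd.DataFrame
    degradation_transcripts: pd.DataFrame
    differential_expression: pd.DataFrame
    target_sites: pd.DataFrame
    interactions: pd.DataFrame
    report_paths: Dict[str, str] = field(default_factory=dict)


def _report_header(config: PipelineConfig) -> str:
    th = " ".join(f"{k}={v}" for k, v in asdict(config.thresholds).items())
    return f"# mirseed v{__version__} seed={config.seed} {th}\n"


def _write_report(df: pd.DataFrame, path: Path, config: PipelineConfig, index=False) -> None:
    with open(path, "w") as fh:
        fh.write(_report_header(config))
        df.to_csv(fh, sep="\t", index=index, lineterminator="\n")


def _load_references(config: PipelineConfig) -> Dict[str, ReferenceSet]:
    kinds = {
        "mitochondria": ("organellar", "both"),
        "chloroplast": ("organellar", "both"),
        "ncrna": ("ncrna", "forward"),
        "mirna_mature": ("mirna-mature", "forward"),
        "mirna_hairpin": ("mirna-hairpin", "forward"),
        "transcriptome": ("transcriptome", "forward"),
    }
    return {
        key: read_reference(config.references[key], key, kind, policy)
        for key, (kind, policy) in kinds.items()
    }


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every stage and write the report bundle to the output directory."""
    config.validate()
    refs = _load_references(config)
    th = config.thresholds
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: Dict[str, str] = {"version": __version__, "status": "running"}
    manifest_path = outdir / "manifest.json"

    def checkpoint(stage: str) -> None:
        manifest[stage] = "done"
        manifest_path.write_text(json.dumps(manifest, indent=2))

    try:
        # --- cleanup, collapse, minimum count -------------------------------
        lib_rows, hist_cols, per_lib_tags = [], {}, []
        surviving: set = set()
        lib_names = [lib.name for lib in config.libraries]
        groups = {lib.name: lib.genotype for lib in config.libraries}
        for spec in config.libraries:
            clean, _stats = preprocess.clean_library(
                iter_fastq(spec.path),
                spec.name,
                config.adapter,
                quality_cutoff=th.quality_cutoff,
                min_overlap=th.adapter_min_overlap,
            )
            tags = preprocess.collapse(clean, spec.name)
            kept, discarded_reads, pct = preprocess.filter_min_count(tags, th.min_count)
            lib_rows.append(asdict(preprocess.summarize_library(clean, spec.name, kept, discarded_reads, pct)))
            hist, _modes = preprocess.length_profile(clean)
            hist_cols[spec.name] = hist
            per_lib_tags.append(tags)
            surviving.update(t.sequence for t in kept)
        library_description = pd.DataFrame(lib_rows)
        length_histogram = pd.DataFrame(hist_cols)
        length_histogram.index.name = "length"
        checkpoint("preprocess")

        # --- depuration ------------------------------------------------------
        # a tag survives when it passes the per-library minimum count in at
        # least one library; counts of surviving tags stay untruncated so
        # replicate variability is not inflated downstream
        tags = [t for t in merge_tags(per_lib_tags) if t.sequence in surviving]
        depured, dep_report = depure(
            tags,
            refs["mitochondria"],
            refs["chloroplast"],
            refs["ncrna"],
            max_mismatch=th.subtraction_max_mismatch,
        )
        depuration = dep_report.to_frame()
        checkpoint("depure")

        # --- conserved annotation --------------------------------------------
        assignments = annotate_tags(
            depured,
            refs["mirna_mature"],
            refs["mirna_hairpin"],
            max_mismatch=th.conserved_max_mismatch,
            min_coverage=th.conserved_min_coverage,
        )
        family_summaries, stats = summarize_families(assignments, depured, lib_names)
        conserved_summary = stats.per_library.reset_index()
        checkpoint("annotate")

        # --- novel discovery --------------------------------------------------
        non_conserved = [t for t in depured if t.sequence not in assignments]
        discovery = discover(
            non_conserved,
            refs["transcriptome"],
            refs["mirna_mature"],
            breadth_threshold=th.breadth_threshold,
            max_loci=th.max_loci,
            max_locus_width=th.max_locus_width,
            merge_gap=th.merge_gap,
            prefix=config.species_prefix,
        )
        checkpoint("discover")

        # --- differential expression -----------------------------------------
        counts = tag_count_frame(depured, lib_names)
        library_sizes = {lib: int(counts[lib].sum()) for lib in lib_names}
        genotype_a, genotype_b = sorted({lib.genotype for lib in config.libraries})
        de = run_de(
            counts,
            library_sizes,
            groups,
            genotype_a,
            genotype_b,
            thresholds=DeThresholds(th.p_threshold, th.fc_threshold),
        )
        checkpoint("de")

        # --- family report with consensus names and in-silico DE flags --------
        fam_rows = []
        for fam in family_summaries:
            clusters = consensus_name(fam.family, fam.members, assignments, config.species_prefix)
            member_calls = {de.loc[t.sequence, "call"] for t in fam.members if t.sequence in de.index}
            de_flag = ";".join(sorted(c for c in member_calls if c != "ns")) or "-"
            for name, consensus, member_seqs in clusters:
                row = {
                    "family": fam.family,
                    "given_name": name,
                    "consensus": consensus,
                    "n_member_tags": len(member_seqs),
                    "de_call": de_flag,
                }
                row.update({lib: fam.counts.get(lib, 0) for lib in lib_names})
                fam_rows.append(row)
        families = pd.DataFrame(fam_rows)
        novel_rows = []
        for cand in discovery.candidates:
            row = {
                "name": cand.name,
                "representative": cand.representative,
                "transcript_id": cand.transcript_id,
                "start": cand.start,
                "end": cand.end,
                "de_call": de.loc[cand.representative, "call"]
                if cand.representative in de.index
                else "ns",
            }
            row.update({lib: cand.counts.get(lib, 0) for lib in lib_names})
            novel_rows.append(row)
        novel_candidates = pd.DataFrame(novel_rows)
        degradation_transcripts = pd.DataFrame(
            {"transcript_id": sorted(discovery.degradation_transcripts)}
        )

        # --- target scanning ---------------------------------------------------
        queries: List[Tuple[str, str]] = []
        for fam in family_summaries:
            for name, consensus, _members in consensus_name(
                fam.family, fam.members, assignments, config.species_prefix
            ):
                queries.append((name, consensus))
        for cand in discovery.candidates:
            queries.append((cand.name, cand.representative))
        params = ScoringParams(max_expectation=th.max_expectation, upe_max=th.upe_max)
        backend = gc_open_energy if config.use_accessibility else None
        sites = []
        for qid, qseq in queries:
            for tid, tseq in refs["transcriptome"].items():
                sites.extend(
                    scan_transcript(qid, qseq, tid, tseq, params, accessibility=backend)
                )
        target_sites = pd.DataFrame(
            [
                {
                    "mirna_id": s.mirna_id,
                    "transcript_id": s.transcript_id,
                    "start": s.start,
                    "end": s.end,
                    "expectation": s.expectation,
                    "mode": s.mode,
                    "upe": "" if s.upe is None else s.upe,
                    "duplex": s.duplex,
                }
                for s in sites
            ],
            columns=["mirna_id", "transcript_id", "start", "end", "expectation", "mode", "upe", "duplex"],
        )
        checkpoint("targets")

        # --- interaction logic (optional transcript presence input) -----------
        interactions = pd.DataFrame()
        if config.transcript_presence:
            presence_df = pd.read_csv(config.transcript_presence, sep="\t")
            presence = {
                row["transcript_id"]: str(row["genotypes"]).split(",")
                for _, row in presence_df.iterrows()
            }
            mirna_calls = {}
            seq_by_query = dict(queries)
            for qid, qseq in queries:
                if qseq in de.index:
                    mirna_calls[qid] = de.loc[qseq, "call"]
            interactions = link_expression(sites, mirna_calls, presence)
        checkpoint("link")

        result = PipelineResult(
            library_description=library_description,
            length_histogram=length_histogram,
            depuration=depuration,
            conserved_summary=conserved_summary,
            families=families,
            novel_candidates=novel_candidates,
            degradation_transcripts=degradation_transcripts,
            differential_expression=de.reset_index(names="tag"),
            target_sites=target_sites,
            interactions=interactions,
        )
        reports = {
            "library_description": result.library_description,
            "length_histogram": result.length_histogram,
            "depuration": result.depuration,
            "conserved_summary": result.conserved_summary,
            "mirna_families": result.families,
            "novel_candidates": result.novel_candidates,
            "degradation_transcripts": result.degradation_transcripts,
            "differential_expression": result.differential_expression,
            "target_sites": result.target_sites,
            "interactions": result.interactions,
        }
        for key, df in reports.items():
            path = outdir / f"{key}.tsv"
            _write_report(df, path, config, index=(key == "length_histogram"))
            result.report_paths[key] = str(path)
        manifest["status"] = "ok"
        manifest_path.write_text(json.dumps(manifest, indent=2))
        return result
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        manifest_path.write_text(json.dumps(manifest, indent=2))
        raise
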