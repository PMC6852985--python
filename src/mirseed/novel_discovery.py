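"""Degradation-aware discovery of novel miRNA candidates.

Non-conserved depured tags are mapped exactly (no mismatches, no gaps,
forward strand) to the reference transcriptome.  Each transcript gets a
read-count-weighted coverage profile; transcripts whose profile shows
reads across (most of) their length are degradation products of mRNA
turnover and are discarded, while transcripts with one or two narrow,
well-localized loci yield novel-miRNA candidates represented by the
highest-count tag of each locus.

Candidates are named by a relaxed homology search against the known
miRNA database (best-hit family) or serially (``ecu-novel-N``) when no
relative exists.  Hairpin-precursor folding is deliberately not part of
this stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core import ConfigurationError, ReferenceSet, SequenceTag
from .conserved_annotation import classify_conserved, family_of


def map_exact(
    tags: Sequence[SequenceTag], transcriptome: ReferenceSet
) -> Dict[str, List[Tuple[str, int]]]:
    """Exact end-to-end forward-strand hits: tag sequence -> [(transcript, offset)].

    Multi-mapping tags keep all their positions; tags with no hit are
    absent from the result.
    """
    if len(transcriptome) == 0:
        raise ConfigurationError("empty transcriptome")
    hits: Dict[str, List[Tuple[str, int]]] = {}
    for tag in tags:
        seq = tag.sequence
        found = []
        for tid, tseq in transcriptome.items():
            i = tseq.find(seq)
            while i != -1:
                found.append((tid, i))
                i = tseq.find(seq, i + 1)
        if found:
            hits[seq] = found
    return hits


@dataclass
class Locus:
    """A merged run of covered positions on a transcript (0-based, half-open)."""

    start: int
    end: int
    member_tags: List[str] = field(default_factory=list)

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass
class TranscriptCoverageProfile:
    transcript_id: str
    length: int
    depth: np.ndarray
    breadth: float
    loci: List[Locus]


def profile_transcript(
    transcript_id: str,
    length: int,
    mapped: Sequence[Tuple[str, int, int]],
    merge_gap: int = 5,
    weight_by_count: bool = True,
) -> TranscriptCoverageProfile:
    """Coverage profile from (tag sequence, read count, offset) placements.

    Depth is the per-position sum of covering read counts (or of unique
    tags when ``weight_by_count`` is False); loci are maximal covered
    runs merged across gaps of at most ``merge_gap`` positions.
    """
    depth = np.zeros(length, dtype=float)
    placements = []
    for seq, count, offset in mapped:
        if offset < 0 or offset + len(seq) > length:
            raise ValueError(
                f"hit outside transcript bounds: {transcript_id} {offset}+{len(seq)} > {length}"
            )
        w = count if weight_by_count else 1
        depth[offset : offset + len(seq)] += w
        placements.append((seq, offset))
    covered = depth > 0
    breadth = float(covered.sum()) / length if length else 0.0
    loci: List[Locus] = []
    run_start = None
    last_covered = None
    for pos in range(length):
        if covered[pos]:
            if run_start is None:
                run_start = pos
            elif last_covered is not None and pos - last_covered - 1 > merge_gap:
                loci.append(Locus(run_start, last_covered + 1))
                run_start = pos
            last_covered = pos
    if run_start is not None:
        loci.append(Locus(run_start, last_covered + 1))
    for locus in loci:
        locus.member_tags = sorted(
            {seq for seq, off in placements if off < locus.end and off + len(seq) > locus.start}
        )
    return TranscriptCoverageProfile(
        transcript_id=transcript_id, length=length, depth=depth, breadth=breadth, loci=loci
    )


@dataclass
class NovelCandidate:
    """A localized novel-miRNA candidate on one transcript."""

    representative: str
    transcript_id: str
    start: int
    end: int
    counts: Dict[str, int]
    name: str = ""


def classify_degradation(
    profile: TranscriptCoverageProfile,
    tag_counts: Dict[str, SequenceTag],
    breadth_threshold: float = 0.8,
    max_loci: int = 2,
    max_locus_width: int = 30,
    libraries: Optional[Sequence[str]] = None,
) -> Tuple[str, List[NovelCandidate]]:
    """Call a transcript 'degradation' or emit its candidate loci.

    Degradation iff breadth >= breadth_threshold, or more than
    ``max_loci`` loci, or any locus wider than ``max_locus_width``;
    otherwise each locus yields one candidate represented by its
    highest-count member tag.
    """
    if not (0.0 < breadth_threshold <= 1.0):
        raise ConfigurationError("breadth_threshold must be in (0, 1]")
    if max_loci < 1 or max_locus_width < 17:
        raise ConfigurationError("max_loci must be >= 1 and max_locus_width >= 17")
    if (
        profile.breadth >= breadth_threshold
        or len(profile.loci) > max_loci
        or any(l.width > max_locus_width for l in profile.loci)
    ):
        return "degradation", []
    candidates = []
    for locus in profile.loci:
        members = [tag_counts[s] for s in locus.member_tags if s in tag_counts]
        if not members:
            continue
        rep = max(members, key=lambda t: (t.total_count, t.sequence))
        counts = dict(rep.counts)
        candidates.append(
            NovelCandidate(
                representative=rep.sequence,
                transcript_id=profile.transcript_id,
                start=locus.start,
                end=locus.end,
                counts=counts,
            )
        )
    return "candidate", candidates


def name_novel(
    candidates: Sequence[NovelCandidate],
    mature_db: Optional[ReferenceSet],
    prefix: str = "ecu",
    relaxed_mismatch: int = 5,
    relaxed_coverage: float = 0.7,
) -> None:
    """Assign provisional names in place.

    A relaxed homology hit to the known-miRNA database names the
    candidate after the best-hit family (letter suffixes by descending
    count when several candidates share a family); candidates without
    relatives are numbered ``<prefix>-novel-N`` in descending count
    order.
    """
    by_family: Dict[str, List[NovelCandidate]] = {}
    orphans: List[NovelCandidate] = []
    for cand in candidates:
        hits = (
            classify_conserved(cand.representative, mature_db, relaxed_mismatch, relaxed_coverage)
            if mature_db is not None and len(mature_db)
            else []
        )
        if hits:
            by_family.setdefault(family_of(hits[0].ref_id), []).append(cand)
        else:
            orphans.append(cand)
    for family, group in by_family.items():
        group.sort(key=lambda c: (-sum(c.counts.values()), c.representative))
        if len(group) == 1:
            group[0].name = f"{prefix}-{family}"
        else:
            for i, cand in enumerate(group):
                cand.name = f"{prefix}-{family}{chr(ord('a') + i)}"
    orphans.sort(key=lambda c: (-sum(c.counts.values()), c.representative))
    for i, cand in enumerate(orphans):
        cand.name = f"{prefix}-novel-{i + 1}"


@dataclass
class DiscoveryResult:
    candidates: List[NovelCandidate]
    degradation_transcripts: List[str]
    profiles: Dict[str, TranscriptCoverageProfile]


def discover(
    tags: Sequence[SequenceTag],
    transcriptome: ReferenceSet,
    mature_db: Optional[ReferenceSet] = None,
    breadth_threshold: float = 0.8,
    max_loci: int = 2,
    max_locus_width: int = 30,
    merge_gap: int = 5,
    weight_by_count: bool = True,
    prefix: str = "ecu",
) -> DiscoveryResult:
    """Full discovery pass: map, profile, filter degradation, name candidates."""
    hits = map_exact(tags, transcriptome)
    tag_by_seq = {t.sequence: t for t in tags}
    per_transcript: Dict[str, List[Tuple[str, int, int]]] = {}
    for seq, placements in hits.items():
        count = tag_by_seq[seq].total_count
        for tid, offset in placements:
            per_transcript.setdefault(tid, []).append((seq, count, offset))
    candidates: List[NovelCandidate] = []
    degraded: List[str] = []
    profiles: Dict[str, TranscriptCoverageProfile] = {}
    for tid in sorted(per_transcript):
        profile = profile_transcript(
            tid,
            len(transcriptome.sequences[tid]),
            per_transcript[tid],
            merge_gap=merge_gap,
            weight_by_count=weight_by_count,
        )
        profiles[tid] = profile
        verdict, cands = classify_degradation(
            profile,
            tag_by_seq,
            breadth_threshold=breadth_threshold,
            max_loci=max_loci,
            max_locus_width=max_locus_width,
        )
        if verdict == "degradation":
            degraded.append(tid)
        else:
            candidates.extend(cands)
    name_novel(candidates, mature_db, prefix=prefix)
    return DiscoveryResult(candidates=candidates, degradation_transcripts=degraded, profiles=profiles)
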