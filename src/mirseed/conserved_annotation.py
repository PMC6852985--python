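"""Conserved-miRNA classification by ungapped homology to a miRNA database.

A depured tag is *conserved* when it has an ungapped local alignment to
a mature or precursor miRNA database entry with at most ``max_mismatch``
substitutions (default 2) covering at least ``min_coverage`` of the tag
length (default 90%).  Conserved tags are aggregated into families
parsed from the database identifiers (the "miR<number>" token), and each
family receives positional-majority consensus sequences with species-
prefixed names (``ecu-miR<number>a``, ``b``, ... in descending count
order).

The search contract is the exhaustive scan over every alignment
diagonal (including tag overhangs at entry ends); the implementation
seeds candidate diagonals with a shared-k-mer index whenever the
thresholds guarantee an exact seed of that length (pigeonhole), and
falls back to full enumeration otherwise.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._seq import canonical, encode
from .core import ConfigurationError, HomologyHit, ReferenceSet, SequenceTag

_FAMILY_RE = re.compile(r"mir-?0*(\d+)", re.IGNORECASE)


def family_of(db_id: str) -> str:
    """Parse the miRNA family from a database identifier.

    ``ata-miR2275a-3p`` -> ``miR2275``; ``ppt-MIR894`` -> ``miR894``.
    Unparsable ids yield the family ``unknown`` with a warning.
    """
    m = _FAMILY_RE.search(db_id)
    if not m:
        warnings.warn(f"cannot parse miRNA family from id {db_id!r}", stacklevel=2)
        return "unknown"
    return f"miR{m.group(1)}"


def _diagonal_hits(
    tag: str, ref_id: str, ref_seq: str, max_mismatch: int, min_aligned: int
) -> List[HomologyHit]:
    """Exhaustive diagonal enumeration for one tag/entry pair."""
    t, r = encode(tag), encode(ref_seq)
    m, L = len(t), len(r)
    hits = []
    for d in range(-(m - min_aligned), L - min_aligned + 1):
        rs, re_ = max(d, 0), min(d + m, L)
        o = re_ - rs
        if o < min_aligned:
            continue
        ts = rs - d
        mm = int(np.count_nonzero(t[ts : ts + o] != r[rs : rs + o]))
        if mm <= max_mismatch:
            hits.append(HomologyHit(tag, ref_id, rs, o, mm, tag_start=ts))
    return hits


class MirnaIndex:
    """Shared-k-mer diagonal index over a miRNA reference set.

    Guarantees no lost hits as long as every qualifying alignment
    contains an exact run of at least k matching bases; callers check
    that pigeonhole bound before using the index.
    """

    def __init__(self, ref: ReferenceSet, k: int):
        self.k = k
        self.ref = ref
        self.encoded = {rid: encode(seq) for rid, seq in ref.items()}
        self.kmers: Dict[str, List[Tuple[str, int]]] = {}
        for rid, seq in ref.items():
            for pos in range(len(seq) - k + 1):
                self.kmers.setdefault(seq[pos : pos + k], []).append((rid, pos))

    def candidate_diagonals(self, tag: str) -> Dict[str, set]:
        cands: Dict[str, set] = {}
        for tp in range(len(tag) - self.k + 1):
            for rid, rp in self.kmers.get(tag[tp : tp + self.k], ()):
                cands.setdefault(rid, set()).add(rp - tp)
        return cands


def _seed_k(min_aligned: int, max_mismatch: int) -> int:
    """Longest exact run guaranteed in a qualifying alignment (pigeonhole)."""
    return math.ceil((min_aligned - max_mismatch) / (max_mismatch + 1))


def classify_conserved(
    tag: str,
    mirna_db: ReferenceSet,
    max_mismatch: int = 2,
    min_coverage: float = 0.90,
    index: Optional[MirnaIndex] = None,
) -> List[HomologyHit]:
    """All qualifying ungapped local hits of a tag in a miRNA database.

    A tag with at least one hit is labelled conserved.  Hits are sorted
    best-first: fewest mismatches, longest alignment, smallest db id.
    """
    if not (0.0 < min_coverage <= 1.0):
        raise ConfigurationError("min_coverage must be in (0, 1]")
    if max_mismatch < 0:
        raise ConfigurationError("max_mismatch must be >= 0")
    if len(mirna_db) == 0:
        raise ConfigurationError("empty miRNA database")
    tag = canonical(tag)
    m = len(tag)
    min_aligned = math.ceil(min_coverage * m)
    hits: List[HomologyHit] = []
    if index is not None and index.k <= _seed_k(min_aligned, max_mismatch):
        t = encode(tag)
        for rid, diagonals in index.candidate_diagonals(tag).items():
            r = index.encoded[rid]
            L = len(r)
            for d in sorted(diagonals):
                rs, re_ = max(d, 0), min(d + m, L)
                o = re_ - rs
                if o < min_aligned:
                    continue
                ts = rs - d
                mm = int(np.count_nonzero(t[ts : ts + o] != r[rs : rs + o]))
                if mm <= max_mismatch:
                    hits.append(HomologyHit(tag, rid, rs, o, mm, tag_start=ts))
    else:
        for rid, seq in mirna_db.items():
            hits.extend(_diagonal_hits(tag, rid, seq, max_mismatch, min_aligned))
    hits.sort(key=lambda h: (h.mismatches, -h.length, h.ref_id, h.offset))
    return hits


@dataclass
class Assignment:
    """A conserved tag's best hit, family, and database tier."""

    hit: HomologyHit
    family: str
    source: str  # "mature" | "hairpin"


def annotate_tags(
    tags: Sequence[SequenceTag],
    mature_db: ReferenceSet,
    hairpin_db: Optional[ReferenceSet] = None,
    max_mismatch: int = 2,
    min_coverage: float = 0.90,
) -> Dict[str, Assignment]:
    """Classify every tag; assign each conserved tag to one family.

    A mature-set hit takes precedence over a hairpin-only hit; among
    hits of the same tier the best one (fewest mismatches, longest
    alignment, smallest id) decides the family, so each tag is counted
    exactly once.
    """
    min_aligned_floor = math.ceil(min_coverage * 17)
    k = min(8, _seed_k(min_aligned_floor, max_mismatch))
    indexes = {}
    for name, db in (("mature", mature_db), ("hairpin", hairpin_db)):
        if db is not None and k >= 4:
            indexes[name] = MirnaIndex(db, k)
        else:
            indexes[name] = None
    assignments: Dict[str, Assignment] = {}
    for tag in tags:
        for source, db in (("mature", mature_db), ("hairpin", hairpin_db)):
            if db is None:
                continue
            hits = classify_conserved(
                tag.sequence, db, max_mismatch, min_coverage, index=indexes[source]
            )
            if hits:
                best = hits[0]
                assignments[tag.sequence] = Assignment(best, family_of(best.ref_id), source)
                break
    return assignments


@dataclass
class FamilySummary:
    """A miRNA family with its member tags and summed per-library counts."""

    family: str
    members: List[SequenceTag]
    counts: Dict[str, int]
    consensus: List[Tuple[str, str]] = field(default_factory=list)  # (name, sequence)

    @property
    def n_members(self) -> int:
        return len(self.members)


@dataclass
class ConservedStats:
    """Conserved fraction per library on two bases (unique tags / read counts)."""

    per_library: pd.DataFrame  # rows: library; columns as below

    @classmethod
    def compute(
        cls,
        depured_tags: Sequence[SequenceTag],
        conserved: Sequence[SequenceTag],
        libraries: Sequence[str],
    ) -> "ConservedStats":
        conserved_set = {t.sequence for t in conserved}
        rows = []
        for lib in libraries:
            tags_lib = sum(1 for t in depured_tags if t.count_in(lib) > 0)
            cons_lib = sum(1 for t in depured_tags if t.sequence in conserved_set and t.count_in(lib) > 0)
            reads_lib = sum(t.count_in(lib) for t in depured_tags)
            cons_reads = sum(t.count_in(lib) for t in depured_tags if t.sequence in conserved_set)
            rows.append(
                {
                    "library": lib,
                    "depured_tags": tags_lib,
                    "conserved_tags": cons_lib,
                    "pct_conserved_tags": round(100.0 * cons_lib / tags_lib, 2) if tags_lib else 0.0,
                    "depured_reads": reads_lib,
                    "conserved_reads": cons_reads,
                    "pct_conserved_reads": round(100.0 * cons_reads / reads_lib, 2)
                    if reads_lib
                    else 0.0,
                }
            )
        return cls(per_library=pd.DataFrame(rows).set_index("library"))


def summarize_families(
    assignments: Dict[str, Assignment],
    depured_tags: Sequence[SequenceTag],
    libraries: Sequence[str],
) -> Tuple[List[FamilySummary], ConservedStats]:
    """Aggregate conserved tags by family; families ordered by member count.

    Per-library family counts are the sums over member tags, so total
    counts are conserved between the tag and family levels.
    """
    tag_by_seq = {t.sequence: t for t in depured_tags}
    members: Dict[str, List[SequenceTag]] = {}
    for seq, asg in assignments.items():
        if seq in tag_by_seq:
            members.setdefault(asg.family, []).append(tag_by_seq[seq])
    summaries = []
    for family, tags in members.items():
        counts = {lib: sum(t.count_in(lib) for t in tags) for lib in libraries}
        tags.sort(key=lambda t: (-t.total_count, t.sequence))
        summaries.append(FamilySummary(family=family, members=tags, counts=counts))
    summaries.sort(key=lambda f: (-f.n_members, f.family))
    conserved_tags = [tag_by_seq[s] for s in assignments if s in tag_by_seq]
    stats = ConservedStats.compute(depured_tags, conserved_tags, libraries)
    return summaries, stats


def _majority(column: List[str]) -> str:
    best, best_n = "", -1
    for base in "ACGT":
        n = column.count(base)
        if n > best_n:
            best, best_n = base, n
    return best


def consensus_name(
    family: str,
    members: Sequence[SequenceTag],
    assignments: Dict[str, Assignment],
    prefix: str = "ecu",
) -> List[Tuple[str, str, List[str]]]:
    """Positional-majority consensus sequences and names for one family.

    Members are grouped by their anchoring database entry and aligned in
    anchor coordinates; groups with identical consensus merge into one
    cluster.  Clusters are lettered a, b, ... in descending total-count
    order, giving names like ``ecu-miR156a``.

    Returns a list of (name, consensus sequence, member sequences).
    """
    if not members:
        raise ConfigurationError("consensus_name requires at least one member")
    groups: Dict[str, List[SequenceTag]] = {}
    for tag in members:
        asg = assignments[tag.sequence]
        groups.setdefault(asg.hit.ref_id, []).append(tag)
    clusters: Dict[str, Dict[str, object]] = {}
    for anchor, tags in groups.items():
        placed: List[Tuple[str, int]] = []  # (sequence, anchor coordinate of base 0)
        for tag in tags:
            hit = assignments[tag.sequence].hit
            placed.append((tag.sequence, hit.offset - hit.tag_start))
        lo = min(d for _, d in placed)
        hi = max(d + len(s) for s, d in placed)
        cols = []
        for pos in range(lo, hi):
            col = [s[pos - d] for s, d in placed if 0 <= pos - d < len(s)]
            cols.append(_majority(col) if col else "")
        consensus = "".join(cols)
        entry = clusters.setdefault(consensus, {"tags": [], "total": 0})
        entry["tags"].extend(t.sequence for t in tags)
        entry["total"] += sum(t.total_count for t in tags)
    ordered = sorted(clusters.items(), key=lambda kv: (-kv[1]["total"], kv[0]))
    out = []
    for i, (consensus, entry) in enumerate(ordered):
        letter = chr(ord("a") + i)
        out.append((f"{prefix}-{family}{letter}", consensus, sorted(set(entry["tags"]))))
    return out
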