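"""Sequential subtraction of organellar and ncRNA-matching tags.

Tags are aligned end-to-end (ungapped, bounded substitutions) against
each contamination reference in the fixed order mitochondria ->
chloroplast -> ncRNA; matching tags are removed and a depuration report
with per-stage counts and percentages (relative to each stage's input)
is produced.  The default mismatch tolerance is 0.

Correctness is defined by the exhaustive sliding-window scan; the
implementation uses a fast substring path for the zero-mismatch case and
a vectorized window comparison otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd

from ._seq import canonical, encode, revcomp
from .core import ConfigurationError, HomologyHit, ReferenceSet, SequenceTag


def _scan_mismatch(tag: str, ref_seq: str, max_mismatch: int) -> List[Tuple[int, int]]:
    """All (offset, mismatches) where tag aligns end-to-end in ref_seq."""
    m, L = len(tag), len(ref_seq)
    if m > L:
        return []
    if max_mismatch == 0:
        out = []
        i = ref_seq.find(tag)
        while i != -1:
            out.append((i, 0))
            i = ref_seq.find(tag, i + 1)
        return out
    windows = np.lib.stride_tricks.sliding_window_view(encode(ref_seq), m)
    mm = (windows != encode(tag)).sum(axis=1)
    return [(int(i), int(mm[i])) for i in np.flatnonzero(mm <= max_mismatch)]


def ungapped_match(
    tag: str, ref: ReferenceSet, max_mismatch: int = 0
) -> List[HomologyHit]:
    """End-to-end ungapped hits of a tag anywhere in a reference set.

    Both strands are searched when the set's strand policy is ``both``;
    a '-' strand hit means the reverse complement of the tag matches the
    reference at the reported offset.
    """
    if max_mismatch < 0:
        raise ConfigurationError("max_mismatch must be >= 0")
    tag = canonical(tag)
    hits: List[HomologyHit] = []
    queries = [(tag, "+")]
    if ref.strand_policy == "both":
        queries.append((revcomp(tag), "-"))
    for query, strand in queries:
        for rid, seq in ref.items():
            for offset, mm in _scan_mismatch(query, seq, max_mismatch):
                hits.append(
                    HomologyHit(
                        tag=tag,
                        ref_id=rid,
                        offset=offset,
                        length=len(tag),
                        mismatches=mm,
                        strand=strand,
                    )
                )
    return hits


@dataclass
class StageReport:
    """One subtraction stage of the depuration (Table-2-like row pair)."""

    stage: str
    n_input: int
    n_aligned: int
    n_unaligned: int

    @property
    def pct_aligned(self) -> float:
        return round(100.0 * self.n_aligned / self.n_input, 2) if self.n_input else 0.0

    @property
    def pct_unaligned(self) -> float:
        return round(100.0 * self.n_unaligned / self.n_input, 2) if self.n_input else 0.0


@dataclass
class DepurationReport:
    """Full depuration summary: per-stage partitions plus the final tally."""

    n_input: int
    stages: List[StageReport] = field(default_factory=list)

    @property
    def n_depured(self) -> int:
        return self.stages[-1].n_unaligned if self.stages else self.n_input

    @property
    def pct_depured(self) -> float:
        return round(100.0 * self.n_depured / self.n_input, 2) if self.n_input else 0.0

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "stage": s.stage,
                "input_tags": s.n_input,
                "aligned_tags": s.n_aligned,
                "pct_aligned": s.pct_aligned,
                "unaligned_tags": s.n_unaligned,
                "pct_unaligned": s.pct_unaligned,
            }
            for s in self.stages
        ]
        return pd.DataFrame(rows)


def subtract(
    tags: Sequence[SequenceTag], ref: ReferenceSet, max_mismatch: int = 0
) -> Tuple[List[SequenceTag], StageReport]:
    """Remove tags with at least one hit in the reference set.

    The kept/removed partition is exact: every input tag lands in exactly
    one side, and the report counts refer to the stage's input.
    """
    kept, removed = [], 0
    for tag in tags:
        if ungapped_match(tag.sequence, ref, max_mismatch):
            removed += 1
        else:
            kept.append(tag)
    report = StageReport(
        stage=ref.name, n_input=len(tags), n_aligned=removed, n_unaligned=len(kept)
    )
    return kept, report


def depure(
    tags: Sequence[SequenceTag],
    mito: ReferenceSet,
    chloro: ReferenceSet,
    ncrna: ReferenceSet,
    max_mismatch: int = 0,
) -> Tuple[List[SequenceTag], DepurationReport]:
    """Apply the fixed subtraction chain mitochondria -> chloroplast -> ncRNA."""
    for ref, expected in ((mito, "organellar"), (chloro, "organellar"), (ncrna, "ncrna")):
        if ref is None:
            raise ConfigurationError("depure requires mito, chloro and ncRNA reference sets")
        if ref.kind != expected:
            raise ConfigurationError(
                f"reference {ref.name!r} has class {ref.kind!r}, expected {expected!r}"
            )
    report = DepurationReport(n_input=len(tags))
    current = list(tags)
    for ref in (mito, chloro, ncrna):
        current, stage = subtract(current, ref, max_mismatch)
        report.stages.append(stage)
    return current, report
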