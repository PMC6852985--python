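"""Read cleanup: adapter/quality trimming, length window, tag collapsing.

Raw small-RNA reads are 3'-adapter-trimmed (leftmost suffix match of at
least ``min_overlap`` adapter bases), quality-trimmed from the 3' end,
and kept only if the remaining insert is 17-33 nt.  Clean reads from one
library are collapsed to counted sequence tags, and tags below the
minimum per-library count (default 3) are discarded.

N-containing reads are dropped outright: every downstream comparison is
ungapped and exact over {A,C,G,T}, so ambiguity codes cannot be matched
without inventing extra rules.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._seq import canonical
from .core import ConfigurationError, SequenceTag

MIN_LENGTH = 17
MAX_LENGTH = 33

PHRED_OFFSET = 33


@dataclass
class TrimStats:
    """Bookkeeping for one library's cleanup (reads, not tags)."""

    library: str
    n_raw: int = 0
    n_clean: int = 0
    n_too_short: int = 0
    n_too_long: int = 0
    n_with_n: int = 0

    @property
    def n_discarded(self) -> int:
        return self.n_raw - self.n_clean


def trim_adapter(seq: str, adapter: str, min_overlap: int = 8) -> str:
    """Clip the 3' adapter at the leftmost suffix match of >= min_overlap nt.

    A match at position i requires read[i:] to be a prefix of the adapter
    (or to contain the full adapter), with overlap >= min_overlap.
    Trimming repeats until no such suffix remains, so the operation is
    idempotent even when the insert itself ends in an adapter prefix.
    """
    if len(adapter) < min_overlap:
        raise ConfigurationError("adapter shorter than min_overlap")
    prefix = adapter[:min_overlap]
    while True:
        n = len(seq)
        cut = None
        i = seq.find(prefix)
        while i != -1:
            k = min(len(adapter), n - i)
            if seq[i : i + k] == adapter[:k]:
                cut = i
                break
            i = seq.find(prefix, i + 1)
        if cut is None:
            return seq
        seq = seq[:cut]


def quality_trim(seq: str, qual: str, cutoff: int = 20) -> str:
    """Remove trailing bases whose Phred quality is below the cutoff."""
    end = len(seq)
    while end > 0 and ord(qual[end - 1]) - PHRED_OFFSET < cutoff:
        end -= 1
    return seq[:end]


def trim_read(
    seq: str,
    qual: str,
    adapter: str,
    quality_cutoff: int = 20,
    min_overlap: int = 8,
    min_length: int = MIN_LENGTH,
    max_length: int = MAX_LENGTH,
) -> Optional[str]:
    """Trim one raw read; return the clean insert or None if discarded."""
    if len(seq) != len(qual):
        raise ValueError("sequence/quality length mismatch")
    s = canonical(seq)
    s = trim_adapter(s, canonical(adapter), min_overlap)
    s = quality_trim(s, qual[: len(s)], quality_cutoff)
    if "N" in s:
        return None
    if not (min_length <= len(s) <= max_length):
        return None
    return s


def clean_library(
    reads: Iterable[Tuple[str, str, str]],
    library: str,
    adapter: str,
    quality_cutoff: int = 20,
    min_overlap: int = 8,
) -> Tuple[List[str], TrimStats]:
    """Trim every read of a library; return clean inserts and statistics."""
    stats = TrimStats(library=library)
    clean: List[str] = []
    adapter = canonical(adapter)
    for _rid, seq, qual in reads:
        stats.n_raw += 1
        if len(seq) != len(qual):
            raise ValueError(f"sequence/quality length mismatch in read #{stats.n_raw - 1}")
        s = trim_adapter(canonical(seq), adapter, min_overlap)
        s = quality_trim(s, qual[: len(s)], quality_cutoff)
        if "N" in s:
            stats.n_with_n += 1
            continue
        if len(s) < MIN_LENGTH:
            stats.n_too_short += 1
            continue
        if len(s) > MAX_LENGTH:
            stats.n_too_long += 1
            continue
        stats.n_clean += 1
        clean.append(s)
    return clean, stats


def collapse(clean_reads: Sequence[str], library: str) -> List[SequenceTag]:
    """Collapse one library's clean reads into counted sequence tags.

    Conservation: the sum of tag counts equals the number of clean reads.
    Tags are ordered by descending count, then sequence.
    """
    counter = Counter(clean_reads)
    tags = [
        SequenceTag(seq, {library: n}, f"{library}_{n}")
        for seq, n in sorted(counter.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return tags


def filter_min_count(
    tags: Sequence[SequenceTag], min_count: int = 3
) -> Tuple[List[SequenceTag], int, float]:
    """Drop tags below the per-library minimum count.

    Returns (kept tags, number of discarded reads, percentage of the
    library's clean reads discarded).
    """
    if min_count < 1:
        raise ConfigurationError("min_count must be >= 1")
    kept, discarded_reads, total_reads = [], 0, 0
    for tag in tags:
        n = tag.total_count
        total_reads += n
        if n >= min_count:
            kept.append(tag)
        else:
            discarded_reads += n
    pct = 100.0 * discarded_reads / total_reads if total_reads else 0.0
    return kept, discarded_reads, pct


def length_profile(clean_reads: Sequence[str]) -> Tuple[pd.Series, List[int]]:
    """Length histogram over the 17-33 nt window plus modal lengths.

    Returns (histogram indexed by length, modes ordered by descending
    frequency).  Modes are the local maxima of the histogram; an empty
    input is an error.
    """
    if not clean_reads:
        raise ValueError("length_profile: empty input")
    lengths = np.fromiter((len(s) for s in clean_reads), dtype=int)
    idx = np.arange(MIN_LENGTH, MAX_LENGTH + 1)
    counts = np.bincount(lengths, minlength=MAX_LENGTH + 1)[MIN_LENGTH : MAX_LENGTH + 1]
    hist = pd.Series(counts, index=idx, name="reads")
    modes = [
        int(l)
        for l in idx
        if counts[l - MIN_LENGTH] > 0
        and (l == MIN_LENGTH or counts[l - MIN_LENGTH] >= counts[l - 1 - MIN_LENGTH])
        and (l == MAX_LENGTH or counts[l - MIN_LENGTH] >= counts[l + 1 - MIN_LENGTH])
    ]
    modes.sort(key=lambda l: (-counts[l - MIN_LENGTH], l))
    return hist, modes


@dataclass
class LibrarySummary:
    """One row of the library-description report."""

    library: str
    n_clean_reads: int
    average_length: float
    n_tags: int
    n_included_reads: int
    n_discarded_reads: int
    pct_discarded: float


def summarize_library(
    clean_reads: Sequence[str],
    library: str,
    kept_tags: Sequence[SequenceTag],
    discarded_reads: int,
    pct_discarded: float,
) -> LibrarySummary:
    avg = float(np.mean([len(s) for s in clean_reads])) if clean_reads else 0.0
    return LibrarySummary(
        library=library,
        n_clean_reads=len(clean_reads),
        average_length=round(avg, 1),
        n_tags=len(kept_tags),
        n_included_reads=len(clean_reads) - discarded_reads,
        n_discarded_reads=discarded_reads,
        pct_discarded=round(pct_discarded, 2),
    )
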