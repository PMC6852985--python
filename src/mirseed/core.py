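"""Shared domain types of the small-RNA pipeline.

The unit of analysis downstream of read collapsing is the *sequence tag*:
a unique small-RNA sequence with a per-library read count.  References
(organellar genomes, ncRNA families, miRNA databases, the transcriptome)
are named collections of sequences with a class-specific strand policy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List

from ._seq import canonical

REFERENCE_CLASSES = ("organellar", "ncrna", "mirna-mature", "mirna-hairpin", "transcriptome")


class ConfigurationError(ValueError):
    """Raised when a parameter or reference set violates its contract."""


@dataclass
class ReferenceSet:
    """A named collection of reference sequences.

    strand_policy controls homology searches: ``both`` scans forward and
    reverse-complement orientations (DNA-derived references such as
    organellar genomes), ``forward`` scans only the given orientation
    (RNA-derived references: ncRNA families, mature miRNAs, transcripts).
    """

    name: str
    kind: str
    sequences: Dict[str, str]
    strand_policy: str = "forward"

    def __post_init__(self) -> None:
        if self.kind not in REFERENCE_CLASSES:
            raise ConfigurationError(f"unknown reference class {self.kind!r}")
        if self.strand_policy not in ("both", "forward"):
            raise ConfigurationError(f"unknown strand policy {self.strand_policy!r}")
        clean = {}
        for rid, seq in self.sequences.items():
            if rid in clean:
                raise ConfigurationError(f"duplicate reference id {rid!r}")
            s = canonical(seq)
            if not s:
                raise ConfigurationError(f"empty reference sequence {rid!r}")
            clean[rid] = s
        self.sequences = clean

    def __len__(self) -> int:
        return len(self.sequences)

    def items(self):
        return self.sequences.items()


@dataclass
class SequenceTag:
    """A unique small-RNA sequence with per-library read counts.

    ``label`` follows the library-naming convention ``<LIB>_<count>`` of
    the library the tag was first collapsed in.
    """

    sequence: str
    counts: Dict[str, int] = field(default_factory=dict)
    label: str = ""

    @property
    def total_count(self) -> int:
        return sum(self.counts.values())

    def count_in(self, library: str) -> int:
        return self.counts.get(library, 0)


def merge_tags(per_library: Iterable[List[SequenceTag]]) -> List[SequenceTag]:
    """Merge single-library tag lists into multi-library tags.

    The label of a merged tag is taken from the library with the highest
    count (ties broken by library name).
    """
    merged: Dict[str, SequenceTag] = {}
    for tags in per_library:
        for tag in tags:
            tgt = merged.get(tag.sequence)
            if tgt is None:
                merged[tag.sequence] = SequenceTag(tag.sequence, dict(tag.counts), tag.label)
            else:
                for lib, n in tag.counts.items():
                    tgt.counts[lib] = tgt.counts.get(lib, 0) + n
    out = list(merged.values())
    for tag in out:
        lib = min(sorted(tag.counts), key=lambda k: -tag.counts[k])
        tag.label = f"{lib}_{tag.counts[lib]}"
    out.sort(key=lambda t: (-t.total_count, t.sequence))
    return out


@dataclass(frozen=True)
class HomologyHit:
    """An ungapped alignment of a tag to a reference sequence.

    ``offset`` is 0-based in the reference; ``tag_start`` is the first
    tag position inside the alignment (nonzero when the tag overhangs
    the reference's 5' end); ``coverage`` is the aligned fraction of the
    *tag* length.  ``strand`` is '+' or '-'; for '-' hits the reverse
    complement of the tag aligns at the given offset.
    """

    tag: str
    ref_id: str
    offset: int
    length: int
    mismatches: int
    strand: str = "+"
    tag_start: int = 0

    @property
    def coverage(self) -> float:
        return self.length / len(self.tag)


def tag_count_frame(tags: Iterable[SequenceTag], libraries: Iterable[str]):
    """Per-library count matrix (rows = tag sequences) as a DataFrame."""
    import pandas as pd

    libs = list(libraries)
    rows = {t.sequence: [t.count_in(lib) for lib in libs] for t in tags}
    return pd.DataFrame.from_dict(rows, orient="index", columns=libs).astype(int)
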