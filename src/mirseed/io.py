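"""FASTA/FASTQ and table I/O helpers (Biopython-backed, gzip transparent)."""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Dict, Iterable, Iterator, Tuple

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import ReferenceSet


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path) -> Dict[str, str]:
    """Read a FASTA file into an id -> sequence dict (order preserved)."""
    with _open_text(path) as fh:
        return {rec.id: str(rec.seq) for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(sequences: Dict[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=rid, description="") for rid, seq in sequences.items()]
    with _open_text(path, "wt") as fh:
        SeqIO.write(records, fh, "fasta")


def read_reference(path, name: str, kind: str, strand_policy: str = "forward") -> ReferenceSet:
    return ReferenceSet(name=name, kind=kind, sequences=read_fasta(path), strand_policy=strand_policy)


def iter_fastq(path) -> Iterator[Tuple[str, str, str]]:
    """Yield (read id, sequence, quality string) from a FASTQ file.

    Malformed records raise ValueError with the offending record index.
    """
    with _open_text(path) as fh:
        idx = 0
        try:
            for title, seq, qual in _fastq_triples(fh):
                yield title.split()[0], seq, qual
                idx += 1
        except ValueError as exc:
            raise ValueError(f"malformed FASTQ record #{idx}: {exc}") from exc


def _fastq_triples(fh):
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    return FastqGeneralIterator(fh)


def write_fastq(records: Iterable[Tuple[str, str, str]], path) -> None:
    """Write (id, sequence, quality) triples as Phred+33 FASTQ."""
    with _open_text(path, "wt") as fh:
        for rid, seq, qual in records:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")
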