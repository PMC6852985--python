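"""Low-level sequence utilities shared across the pipeline.

The internal canonical alphabet is DNA (``ACGT``); RNA input is accepted
everywhere and ``U`` is mapped to ``T`` on entry.  Reverse complements and
byte-array encodings are centralized here so that every module agrees on
the alphabet.
"""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

DNA_ALPHABET = frozenset("ACGT")


def canonical(seq: str) -> str:
    """Upper-case a sequence and map U to T (canonical DNA form)."""
    return seq.upper().replace("U", "T")


def revcomp(seq: str) -> str:
    """Reverse complement of a canonical DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def to_rna(seq: str) -> str:
    """Render a canonical DNA string as RNA (T -> U)."""
    return canonical(seq).replace("T", "U")


def encode(seq: str) -> np.ndarray:
    """Encode a canonical DNA string as a uint8 array (ASCII codes)."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def is_dna(seq: str) -> bool:
    return bool(seq) and set(seq) <= DNA_ALPHABET


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_dna(rng: np.random.Generator, length: int) -> str:
    """Draw a uniform random DNA string of the given length."""
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")
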