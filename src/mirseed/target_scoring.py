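"""miRNA-target complementarity scoring (plant-style expectation score).

A miRNA (5'->3') is aligned antiparallel against a transcript window
(3'->5').  Each duplex position contributes a penalty: Watson-Crick 0,
G:U wobble 0.5, mismatch 1.0, miRNA-side bulge 2.0; penalties inside
the seed region (miRNA positions 2-13, 1-based from the 5' end) are
doubled.  The total is the *expectation*: lower is better, and sites
above ``max_expectation`` (default 2.5) are rejected, as is any duplex
with a true mismatch in the seed (G:U wobbles are penalized but
allowed) or any alignment that would need a bulge on the target side.
A non-Watson-Crick pair inside the central window (positions 9-11)
switches the predicted mode from cleavage to translational inhibition.

Site accessibility (the energy needed to unpair the site plus 17 nt
upstream / 13 nt downstream of flank) is a pluggable backend; the
default shipped backend is a deterministic structure-free GC-content
proxy suitable for tests and ranking, not a partition-function folder.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._seq import canonical, encode, is_dna
from .core import ConfigurationError

_COMP = {"A": "T", "T": "A", "G": "C", "C": "G"}
_GU = {("G", "T"), ("T", "G")}  # wobble pairs in DNA lettering (U == T)


@dataclass(frozen=True)
class ScoringParams:
    """Thresholds and penalty table of the expectation score."""

    max_expectation: float = 2.5
    hsp_size: int = 20
    seed_start: int = 2  # 1-based miRNA positions, inclusive
    seed_end: int = 13
    seed_mismatches_allowed: int = 0
    central_start: int = 9
    central_end: int = 11
    upe_max: float = 20.0
    flank_up: int = 17
    flank_down: int = 13
    target_bulges_allowed: bool = False
    mismatch_penalty: float = 1.0
    gu_penalty: float = 0.5
    bulge_penalty: float = 2.0
    seed_multiplier: float = 2.0
    max_mirna_bulges: int = 1

    def __post_init__(self) -> None:
        if not (1 <= self.seed_start <= self.seed_end):
            raise ConfigurationError("invalid seed region")
        if not (self.seed_start <= self.central_start <= self.central_end <= self.seed_end):
            raise ConfigurationError("central window must lie inside the seed region")
        for name in ("max_expectation", "upe_max", "mismatch_penalty", "gu_penalty", "bulge_penalty"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")


@dataclass
class DuplexScore:
    """An accepted duplex: expectation plus per-miRNA-position pair classes."""

    expectation: float
    pairs: Tuple[str, ...]  # per miRNA position: 'wc' | 'gu' | 'mm' | 'bulge'

    def render(self) -> str:
        symbols = {"wc": "|", "gu": "o", "mm": ".", "bulge": "-"}
        return "".join(symbols[p] for p in self.pairs)


def _pair_class(mirna_base: str, target_base: str) -> str:
    if _COMP[mirna_base] == target_base:
        return "wc"
    if (mirna_base, target_base) in _GU:
        return "gu"
    return "mm"


def _score_pairs(pairs: Sequence[str], params: ScoringParams) -> Optional[float]:
    """Expectation of a pair-class vector, or None when rejected."""
    total = 0.0
    for i, cls in enumerate(pairs):
        pos = i + 1
        in_seed = params.seed_start <= pos <= params.seed_end
        if cls == "wc":
            continue
        if cls == "mm" and in_seed:
            return None  # true mismatch in the seed
        penalty = {
            "gu": params.gu_penalty,
            "mm": params.mismatch_penalty,
            "bulge": params.bulge_penalty,
        }[cls]
        if in_seed:
            penalty *= params.seed_multiplier
        total += penalty
    if total > params.max_expectation:
        return None
    return total


def score_duplex(
    mirna: str, window: str, params: ScoringParams = ScoringParams()
) -> Optional[DuplexScore]:
    """Score one miRNA against one transcript window; None when rejected.

    The window is given 5'->3' in transcript orientation.  A window one
    base shorter than the miRNA is scored with a single miRNA-side
    bulge at the best position; longer windows would require target
    bulges and are rejected.
    """
    mirna = canonical(mirna)
    window = canonical(window)
    if not is_dna(mirna) or not is_dna(window):
        raise ValueError("sequences must be over A/C/G/T(U)")
    m = len(mirna)
    rw = window[::-1]  # 3'->5', so rw[i] faces miRNA position i+1
    if len(window) == m:
        pairs = tuple(_pair_class(mirna[i], rw[i]) for i in range(m))
        expectation = _score_pairs(pairs, params)
        return None if expectation is None else DuplexScore(expectation, pairs)
    if len(window) == m - 1 and params.max_mirna_bulges >= 1:
        best: Optional[DuplexScore] = None
        for j in range(m):  # bulged (unpaired) miRNA position j+1
            pairs = []
            for k in range(m - 1):
                i = k if k < j else k + 1
                pairs.append(_pair_class(mirna[i], rw[k]))
            pairs.insert(j, "bulge")
            expectation = _score_pairs(tuple(pairs), params)
            if expectation is not None and (best is None or expectation < best.expectation):
                best = DuplexScore(expectation, tuple(pairs))
        return best
    return None  # target bulge required, or unsupported geometry


def call_mode(score: DuplexScore, params: ScoringParams = ScoringParams()) -> str:
    """'translational-inhibition' iff a non-WC pair sits in the central window."""
    for pos in range(params.central_start, params.central_end + 1):
        if pos - 1 < len(score.pairs) and score.pairs[pos - 1] != "wc":
            return "translational-inhibition"
    return "cleavage"


@dataclass
class TargetSite:
    """A scored miRNA binding site on a transcript."""

    mirna_id: str
    transcript_id: str
    start: int  # 0-based half-open transcript interval
    end: int
    expectation: float
    mode: str
    duplex: str
    upe: Optional[float] = None


def gc_open_energy(region: str) -> float:
    """Structure-free site-opening energy proxy from GC content.

    Scaled so that an average-composition region lands below the
    default accessibility cutoff while strongly GC-enriched regions
    exceed it.  Deterministic; a thermodynamic folding backend can be
    substituted via the same callable interface.
    """
    region = canonical(region)
    if not region:
        return 0.0
    gc = sum(region.count(b) for b in "GC") / len(region)
    return round(28.0 * gc + 4.0, 3)


AccessibilityBackend = Callable[[str], float]


def scan_transcript(
    mirna_id: str,
    mirna: str,
    transcript_id: str,
    transcript: str,
    params: ScoringParams = ScoringParams(),
    accessibility: Optional[AccessibilityBackend] = None,
    apply_upe_filter: Optional[bool] = None,
) -> List[TargetSite]:
    """Score every window of a transcript and keep the best local sites.

    Every offset is evaluated (widths m and, when miRNA bulges are
    allowed, m-1); among mutually overlapping accepted duplexes only
    the local-minimum-expectation site is retained (ties: leftmost,
    bulge-free preferred).  When an accessibility backend is given,
    sites whose opening energy over site plus flanks exceeds
    ``params.upe_max`` are removed.
    """
    if apply_upe_filter is None:
        apply_upe_filter = accessibility is not None
    if apply_upe_filter and accessibility is None:
        raise ConfigurationError("UPE filtering requested but no accessibility backend given")
    mirna = canonical(mirna)
    transcript = canonical(transcript)
    m, L = len(mirna), len(transcript)
    if L < params.hsp_size:
        return []
    sites: List[TargetSite] = []
    scored = []
    for start, end in _accepted_windows(mirna, transcript, params):
        score = score_duplex(mirna, transcript[start:end], params)
        if score is None:
            continue
        scored.append((score.expectation, start, end, score))
    scored.sort(key=lambda t: (t[0], t[1], -(t[2] - t[1])))
    kept: List[Tuple[float, int, int, DuplexScore]] = []
    for cand in scored:
        if all(cand[2] <= k[1] or cand[1] >= k[2] for k in kept):
            kept.append(cand)
    kept.sort(key=lambda t: t[1])
    for expectation, start, end, score in kept:
        site = TargetSite(
            mirna_id=mirna_id,
            transcript_id=transcript_id,
            start=start,
            end=end,
            expectation=expectation,
            mode=call_mode(score, params),
            duplex=score.render(),
        )
        if accessibility is not None:
            region = transcript[max(0, start - params.flank_up) : min(L, end + params.flank_down)]
            site.upe = accessibility(region)
            if apply_upe_filter and site.upe > params.upe_max:
                continue
        sites.append(site)
    return sites


def _accepted_windows(
    mirna: str, transcript: str, params: ScoringParams
) -> List[Tuple[int, int]]:
    """Vectorized prefilter: window intervals whose duplex can be accepted.

    Exactness is guaranteed by re-scoring each returned window with
    :func:`score_duplex`; this pass only rules windows in or out, using
    the same penalty table, so scan results equal exhaustive window
    enumeration.
    """
    m, L = len(mirna), len(transcript)
    out: List[Tuple[int, int]] = []
    tr = encode(transcript)
    comp = encode("".join(_COMP[b] for b in mirna))
    gu = encode("".join({"G": "T", "T": "G"}.get(b, "N") for b in mirna))
    seed_mask = np.array(
        [params.seed_start <= i + 1 <= params.seed_end for i in range(m)], dtype=bool
    )
    widths = [(m, None)]
    if params.max_mirna_bulges >= 1:
        widths.extend((m - 1, j) for j in range(m))
    for width, bulge_j in widths:
        if width > L or width < 1:
            continue
        if bulge_j is None:
            c, g, smask = comp, gu, seed_mask
            extra = 0.0
        else:
            keep = np.ones(m, dtype=bool)
            keep[bulge_j] = False
            c, g, smask = comp[keep], gu[keep], seed_mask[keep]
            extra = params.bulge_penalty * (
                params.seed_multiplier if seed_mask[bulge_j] else 1.0
            )
            if extra > params.max_expectation:
                continue
        windows = np.lib.stride_tricks.sliding_window_view(tr, width)[:, ::-1]
        wc = windows == c
        wobble = windows == g
        mm = ~wc & ~wobble
        penalties = np.where(wc, 0.0, np.where(wobble, params.gu_penalty, params.mismatch_penalty))
        penalties = np.where(smask, penalties * params.seed_multiplier, penalties)
        expectation = penalties.sum(axis=1) + extra
        ok = (expectation <= params.max_expectation) & ~(mm & smask).any(axis=1)
        for off in np.flatnonzero(ok):
            out.append((int(off), int(off) + width))
    return sorted(set(out))


def link_expression(
    sites: Sequence[TargetSite],
    mirna_calls: Mapping[str, str],
    transcript_presence: Mapping[str, Sequence[str]],
) -> pd.DataFrame:
    """Join miRNA differential-expression calls with target detection.

    A miRNA over-expressed in one genotype whose target transcript is
    detected only in the other genotype is a repression-consistent
    pair; a target present in both genotypes is flagged 'partial'
    (the repression cannot be attributed to the miRNA alone).
    Returns an empty frame when no miRNA is differentially expressed.
    """
    rows = []
    for site in sites:
        call = mirna_calls.get(site.mirna_id, "ns")
        if not call.startswith("up-in-"):
            continue
        up_geno = call[len("up-in-") :]
        present = set(transcript_presence.get(site.transcript_id, ()))
        if not present:
            verdict = "target-undetected"
        elif up_geno in present and len(present) == 1:
            verdict = "inconsistent"
        elif up_geno not in present:
            verdict = "repression-consistent"
        else:
            verdict = "partial"
        rows.append(
            {
                "mirna_id": site.mirna_id,
                "transcript_id": site.transcript_id,
                "mirna_call": call,
                "target_detected_in": ",".join(sorted(present)),
                "interaction": verdict,
                "expectation": site.expectation,
                "mode": site.mode,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "mirna_id",
            "transcript_id",
            "mirna_call",
            "target_detected_in",
            "interaction",
            "expectation",
            "mode",
        ],
    )
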