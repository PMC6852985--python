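"""Expectation scoring of miRNA-target duplexes and transcript scanning."""

import numpy as np
import pytest

from mirseed._seq import canonical, random_dna, revcomp
from mirseed.core import ConfigurationError
from mirseed.target_scoring import (
    ScoringParams,
    call_mode,
    gc_open_energy,
    link_expression,
    scan_transcript,
    score_duplex,
    TargetSite,
)

PARAMS = ScoringParams()
MIR = canonical("UUGACAGAAGAUAGAGAGCAC")  # 21 nt
PERFECT = revcomp(MIR)

_MM = {"A": "C", "T": "C", "G": "A", "C": "A"}  # a guaranteed true mismatch
_WOBBLE = {"G": "T", "T": "G"}


def _with_pair(window: str, mirna_pos: int, target_base: str) -> str:
    """Replace the target base facing the given 1-based miRNA position."""
    w = list(window)
    w[len(MIR) - mirna_pos] = target_base
    return "".join(w)


class TestScoreDuplex:
    def test_perfect_complement_scores_zero(self):
        score = score_duplex(MIR, PERFECT, PARAMS)
        assert score.expectation == 0.0
        assert set(score.pairs) == {"wc"}

    def test_seed_mismatch_rejects_the_duplex(self):
        window = _with_pair(PERFECT, 3, _MM[MIR[2]])
        assert score_duplex(MIR, window, PARAMS) is None

    def test_central_wobble_costs_one_and_inhibits_translation(self):
        assert MIR[9] in _WOBBLE  # position 10 supports a wobble pair
        window = _with_pair(PERFECT, 10, _WOBBLE[MIR[9]])
        score = score_duplex(MIR, window, PARAMS)
        assert score.expectation == pytest.approx(1.0)  # 0.5 doubled in the seed
        assert call_mode(score, PARAMS) == "translational-inhibition"

    def test_mismatch_outside_seed_costs_one_and_cleaves(self):
        window = _with_pair(PERFECT, 15, _MM[MIR[14]])
        score = score_duplex(MIR, window, PARAMS)
        assert score.expectation == pytest.approx(1.0)
        assert call_mode(score, PARAMS) == "cleavage"

    def test_wobble_outside_central_window_still_cleaves(self):
        pos = 14
        base = MIR[pos - 1]
        if base not in _WOBBLE:
            pytest.skip("position 14 not wobble-capable for this miRNA")
        window = _with_pair(PERFECT, pos, _WOBBLE[base])
        score = score_duplex(MIR, window, PARAMS)
        assert call_mode(score, PARAMS) == "cleavage"

    def test_expectation_cap_rejects_weak_duplexes(self):
        window = PERFECT
        for pos in (14, 15, 16):  # three non-seed mismatches: expectation 3.0 > 2.5
            window = _with_pair(window, pos, _MM[MIR[pos - 1]])
        assert score_duplex(MIR, window, PARAMS) is None

    def test_mirna_bulge_costs_two(self):
        window = PERFECT[:3] + PERFECT[4:]  # drop one target base outside the seed
        score = score_duplex(MIR, window, PARAMS)
        assert score is not None
        assert score.expectation == pytest.approx(2.0)
        assert "bulge" in score.pairs

    def test_longer_window_needs_target_bulge_and_is_rejected(self):
        assert score_duplex(MIR, PERFECT + "A", PARAMS) is None

    def test_alphabet_violation(self):
        with pytest.raises(ValueError):
            score_duplex("ACGX" * 5 + "A", PERFECT, PARAMS)

    def test_degrading_a_pair_never_lowers_the_expectation(self):
        """WC -> G:U -> mismatch is monotone non-decreasing (rejection = +inf)."""
        rng = np.random.default_rng(0)
        for _ in range(50):
            mir = random_dna(rng, 21)
            window = revcomp(mir)
            pos = int(rng.integers(1, 22))
            base = mir[pos - 1]
            exps = []
            for target in (revcomp(mir)[21 - pos], _WOBBLE.get(base), _MM[base]):
                if target is None:
                    continue
                s = score_duplex(mir, _with_pair_generic(mir, window, pos, target), PARAMS)
                exps.append(np.inf if s is None else s.expectation)
            assert all(a <= b for a, b in zip(exps, exps[1:]))


def _with_pair_generic(mirna, window, mirna_pos, target_base):
    w = list(window)
    w[len(mirna) - mirna_pos] = target_base
    return "".join(w)


class TestScan:
    def test_single_planted_site_is_found_exactly_once(self):
        rng = np.random.default_rng(1)
        t = random_dna(rng, 300) + PERFECT + random_dna(rng, 200)
        sites = scan_transcript("m", MIR, "t", t, PARAMS)
        perfect = [s for s in sites if s.expectation == 0.0]
        assert len(perfect) == 1
        assert (perfect[0].start, perfect[0].end) == (300, 321)
        assert perfect[0].mode == "cleavage"

    def test_transcript_without_sites_yields_empty_list(self):
        rng = np.random.default_rng(2)
        sites = scan_transcript("m", MIR, "t", random_dna(rng, 400), PARAMS)
        assert sites == []

    def test_scan_equals_exhaustive_window_enumeration(self):
        """Oracle: score every window of every width explicitly with score_duplex."""
        rng = np.random.default_rng(3)
        for trial in range(60):
            mir = random_dna(rng, int(rng.integers(19, 23)))
            m = len(mir)
            t = random_dna(rng, 120)
            if rng.random() < 0.6:  # plant a (possibly degraded) site
                ins = list(revcomp(mir))
                for pos in rng.choice(m, size=int(rng.integers(0, 3)), replace=False):
                    ins[pos] = "ACGT"[int(rng.integers(0, 4))]
                cut = int(rng.integers(0, len(t) - m))
                t = t[:cut] + "".join(ins) + t[cut + m :]
            oracle = []
            for width in (m, m - 1):
                for off in range(len(t) - width + 1):
                    s = score_duplex(mir, t[off : off + width], PARAMS)
                    if s is not None:
                        oracle.append((off, off + width, s.expectation))
            got = scan_transcript("m", mir, "t", t, PARAMS)
            oracle_set = set(oracle)
            for site in got:
                assert (site.start, site.end, site.expectation) in oracle_set
            # every accepted window is either kept or overlapped by a kept
            # site with an expectation at least as good
            for off, end, exp in oracle:
                assert any(
                    s.expectation <= exp and s.start < end and s.end > off for s in got
                )

    def test_overlapping_sites_reduce_to_the_local_minimum(self):
        rng = np.random.default_rng(4)
        t = random_dna(rng, 60) + PERFECT + random_dna(rng, 60)
        sites = scan_transcript("m", MIR, "t", t, PARAMS)
        starts = [s.start for s in sites]
        assert len(starts) == len(set(starts))
        for a in sites:
            for b in sites:
                if a is not b:
                    assert a.end <= b.start or a.start >= b.end

    def test_upe_filter_requires_a_backend(self):
        with pytest.raises(ConfigurationError):
            scan_transcript("m", MIR, "t", "A" * 100, PARAMS, accessibility=None, apply_upe_filter=True)

    def test_accessibility_backend_annotates_and_filters(self):
        rng = np.random.default_rng(5)
        t = random_dna(rng, 100) + PERFECT + random_dna(rng, 100)
        sites = scan_transcript("m", MIR, "t", t, PARAMS, accessibility=gc_open_energy)
        for s in sites:
            assert s.upe is not None and s.upe <= PARAMS.upe_max
        blocked = scan_transcript(
            "m", MIR, "t", t, ScoringParams(upe_max=0.0), accessibility=gc_open_energy
        )
        assert blocked == []


class TestLinkExpression:
    SITE = TargetSite("mirA", "tx1", 10, 31, 0.0, "cleavage", "|" * 21)

    def test_repression_consistent_pair(self):
        df = link_expression([self.SITE], {"mirA": "up-in-O"}, {"tx1": ["T"]})
        assert list(df["interaction"]) == ["repression-consistent"]

    def test_target_in_both_genotypes_is_partial(self):
        df = link_expression([self.SITE], {"mirA": "up-in-O"}, {"tx1": ["T", "O"]})
        assert list(df["interaction"]) == ["partial"]

    def test_no_differential_mirna_gives_empty_report(self):
        df = link_expression([self.SITE], {"mirA": "ns"}, {"tx1": ["T"]})
        assert df.empty


def test_planted_target_sites_are_recovered_with_no_spurious_hits(analysis):
    """Every implanted perfect-complement site is found; nothing else scores <= 1."""
    truth = analysis.truth
    tx = analysis.refs["transcriptome"]
    queries = {lid: info[3] for lid, info in truth.novel_loci.items()}
    for mid in truth.target_sites:
        if mid not in queries:  # conserved mature miRNAs
            queries[mid] = analysis.refs["mirna_mature"].sequences[mid]
    strict = ScoringParams(max_expectation=1.0)
    found = {}
    all_sites = []
    for qid, qseq in queries.items():
        for tid, tseq in tx.items():
            for site in scan_transcript(qid, qseq, tid, tseq, strict):
                all_sites.append(site)
                if site.expectation == 0.0:
                    found[qid] = (tid, site.start, site.end)
    for source_id, planted in truth.target_sites.items():
        assert found.get(source_id) == planted
    truth_intervals = set(truth.target_sites.values())
    spurious = [
        s
        for s in all_sites
        if not any(
            s.transcript_id == tid and s.start < end and s.end > start
            for tid, start, end in truth_intervals
        )
    ]
    assert spurious == []
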