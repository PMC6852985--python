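"""Synthetic references and genotype-contrasted small-RNA libraries.

Generates everything the pipeline consumes, with complete planted
truth: organellar genomes, an ncRNA family set, a mature + hairpin
miRNA database, a reference transcriptome with planted novel-miRNA
loci, degradation-tiled transcripts and implanted target sites, and
four raw FASTQ libraries (2 genotypes x 2 replicates, 'O' = sexual,
'T' = apomictic) whose reads carry a 3' adapter and a bimodal insert
length distribution peaking at 21 and 24 nt.

Class composition mirrors the marginal statistics of real spikelet
small-RNA libraries from contrasting genotypes: a fraction of a
percent organellar reads, a few percent ncRNA degradation fragments,
~0.4% conserved-miRNA reads, and genotype-specific fold-change spikes
planted on selected read classes.  Reads are drawn by a single
multinomial per library over a fixed pool of insert sequences, plus a
stream of never-repeating random singletons that the minimum-count
filter is meant to discard.

Every output is a pure function of the configuration (seed included).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._seq import random_dna, revcomp
from .core import ConfigurationError, ReferenceSet

LIBRARIES: Tuple[Tuple[str, str, int], ...] = (
    ("O2P1", "O", 1),
    ("O2P2", "O", 2),
    ("T3P1", "T", 1),
    ("T3P2", "T", 2),
)

GENOTYPES = ("O", "T")

_FAMILY_NUMBERS = (156, 396, 827, 2275, 894, 169, 5072, 8175, 172, 398)
_SPECIES = ("osa", "ata", "zma", "bdi", "gma", "ssp", "ath", "ppt")

# offsets around each length mode and their probabilities
_MODE_OFFSETS = np.array([-2, -1, 0, 1, 2])
_MODE_OFFSET_P = np.array([0.05, 0.15, 0.60, 0.15, 0.05])


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic libraries."""

    seed: int = 1
    n_reads_per_library: int = 50_000
    length_modes: Tuple[int, int] = (21, 24)
    length_mode_weights: Tuple[float, float] = (0.55, 0.45)
    adapter: str = "TGGAATTCTCGGGTGCCAAGG"  # Illumina TruSeq small-RNA 3' adapter
    frac_organellar: float = 0.0045
    frac_ncrna: float = 0.045
    frac_conserved_mirna: float = 0.004
    frac_degradation: float = 0.03
    frac_novel_mirna: float = 0.004
    frac_random: float = 0.9125
    n_mirna_families: int = 5
    planted_de: Tuple[Tuple[str, str, float], ...] = (
        ("novel:nov1", "T", 3.0),
        ("novel:nov2", "O", 3.0),
    )
    mismatch_profile: Dict[int, float] = field(
        default_factory=lambda: {0: 0.7, 1: 0.2, 2: 0.1, 3: 0.0}
    )
    singleton_fraction: float = 0.18  # share of the random class drawn as fresh singletons
    read_length: int = 50
    n_transcripts: int = 40
    n_novel_loci: int = 4
    n_degradation_transcripts: int = 2
    n_organellar_fragments: int = 40
    n_ncrna_fragments: int = 150
    n_random_tags: int = 6000

    def __post_init__(self) -> None:
        fracs = self.class_fractions()
        if any(f < 0 for f in fracs.values()):
            raise ConfigurationError("class fractions must be non-negative")
        if abs(sum(fracs.values()) - 1.0) > 1e-9:
            raise ConfigurationError(f"class fractions must sum to 1, got {sum(fracs.values())}")
        if not all(17 <= m <= 33 for m in self.length_modes):
            raise ConfigurationError("length modes must lie in [17, 33]")
        if abs(sum(self.length_mode_weights) - 1.0) > 1e-9:
            raise ConfigurationError("length mode weights must sum to 1")
        if self.n_mirna_families < 1:
            raise ConfigurationError("n_mirna_families must be >= 1")
        if self.n_mirna_families > len(_FAMILY_NUMBERS):
            raise ConfigurationError(f"at most {len(_FAMILY_NUMBERS)} families supported")
        bad = set(self.mismatch_profile) - {0, 1, 2, 3}
        if bad or abs(sum(self.mismatch_profile.values()) - 1.0) > 1e-9:
            raise ConfigurationError("mismatch_profile must be a distribution over {0,1,2,3}")
        if not self.adapter:
            raise ConfigurationError("adapter must be non-empty")

    def class_fractions(self) -> Dict[str, float]:
        return {
            "organellar": self.frac_organellar,
            "ncrna": self.frac_ncrna,
            "conserved": self.frac_conserved_mirna,
            "degradation": self.frac_degradation,
            "novel": self.frac_novel_mirna,
            "random": self.frac_random,
        }


@dataclass
class PoolUnit:
    """One fixed insert sequence with its sampling weight and truth."""

    unit_id: str
    read_class: str
    origin_id: str
    sequence: str
    weight: float


@dataclass
class TruthTable:
    """Complete planted ground truth of one simulation."""

    families: Dict[str, Dict[str, str]] = field(default_factory=dict)
    variant_mismatches: Dict[str, int] = field(default_factory=dict)  # sequence -> k
    variant_source: Dict[str, str] = field(default_factory=dict)  # sequence -> member id
    novel_loci: Dict[str, Tuple[str, int, int, str]] = field(default_factory=dict)
    degradation_transcripts: List[str] = field(default_factory=list)
    target_sites: Dict[str, Tuple[str, int, int]] = field(default_factory=dict)
    planted_de: Tuple[Tuple[str, str, float], ...] = ()
    class_of_sequence: Dict[str, Tuple[str, str]] = field(default_factory=dict)
    reads: Optional[pd.DataFrame] = None
    pool: List[PoolUnit] = field(default_factory=list)

    def reads_frame(self) -> pd.DataFrame:
        if self.reads is None:
            raise ValueError("libraries have not been generated yet")
        return self.reads

    def write_reads_tsv(self, path) -> None:
        self.reads_frame().to_csv(path, sep="\t", index=False)


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def _sample_length(rng: np.random.Generator, config: SimulationConfig) -> int:
    mode = config.length_modes[
        0 if rng.random() < config.length_mode_weights[0] else 1
    ]
    length = mode + int(rng.choice(_MODE_OFFSETS, p=_MODE_OFFSET_P))
    return int(min(33, max(17, length)))


def _mutate(rng: np.random.Generator, seq: str, k: int) -> str:
    """Substitute exactly k distinct positions (always to a different base)."""
    if k == 0:
        return seq
    positions = rng.choice(len(seq), size=k, replace=False)
    out = list(seq)
    for pos in positions:
        choices = [b for b in "ACGT" if b != out[pos]]
        out[pos] = choices[int(rng.integers(0, 3))]
    return "".join(out)


def make_references(config: SimulationConfig) -> Tuple[Dict[str, ReferenceSet], TruthTable]:
    """Build the six reference sets and the reference-level truth.

    Returns reference sets keyed 'mitochondria', 'chloroplast',
    'ncrna', 'mirna_mature', 'mirna_hairpin', 'transcriptome'.
    """
    rng = _rng(config, 0)
    truth = TruthTable(planted_de=tuple(config.planted_de))

    mito = ReferenceSet(
        "mitochondria", "organellar", {"mito_genome": random_dna(rng, 3000)}, "both"
    )
    chloro = ReferenceSet(
        "chloroplast", "organellar", {"chloro_genome": random_dna(rng, 4000)}, "both"
    )

    ncrna_lengths = {
        "rRNA_25S": 1800,
        "rRNA_18S": 900,
        "rRNA_5.8S": 120,
        "tRNA_Ala": 75,
        "tRNA_Gly": 74,
        "snRNA_U6": 105,
        "snoRNA_1": 130,
        "snoRNA_2": 95,
    }
    ncrna = ReferenceSet(
        "ncrna", "ncrna", {rid: random_dna(rng, n) for rid, n in ncrna_lengths.items()}, "forward"
    )

    mature: Dict[str, str] = {}
    hairpin: Dict[str, str] = {}
    for fi in range(config.n_mirna_families):
        number = _FAMILY_NUMBERS[fi]
        family = f"miR{number}"
        base_len = int(rng.choice([20, 21, 22], p=[0.15, 0.7, 0.15]))
        base = random_dna(rng, base_len)
        n_members = int(rng.integers(1, 4))
        truth.families[family] = {}
        for mi in range(n_members):
            species = _SPECIES[int(rng.integers(0, len(_SPECIES)))]
            arm = ["", "-5p", "-3p"][int(rng.integers(0, 3))]
            member_id = f"{species}-miR{number}{chr(ord('a') + mi)}{arm}"
            seq = base if mi == 0 else _mutate(rng, base, int(rng.integers(1, 3)))
            mature[member_id] = seq
            truth.families[family][member_id] = seq
            hp_id = f"{species}-MIR{number}{chr(ord('a') + mi)}"
            hairpin[hp_id] = random_dna(rng, 25) + seq + random_dna(rng, 25)
    mature_set = ReferenceSet("mirna_mature", "mirna-mature", mature, "forward")
    hairpin_set = ReferenceSet("mirna_hairpin", "mirna-hairpin", hairpin, "forward")

    transcripts: Dict[str, str] = {}
    tids = [f"isotig{10000 + i}" for i in range(config.n_transcripts)]
    for tid in tids:
        transcripts[tid] = random_dna(rng, int(rng.integers(400, 1201)))

    needed = config.n_degradation_transcripts + config.n_novel_loci
    if needed + config.n_novel_loci + 3 > config.n_transcripts:
        raise ConfigurationError("not enough transcripts for the requested plantings")
    truth.degradation_transcripts = tids[: config.n_degradation_transcripts]
    novel_hosts = tids[
        config.n_degradation_transcripts : config.n_degradation_transcripts + config.n_novel_loci
    ]
    for i, tid in enumerate(novel_hosts):
        locus_id = f"nov{i + 1}"
        L = len(transcripts[tid])
        start = int(rng.integers(50, L - 71))
        end = start + 21
        truth.novel_loci[locus_id] = (tid, start, end, transcripts[tid][start:end])

    # implant perfect-complement target sites for novel loci and a few
    # conserved miRNAs into transcripts that host nothing else
    target_hosts = tids[needed : needed + config.n_novel_loci + 3]
    sources: List[Tuple[str, str]] = [
        (lid, truth.novel_loci[lid][3]) for lid in sorted(truth.novel_loci)
    ]
    sources += [(mid, mature[mid]) for mid in sorted(mature)[:3]]
    for (source_id, seq), tid in zip(sources, target_hosts):
        site = revcomp(seq)
        L = len(transcripts[tid])
        start = int(rng.integers(40, L - len(site) - 40))
        t = transcripts[tid]
        transcripts[tid] = t[:start] + site + t[start + len(site) :]
        truth.target_sites[source_id] = (tid, start, start + len(site))

    transcriptome = ReferenceSet("transcriptome", "transcriptome", transcripts, "forward")
    refs = {
        "mitochondria": mito,
        "chloroplast": chloro,
        "ncrna": ncrna,
        "mirna_mature": mature_set,
        "mirna_hairpin": hairpin_set,
        "transcriptome": transcriptome,
    }
    _build_pool(config, refs, truth)
    return refs, truth


def _weights(rng: np.random.Generator, n: int, concentration: float) -> np.ndarray:
    w = rng.gamma(concentration, 1.0, size=n)
    return w / w.sum()


def _build_pool(
    config: SimulationConfig, refs: Dict[str, ReferenceSet], truth: TruthTable
) -> None:
    """Fixed insert pool shared by all four libraries."""
    rng = _rng(config, 1)
    pool: List[PoolUnit] = []
    fracs = config.class_fractions()

    def add(unit_id, read_class, origin_id, sequence, weight):
        pool.append(PoolUnit(unit_id, read_class, origin_id, sequence, weight))

    # organellar fragments, both strands
    genomes = list(refs["mitochondria"].items()) + list(refs["chloroplast"].items())
    w = _weights(rng, config.n_organellar_fragments, 2.0) * fracs["organellar"]
    for i in range(config.n_organellar_fragments):
        gid, gseq = genomes[int(rng.integers(0, len(genomes)))]
        length = int(rng.integers(18, 31))
        start = int(rng.integers(0, len(gseq) - length))
        frag = gseq[start : start + length]
        if rng.random() < 0.5:
            frag = revcomp(frag)
        add(f"organellar:{i}", "organellar", gid, frag, w[i])

    # ncRNA degradation fragments, forward strand
    nc = list(refs["ncrna"].items())
    w = _weights(rng, config.n_ncrna_fragments, 2.0) * fracs["ncrna"]
    for i in range(config.n_ncrna_fragments):
        rid, rseq = nc[int(rng.integers(0, len(nc)))]
        length = int(rng.integers(17, 34))
        start = int(rng.integers(0, len(rseq) - length))
        add(f"ncrna:{i}", "ncrna", rid, rseq[start : start + length], w[i])

    # conserved-miRNA tags: exact members plus fixed mismatch variants
    families = sorted(truth.families)
    fam_w = _weights(rng, len(families), 50.0) * fracs["conserved"]
    profile = {k: v for k, v in config.mismatch_profile.items() if v > 0}
    for fw, family in zip(fam_w, families):
        members = sorted(truth.families[family])
        mem_w = _weights(rng, len(members), 50.0) * fw
        for mw, member_id in zip(mem_w, members):
            source = truth.families[family][member_id]
            for k, pk in sorted(profile.items()):
                seq = _mutate(rng, source, k)
                truth.variant_mismatches[seq] = k
                truth.variant_source[seq] = member_id
                add(
                    f"conserved:{family}:{member_id}:mm{k}",
                    "conserved",
                    member_id,
                    seq,
                    mw * pk,
                )

    # planted novel-miRNA loci: reads are the exact locus sequence
    loci = sorted(truth.novel_loci)
    w = _weights(rng, len(loci), 50.0) * fracs["novel"]
    for lw, locus_id in zip(w, loci):
        tid, start, end, seq = truth.novel_loci[locus_id]
        add(f"novel:{locus_id}", "novel", f"{tid}:{start}-{end}", seq, lw)

    # degradation tiling of designated transcripts: overlapping 17-30 nt
    # windows on a start grid spanning the whole transcript
    deg_ids = truth.degradation_transcripts
    per_transcript = fracs["degradation"] / max(1, len(deg_ids))
    for tid in deg_ids:
        tseq = refs["transcriptome"].sequences[tid]
        L = len(tseq)
        n_windows = 60
        w = _weights(rng, n_windows, 2.0) * per_transcript
        for i in range(n_windows):
            length = int(rng.integers(17, 31))
            start = int(round(i * (L - length) / (n_windows - 1)))
            add(
                f"degradation:{tid}:{i}",
                "degradation",
                tid,
                tseq[start : start + length],
                w[i],
            )

    # background: fixed random tags plus a singleton stream
    n_rand = config.n_random_tags
    rand_mass = fracs["random"] * (1.0 - config.singleton_fraction)
    w = _weights(rng, n_rand, 5.0) * rand_mass
    for i in range(n_rand):
        add(f"random:{i}", "random", "background", random_dna(rng, _sample_length(rng, config)), w[i])
    add("singleton", "random", "singleton", "", fracs["random"] * config.singleton_fraction)

    for unit in pool:
        if unit.unit_id != "singleton":
            truth.class_of_sequence.setdefault(unit.sequence, (unit.read_class, unit.origin_id))
    truth.pool = pool


def _de_scale(unit_id: str, genotype: str, planted: Sequence[Tuple[str, str, float]]) -> float:
    scale = 1.0
    for target, de_genotype, log2fc in planted:
        if genotype == de_genotype and (
            unit_id == target or unit_id.startswith(target + ":")
        ):
            scale *= 2.0 ** log2fc
    return scale


def make_libraries(
    config: SimulationConfig,
    refs: Dict[str, ReferenceSet],
    truth: TruthTable,
) -> Dict[str, List[Tuple[str, str, str]]]:
    """Draw the four raw libraries; returns library -> (id, seq, qual) reads.

    Abundances of planted differential classes are scaled by
    2^(log2 fold change) in libraries of the matching genotype before a
    single multinomial draw per library.  The read-level truth table is
    stored on ``truth.reads``.
    """
    if config.n_reads_per_library <= 0:
        raise ConfigurationError("n_reads_per_library must be positive")
    if not truth.pool:
        raise ConfigurationError("make_references must be called first")
    libraries: Dict[str, List[Tuple[str, str, str]]] = {}
    truth_rows: List[Tuple[str, str, str, int, str, str]] = []
    qual = "I" * config.read_length
    for lib_index, (lib, genotype, replicate) in enumerate(LIBRARIES):
        rng = _rng(config, 10 + lib_index)
        weights = np.array(
            [
                u.weight * _de_scale(u.unit_id, genotype, config.planted_de)
                for u in truth.pool
            ]
        )
        weights /= weights.sum()
        counts = rng.multinomial(config.n_reads_per_library, weights)
        inserts: List[Tuple[str, str, str]] = []  # (sequence, class, origin)
        for unit, n in zip(truth.pool, counts):
            if n == 0:
                continue
            if unit.unit_id == "singleton":
                for _ in range(int(n)):
                    seq = random_dna(rng, _sample_length(rng, config))
                    inserts.append((seq, "random", "singleton"))
            else:
                inserts.extend([(unit.sequence, unit.read_class, unit.origin_id)] * int(n))
        order = rng.permutation(len(inserts))
        reads = []
        for out_i, idx in enumerate(order):
            seq, read_class, origin = inserts[idx]
            read_id = f"{lib}_{out_i:06d}"
            raw = seq + config.adapter
            if len(raw) < config.read_length:
                raw += random_dna(rng, config.read_length - len(raw))
            raw = raw[: config.read_length]
            reads.append((read_id, raw, qual))
            truth_rows.append((read_id, lib, genotype, replicate, read_class, origin))
        libraries[lib] = reads
    truth.reads = pd.DataFrame(
        truth_rows, columns=["read_id", "library", "genotype", "replicate", "class", "origin_id"]
    )
    return libraries


def make_qpcr_table(
    config: SimulationConfig,
    truth: TruthTable,
    n_biological: int = 3,
    n_technical: int = 3,
    base_ct: float = 25.0,
    reference_ct: float = 20.0,
    noise_sd: float = 0.05,
) -> pd.DataFrame:
    """Synthetic Ct table consistent with the planted fold changes.

    One assay per planted differential unit plus the reference gene
    ('actin'); expression 2^lfc in the up genotype lowers the target
    Ct by lfc cycles.
    """
    rng = _rng(config, 99)
    rows = []
    assays = [(t.split(":")[-1], g, lfc) for t, g, lfc in truth.planted_de]
    for genotype in GENOTYPES:
        for b in range(1, n_biological + 1):
            sample = f"{genotype}_bio{b}"
            for assay, up_genotype, lfc in assays:
                ct = base_ct - (lfc if genotype == up_genotype else 0.0)
                for _ in range(n_technical):
                    rows.append(
                        (sample, genotype, assay, round(ct + rng.normal(0.0, noise_sd), 3))
                    )
            for _ in range(n_technical):
                rows.append(
                    (sample, genotype, "actin", round(reference_ct + rng.normal(0.0, noise_sd), 3))
                )
    return pd.DataFrame(rows, columns=["sample", "genotype", "assay", "ct"])


def write_outputs(
    config: SimulationConfig,
    refs: Dict[str, ReferenceSet],
    truth: TruthTable,
    libraries: Dict[str, List[Tuple[str, str, str]]],
    outdir,
) -> Dict[str, str]:
    """Write references (FASTA), libraries (FASTQ) and truth (TSV)."""
    from pathlib import Path

    from .io import write_fasta, write_fastq

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, str] = {}
    for key, ref in refs.items():
        p = outdir / f"{key}.fasta"
        write_fasta(ref.sequences, p)
        paths[key] = str(p)
    for lib, reads in libraries.items():
        p = outdir / f"{lib}.fastq"
        write_fastq(reads, p)
        paths[lib] = str(p)
    truth_path = outdir / "truth_reads.tsv"
    truth.write_reads_tsv(truth_path)
    paths["truth_reads"] = str(truth_path)
    return paths
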