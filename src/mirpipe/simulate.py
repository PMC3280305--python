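"""Synthetic small-RNA study generator.

Builds a fully specified toy study with recorded ground truth: a random
genome with embedded miRNA hairpins (some clustered within 10 kb, some
designated "known" and exported as a mature+hairpin reference, the rest
left for novel prediction), and two adapter-ligated read libraries
whose per-miRNA counts are Poisson draws around configured abundances
and log2 fold changes.  Reads carry 3'-biased isomiR end variation,
single-substitution seed edits at a configurable rate with a dominant
substitution type, miR* reads, and background degradation fragments,
so every pipeline stage has planted signal to recover.

Hairpins are built constructively — a GC-balanced mature, a short loop,
and the mature's reverse complement as the opposite arm — so they
satisfy the hairpin screening criteria (long perfect stem, strongly
negative MFE) by construction rather than by reference to any folding
backend.  All randomness flows through one seeded generator; identical
seeds give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .io import revcomp, write_fasta
from .regions import GenomicLocus

BASES = np.array(list("ACGT"))

#: 3'-biased isomiR end-offset distributions (5' tight, 3' ragged)
DEFAULT_O5_PROFILE = {0: 0.90, 1: 0.05, -1: 0.05}
DEFAULT_O3_PROFILE = {0: 0.50, 1: 0.20, -1: 0.15, 2: 0.10, -2: 0.05}

#: ordered substitution weights for injected seed edits (A->G dominant)
DEFAULT_EDIT_WEIGHTS = {("A", "G"): 10.0}
_ALL_SUBS = [(a, b) for a in "ACGT" for b in "ACGT" if a != b]

DEFAULT_ADAPTER3 = "TCGTATGCCGTCTTCTGCTTG"
DEFAULT_ADAPTER5 = "GTTCAGAGTTCTACAGTCCGACGATC"
READ_LENGTH = 35


@dataclass
class SimHairpin:
    """One planted hairpin with full provenance."""

    name: str
    chrom: str
    strand: str
    precursor_start: int  # genome coords, 0-based half-open
    precursor_end: int
    precursor: str  # transcript orientation
    mature: str
    star: str
    arm: str  # arm carrying the mature
    mature_offset: int  # mature start within precursor
    known: bool
    clustered: bool = False
    context: str = ""  # flanked mature (isomiR template), transcript strand
    context_pad: int = 10
    ref_hairpin: str = ""  # precursor with short genomic flanks, as a
    # reference database would record it

    @property
    def mature_locus(self) -> GenomicLocus:
        off = self.mature_offset
        if self.strand == "+":
            s = self.precursor_start + off
        else:
            s = self.precursor_end - off - len(self.mature)
        return GenomicLocus(self.chrom, s, s + len(self.mature), self.strand, self.name)

    @property
    def precursor_locus(self) -> GenomicLocus:
        return GenomicLocus(
            self.chrom, self.precursor_start, self.precursor_end, self.strand, self.name
        )


@dataclass
class SimTruth:
    """Complete ground truth of one simulated study."""

    genome: dict[str, str]
    hairpins: list[SimHairpin]
    abundances: dict[str, float] = field(default_factory=dict)
    log2fc: dict[str, float] = field(default_factory=dict)
    effective_log2fc: dict[str, float] = field(default_factory=dict)
    isomir_o5: dict[int, float] = field(default_factory=lambda: dict(DEFAULT_O5_PROFILE))
    isomir_o3: dict[int, float] = field(default_factory=lambda: dict(DEFAULT_O3_PROFILE))
    seed_edit_rate: float = 0.02
    adapter3: str = DEFAULT_ADAPTER3
    adapter5: str = DEFAULT_ADAPTER5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for hp in self.hairpins:
            assert hp.mature in hp.precursor or revcomp(hp.mature) in hp.precursor
            g = self.genome[hp.chrom][hp.precursor_start : hp.precursor_end]
            embedded = hp.precursor if hp.strand == "+" else revcomp(hp.precursor)
            assert g == embedded, f"{hp.name}: precursor not at recorded locus"

    @property
    def known_reference(self) -> tuple[dict[str, str], dict[str, str]]:
        """(mature, hairpin) FASTA dicts for the known subset."""
        matures = {h.name: h.mature for h in self.hairpins if h.known}
        hairpins = {
            h.name.replace("miR", "mir"): h.ref_hairpin or h.precursor
            for h in self.hairpins
            if h.known
        }
        return matures, hairpins


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=n)])


def _gc(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq)


def _make_hairpin(rng: np.random.Generator, name: str, arm: str, mature_len: int = 22) -> tuple[str, str, int]:
    """Constructive hairpin: mature + loop + reverse-complement arm.

    Returns (precursor, mature, mature_offset).  The mature is
    resampled until GC-balanced so the perfect stem is strongly
    stabilising regardless of energy parameters.
    """
    while True:
        mature = _random_seq(rng, mature_len)
        if 0.45 <= _gc(mature) <= 0.65:
            break
    loop = _random_seq(rng, int(rng.integers(10, 15)))
    if arm == "5p":
        precursor = mature + loop + revcomp(mature)
        offset = 0
    else:
        precursor = revcomp(mature) + loop + mature
        offset = len(mature) + len(loop)
    return precursor, mature, offset


def simulate_genome(
    n_chroms: int = 2,
    chrom_len: int = 200_000,
    n_hairpins: int = 20,
    n_clustered: int = 4,
    n_known: int = 10,
    seed: int = 0,
    cluster_spacing: int = 3_000,
    spacing: int = 15_000,
    mature_len: int = 22,
) -> SimTruth:
    """Uniform-random genome with embedded compliant hairpins.

    ``n_clustered`` hairpins are placed ``cluster_spacing`` apart
    (< 10 kb gaps) on the first chromosome to form one known cluster;
    all other placements keep >= ``spacing`` so no accidental clusters
    arise.  Known status alternates along the hairpin list until
    ``n_known`` is reached.  Raises on infeasible packing.
    """
    if n_clustered not in (0, *range(2, n_hairpins + 1)):
        raise ValueError("n_clustered must be 0 or >= 2")
    rng = np.random.default_rng(seed)
    chrom_names = [f"chr{i + 1}" for i in range(n_chroms)]
    chroms = {c: list(_random_seq(rng, chrom_len)) for c in chrom_names}

    # placement slots: cluster block first, then round-robin spaced
    # singles so no accidental < 10 kb gaps arise
    slots: list[tuple[str, int]] = []
    margin = 25_000
    pos = margin
    for _ in range(n_clustered):
        slots.append((chrom_names[0], pos))
        pos += cluster_spacing
    last_at = {c: None for c in chrom_names}
    if n_clustered:
        last_at[chrom_names[0]] = pos - cluster_spacing
    for k in range(n_hairpins - n_clustered):
        chrom = chrom_names[k % n_chroms]
        at = margin if last_at[chrom] is None else last_at[chrom] + spacing
        if at + 200 > chrom_len - margin:
            raise ValueError("infeasible packing: chromosomes too short for hairpin count")
        slots.append((chrom, at))
        last_at[chrom] = at

    known_flags = _known_flags(n_hairpins, n_known)
    hairpins: list[SimHairpin] = []
    pad = 10
    for i, (chrom, at) in enumerate(slots):
        arm = "5p" if i % 2 == 0 else "3p"
        name = f"syn-miR-{i + 1:03d}"
        precursor, mature, offset = _make_hairpin(rng, name, arm, mature_len)
        strand = "+" if rng.random() < 0.5 else "-"
        jitter = int(rng.integers(-500, 501))
        start = at + jitter
        end = start + len(precursor)
        embedded = precursor if strand == "+" else revcomp(precursor)
        chroms[chrom][start:end] = list(embedded)
        hairpins.append(
            SimHairpin(
                name=name,
                chrom=chrom,
                strand=strand,
                precursor_start=start,
                precursor_end=end,
                precursor=precursor,
                mature=mature,
                star="",  # filled below from genomic context
                arm=arm,
                mature_offset=offset,
                known=known_flags[i],
                clustered=i < n_clustered,
            )
        )

    genome = {c: "".join(chars) for c, chars in chroms.items()}
    for hp in hairpins:
        _fill_context(hp, genome, pad)
    truth = SimTruth(genome=genome, hairpins=hairpins, rng_seed=seed)
    return truth


def _known_flags(n: int, n_known: int) -> list[bool]:
    flags = [False] * n
    for i in range(min(2 * n_known, n)):
        if i % 2 == 0 and sum(flags) < n_known:
            flags[i] = True
    i = 0
    while sum(flags) < min(n_known, n):
        if not flags[i]:
            flags[i] = True
        i += 1
    return flags


def _fill_context(hp: SimHairpin, genome: dict[str, str], pad: int) -> None:
    """Record the +/- pad nt transcript-oriented context of the mature
    (isomiR template) and the construction-implied miR* sequence
    (opposite arm with the 2-nt Dicer offset)."""
    ml = hp.mature_locus
    contig = genome[ml.chrom]
    if hp.strand == "+":
        ctx = contig[ml.start - pad : ml.end + pad]
    else:
        ctx = revcomp(contig[ml.start - pad : ml.end + pad])
    hp.context = ctx
    hp.context_pad = pad

    # reference hairpin entry: precursor plus 5 nt of genomic flank on
    # each side, as curated precursor databases record stem-loops
    pl = hp.precursor_locus
    if hp.strand == "+":
        hp.ref_hairpin = contig[pl.start - 5 : pl.end + 5]
    else:
        hp.ref_hairpin = revcomp(contig[pl.start - 5 : pl.end + 5])

    # star arm in transcript orientation, shifted 2 nt 3'-ward
    pl = hp.precursor_locus
    if hp.strand == "+":
        tx = contig[pl.start : pl.end + 2]
    else:
        tx = revcomp(contig[pl.start - 2 : pl.end])
    n_m = len(hp.mature)
    if hp.arm == "5p":
        star_arm_start = len(hp.precursor) - n_m
        hp.star = tx[star_arm_start + 2 : star_arm_start + n_m + 2]
    else:
        hp.star = tx[2 : n_m + 2]


@dataclass
class SimLibrary:
    """One simulated library: raw FASTQ-style reads plus per-class truth."""

    reads: list[tuple[str, str]]  # (read id, 35 nt sequence)
    mirna_counts: dict[str, int]  # Poisson-drawn mature counts
    class_counts: dict[tuple, int]  # (name, kind, detail) -> reads


def _choice(rng: np.random.Generator, items: list, probs: list[float]) -> object:
    p = np.asarray(probs, dtype=float)
    return items[rng.choice(len(items), p=p / p.sum())]


def _variant_seq(hp: SimHairpin, o5: int, o3: int) -> str:
    pad = hp.context_pad
    return hp.context[pad + o5 : pad + len(hp.mature) + o3]


def _edited_seq(
    rng: np.random.Generator, hp: SimHairpin, weights: dict[tuple[str, str], float]
) -> Optional[tuple[str, int, str, str]]:
    """Canonical mature with one weighted substitution at seed
    positions 2-8.  Returns (sequence, position_1based, from, to)."""
    seed = hp.mature[1:8]
    avail = [(a, b) for a, b in _ALL_SUBS if a in seed]
    if not avail:
        return None
    w = [weights.get(t, 1.0) for t in avail]
    ref, obs = _choice(rng, avail, w)
    positions = [i for i in range(1, 8) if hp.mature[i] == ref]
    pos = int(positions[rng.integers(0, len(positions))])
    seq = hp.mature[:pos] + obs + hp.mature[pos + 1 :]
    return seq, pos + 1, ref, obs


def simulate_libraries(
    truth: SimTruth,
    depth1: int = 50_000,
    depth2: int = 50_000,
    seed: int = 1,
    *,
    de_fraction: float = 0.3,
    de_log2fc: float = 2.0,
    bg_fraction: float = 0.15,
    star_fraction: float = 0.10,
    seed_edit_rate: float | None = None,
    edit_weights: dict[tuple[str, str], float] | None = None,
    abundance_sigma: float = 1.0,
) -> tuple[SimLibrary, SimLibrary]:
    """Draw two read libraries from the planted truth.

    Per-miRNA relative abundances are lognormal; a ``de_fraction`` of
    miRNAs get +/-``de_log2fc`` fold changes (balanced signs) applied
    to library 2.  Counts are Poisson at the library depths; the
    abundance table, assigned and *effective* (renormalised) log2 fold
    changes are recorded on ``truth``.  Reads are mature sequences with
    3'-biased end offsets, seed-edited variants at ``seed_edit_rate``,
    miR* reads at ``star_fraction`` of the mature count, and background
    genome fragments (length mode 22 nt), each with the 3' adapter
    appended and truncated to 35 nt.
    """
    rng = np.random.default_rng(seed)
    if seed_edit_rate is None:
        seed_edit_rate = truth.seed_edit_rate
    truth.seed_edit_rate = seed_edit_rate
    weights = dict(DEFAULT_EDIT_WEIGHTS) if edit_weights is None else edit_weights

    hps = truth.hairpins
    n = len(hps)
    rel = np.exp(rng.normal(0.0, abundance_sigma, size=n))
    fc = np.zeros(n)
    n_de = int(round(de_fraction * n))
    de_idx = rng.choice(n, size=n_de, replace=False)
    signs = np.where(np.arange(n_de) % 2 == 0, 1.0, -1.0)
    fc[de_idx] = signs * de_log2fc

    w1 = rel / rel.sum()
    w2u = rel * np.power(2.0, fc)
    w2 = w2u / w2u.sum()
    mirna_share = 1.0 - bg_fraction
    for i, hp in enumerate(hps):
        truth.abundances[hp.name] = float(rel[i])
        truth.log2fc[hp.name] = float(fc[i])
        truth.effective_log2fc[hp.name] = float(np.log2(w2[i] / w1[i]))

    libs = []
    for lib_no, (depth, w) in enumerate(((depth1, w1), (depth2, w2)), start=1):
        reads: list[tuple[str, str]] = []
        mirna_counts: dict[str, int] = {}
        class_counts: dict[tuple, int] = {}
        rid = 0

        def emit(seq: str, key: tuple, times: int) -> None:
            nonlocal rid
            if times <= 0:
                return
            class_counts[key] = class_counts.get(key, 0) + times
            full = (seq + truth.adapter3 * 3)[:READ_LENGTH]
            for _ in range(times):
                rid += 1
                reads.append((f"lib{lib_no}_r{rid}", full))

        for i, hp in enumerate(hps):
            count = int(rng.poisson(depth * mirna_share * w[i]))
            mirna_counts[hp.name] = count
            n_edit = int(rng.binomial(count, seed_edit_rate)) if count else 0
            for _ in range(n_edit):
                edited = _edited_seq(rng, hp, weights)
                if edited is None:
                    n_edit -= 1
                    continue
                seq, pos, ref, obs = edited
                emit(seq, (hp.name, "seed_edit", (pos, ref, obs)), 1)
            # isomiR mix over end-offset combos
            o5s, p5 = zip(*sorted(truth.isomir_o5.items()))
            o3s, p3 = zip(*sorted(truth.isomir_o3.items()))
            combos = [(a, b) for a in o5s for b in o3s]
            probs = np.array([pa * pb for pa in p5 for pb in p3])
            alloc = rng.multinomial(count - n_edit, probs / probs.sum())
            for (o5, o3), times in zip(combos, alloc):
                if times:
                    emit(_variant_seq(hp, o5, o3), (hp.name, "isomir", (o5, o3)), int(times))
            n_star = int(rng.poisson(star_fraction * count))
            emit(hp.star, (hp.name, "star", ()), n_star)

        # background degradation fragments, avoiding planted precursors
        n_bg = int(rng.poisson(depth * bg_fraction))
        chrom_names = sorted(truth.genome)
        lens = {c: len(truth.genome[c]) for c in chrom_names}
        blocked = [
            (hp.chrom, hp.precursor_start - 35, hp.precursor_end + 35) for hp in hps
        ]
        made = 0
        while made < n_bg:
            chrom = chrom_names[int(rng.integers(0, len(chrom_names)))]
            length = int(np.clip(round(rng.normal(22.0, 2.5)), 18, 30))
            pos = int(rng.integers(0, lens[chrom] - length))
            if any(c == chrom and a < pos + length and pos < b for c, a, b in blocked):
                continue
            frag = truth.genome[chrom][pos : pos + length]
            if rng.random() < 0.5:
                frag = revcomp(frag)
            emit(frag, ("background", "background", ()), 1)
            made += 1

        libs.append(SimLibrary(reads=reads, mirna_counts=mirna_counts, class_counts=class_counts))
    return libs[0], libs[1]


def shuffle_genome(genome: dict[str, str], seed: int = 0) -> dict[str, str]:
    """Per-chromosome nucleotide shuffle — same composition, all
    planted structure destroyed (negative control)."""
    rng = np.random.default_rng(seed)
    out = {}
    for chrom in sorted(genome):
        chars = np.array(list(genome[chrom]))
        rng.shuffle(chars)
        out[chrom] = "".join(chars)
    return out


def write_truth(truth: SimTruth, lib1: SimLibrary, lib2: SimLibrary, outdir: str | Path) -> dict[str, Path]:
    """Write genome/reference FASTA, FASTQ libraries and truth TSVs."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["genome"] = out / "genome.fa"
    write_fasta(truth.genome, paths["genome"])
    matures, hairpins = truth.known_reference
    paths["mature"] = out / "known_mature.fa"
    paths["hairpin"] = out / "known_hairpin.fa"
    write_fasta(matures, paths["mature"])
    write_fasta(hairpins, paths["hairpin"])

    for lib_no, lib in ((1, lib1), (2, lib2)):
        p = out / f"lib{lib_no}.fastq"
        with open(p, "w") as fh:
            for rid, seq in lib.reads:
                fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")
        paths[f"lib{lib_no}"] = p

    paths["hairpins_tsv"] = out / "truth_hairpins.tsv"
    with open(paths["hairpins_tsv"], "w") as fh:
        fh.write(
            "name\tchrom\tstart\tend\tstrand\tarm\tknown\tclustered\t"
            "mature\tstar\tprecursor\n"
        )
        for hp in truth.hairpins:
            fh.write(
                f"{hp.name}\t{hp.chrom}\t{hp.precursor_start}\t{hp.precursor_end}\t"
                f"{hp.strand}\t{hp.arm}\t{int(hp.known)}\t{int(hp.clustered)}\t"
                f"{hp.mature}\t{hp.star}\t{hp.precursor}\n"
            )

    paths["expression_tsv"] = out / "truth_expression.tsv"
    with open(paths["expression_tsv"], "w") as fh:
        fh.write("name\tabundance\tlog2fc\teffective_log2fc\tcount_lib1\tcount_lib2\n")
        for hp in truth.hairpins:
            fh.write(
                f"{hp.name}\t{truth.abundances.get(hp.name, float('nan')):.6g}\t"
                f"{truth.log2fc.get(hp.name, float('nan')):.4g}\t"
                f"{truth.effective_log2fc.get(hp.name, float('nan')):.6g}\t"
                f"{lib1.mirna_counts.get(hp.name, 0)}\t{lib2.mirna_counts.get(hp.name, 0)}\n"
            )
    return paths


@dataclass
class SimConfig:
    """YAML-loadable simulation settings (defaults are the package's
    standard study conditions)."""

    seed: int = 0
    n_chroms: int = 2
    chrom_len: int = 200_000
    n_hairpins: int = 20
    n_clustered: int = 4
    n_known: int = 10
    depth1: int = 50_000
    depth2: int = 50_000
    de_fraction: float = 0.3
    de_log2fc: float = 2.0
    bg_fraction: float = 0.15
    star_fraction: float = 0.10
    seed_edit_rate: float = 0.02

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def run_simulation(cfg: SimConfig) -> tuple[SimTruth, SimLibrary, SimLibrary]:
    truth = simulate_genome(
        n_chroms=cfg.n_chroms,
        chrom_len=cfg.chrom_len,
        n_hairpins=cfg.n_hairpins,
        n_clustered=cfg.n_clustered,
        n_known=cfg.n_known,
        seed=cfg.seed,
    )
    truth.seed_edit_rate = cfg.seed_edit_rate
    lib1, lib2 = simulate_libraries(
        truth,
        depth1=cfg.depth1,
        depth2=cfg.depth2,
        seed=cfg.seed + 1,
        de_fraction=cfg.de_fraction,
        de_log2fc=cfg.de_log2fc,
        bg_fraction=cfg.bg_fraction,
        star_fraction=cfg.star_fraction,
        seed_edit_rate=cfg.seed_edit_rate,
    )
    return truth, lib1, lib2
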