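"""Novel miRNA hairpin prediction.

Unannotated tags are mapped exactly to the genome, flanking windows are
excised so that the tag can sit on either hairpin arm, windows are
folded with a nearest-neighbor thermodynamic model (ViennaRNA), and
each fold is screened with standard pre-miRNA criteria:

* minimum free energy <= -18 kcal/mol,
* mature 18-26 nt, entirely on one arm (no terminal-loop overlap),
* >= 16 base pairs between the mature:miR* duplex span (the mature
  plus the 2-nt Dicer offset on its loop-proximal side) and the
  opposite arm,
* no asymmetric internal loop/bulge larger than 4 nt in the duplex,
* hairpin window <= 200 nt.

Failed criteria are enumerated as reason codes.  A predicted miR*
sequence (2-nt 3' overhang geometry) supports, but is not required
for, a pass.  Loci of passing candidates can be classified against a
gene model as exonic / intronic / mixed / intergenic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import RNA

from .io import revcomp
from .preprocess import CleanTag
from .regions import GenomicLocus


@dataclass
class HairpinThresholds:
    """Screening thresholds (standard hairpin-prediction defaults)."""

    max_mfe: float = -18.0  # kcal/mol
    min_mature_len: int = 18
    max_mature_len: int = 26
    min_duplex_pairs: int = 16
    max_bulge: int = 4  # nt of asymmetry within the duplex
    max_hairpin_len: int = 200


DEFAULT_THRESHOLDS = HairpinThresholds()


@dataclass
class HairpinCandidate:
    """An excised, folded genomic window evaluated as a pre-miRNA."""

    window: str
    window_locus: Optional[GenomicLocus]
    mature_start: int  # within window, 0-based half-open
    mature_end: int
    structure: str = ""
    mfe: float = 0.0
    mature_arm: Optional[str] = None
    star_seq: Optional[str] = None
    passed: bool = False
    reasons: list[str] = field(default_factory=list)
    truncated: bool = False


def map_to_genome(
    tag: CleanTag | str, genome: Mapping[str, str], max_hits: int = 20
) -> list[GenomicLocus]:
    """Exact full-length matches of the tag on both genome strands.

    Tags hitting more than ``max_hits`` loci are treated as repeats and
    return an empty list.
    """
    seq = tag.sequence if isinstance(tag, CleanTag) else tag
    rc = revcomp(seq)
    loci: list[GenomicLocus] = []
    for chrom in sorted(genome):
        contig = genome[chrom]
        for query, strand in ((seq, "+"), (rc, "-")):
            pos = contig.find(query)
            while pos >= 0:
                loci.append(GenomicLocus(chrom, pos, pos + len(query), strand, sequence=seq))
                if len(loci) > max_hits:
                    return []
                pos = contig.find(query, pos + 1)
    # palindromic tags would hit both strands at one interval; keep one
    seen: set[tuple] = set()
    unique = []
    for l in loci:
        if (l.chrom, l.start, l.end) not in seen:
            seen.add((l.chrom, l.start, l.end))
            unique.append(l)
    return unique


@dataclass
class Window:
    """One excised candidate window with the tag placed inside it,
    in transcription (5'->3') orientation."""

    sequence: str
    tag_start: int  # within window
    tag_end: int
    locus: GenomicLocus  # genomic coordinates of the window
    truncated: bool = False


def excise_window(
    locus: GenomicLocus, genome: Mapping[str, str], up: int = 70, down: int = 20
) -> tuple[Window, Window]:
    """Two candidate windows around a mapped tag.

    The first places the tag on the 5' arm (``up`` nt upstream, ``down``
    downstream in transcription orientation), the second on the 3' arm.
    Minus-strand windows are reverse-complemented.  Windows truncated at
    a contig edge are flagged.
    """
    contig = genome[locus.chrom]
    if locus.strand == "+":
        spans = [(locus.start - up, locus.end + down), (locus.start - down, locus.end + up)]
    else:
        spans = [(locus.start - down, locus.end + up), (locus.start - up, locus.end + down)]
    windows = []
    for gstart, gend in spans:
        start, end = max(0, gstart), min(len(contig), gend)
        truncated = (start, end) != (gstart, gend)
        seq = contig[start:end]
        if locus.strand == "+":
            t0 = locus.start - start
        else:
            seq = revcomp(seq)
            t0 = end - locus.end
        windows.append(
            Window(
                sequence=seq,
                tag_start=t0,
                tag_end=t0 + locus.length,
                locus=GenomicLocus(locus.chrom, start, end, locus.strand),
                truncated=truncated,
            )
        )
    return windows[0], windows[1]


def fold_hairpin(window: str) -> tuple[str, float]:
    """Fold a window into (dot-bracket structure, MFE in kcal/mol)
    under the nearest-neighbor model shipped with ViennaRNA."""
    if len(window) < 40:
        raise ValueError("window shorter than 40 nt")
    rna = window.upper().replace("T", "U")
    if set(rna) - set("ACGU"):
        raise ValueError(f"non-ACGU characters in window: {sorted(set(rna) - set('ACGU'))}")
    structure, mfe = RNA.fold(rna)
    return structure, round(float(mfe), 2)


def _pair_table(structure: str) -> list[int]:
    """0-based partner index per position, -1 when unpaired."""
    pt = RNA.ptable(structure)
    return [p - 1 for p in pt[1:]]


def evaluate_candidate(
    window: str,
    mature_start: int,
    mature_end: int,
    structure: str | None = None,
    mfe: float | None = None,
    thresholds: HairpinThresholds = DEFAULT_THRESHOLDS,
    window_locus: GenomicLocus | None = None,
) -> HairpinCandidate:
    """Screen a folded window against the hairpin criteria.

    ``reasons`` enumerates every failed criterion:
    ``mfe_above_threshold``, ``mature_length``, ``hairpin_too_long``,
    ``loop_overlap`` (mature pairs into itself or across the terminal
    loop), ``insufficient_pairing``, ``bulge_too_large``.
    """
    if structure is None or mfe is None:
        structure, mfe = fold_hairpin(window)
    if len(structure) != len(window):
        raise ValueError("structure/window length mismatch")

    t = thresholds
    reasons: list[str] = []
    s, e = mature_start, mature_end
    mature_len = e - s

    if mfe > t.max_mfe:
        reasons.append("mfe_above_threshold")
    if not (t.min_mature_len <= mature_len <= t.max_mature_len):
        reasons.append("mature_length")
    if len(window) > t.max_hairpin_len:
        reasons.append("hairpin_too_long")

    pt = _pair_table(structure)
    partners = [pt[i] for i in range(s, e) if pt[i] >= 0]
    arm: Optional[str] = None
    star: Optional[str] = None

    if not partners:
        reasons.append("insufficient_pairing")
        arm = "5p" if (s + e) / 2 < len(window) / 2 else "3p"
    else:
        inside = [p for p in partners if s <= p < e]
        above = [p for p in partners if p >= e]
        below = [p for p in partners if p < s]
        if inside or (above and below):
            reasons.append("loop_overlap")
        else:
            arm = "5p" if above else "3p"
            # duplex span: mature plus the 2-nt Dicer offset on the
            # loop-proximal side
            if arm == "5p":
                span = range(s, min(e + 2, len(window)))
            else:
                span = range(max(s - 2, 0), e)
            span_pairs = [(i, pt[i]) for i in span if pt[i] >= 0 and not (s <= pt[i] < e)]
            if len(span_pairs) < t.min_duplex_pairs:
                reasons.append("insufficient_pairing")
            # asymmetric internal loops within the duplex
            for (i1, j1), (i2, j2) in zip(span_pairs, span_pairs[1:]):
                asym = abs(abs(i2 - i1) - abs(j1 - j2))
                if asym > t.max_bulge:
                    reasons.append("bulge_too_large")
                    break
            # predicted miR*: partners of the mature's own paired ends
            # (not the whole duplex span), shifted 2 nt for the 3'
            # overhang geometry
            mature_paired = [i for i in range(s, e) if pt[i] >= 0]
            if mature_paired:
                i_first, i_last = mature_paired[0], mature_paired[-1]
                j_lo = min(pt[i_first], pt[i_last])
                j_hi = max(pt[i_first], pt[i_last])
                a, b = j_lo + 2, j_hi + 3
                if 0 <= a < b <= len(window):
                    star = window[a:b]

    return HairpinCandidate(
        window=window,
        window_locus=window_locus,
        mature_start=s,
        mature_end=e,
        structure=structure,
        mfe=mfe,
        mature_arm=arm,
        star_seq=star,
        passed=not reasons,
        reasons=reasons,
    )


def star_consistency(
    candidate: HairpinCandidate, tags: Sequence[CleanTag | str], slack: int = 1
) -> bool:
    """True iff an observed tag matches the predicted miR* within
    ``slack`` nt at each end (2-nt 3' overhang duplex geometry).
    Supporting evidence only — never required for a pass."""
    if not candidate.star_seq:
        return False
    star = candidate.star_seq
    window = candidate.window
    pos = window.find(star)
    if pos < 0:
        return False
    observed = {t.sequence if isinstance(t, CleanTag) else t for t in tags}
    for ds in range(-slack, slack + 1):
        for de in range(-slack, slack + 1):
            a, b = pos + ds, pos + len(star) + de
            if 0 <= a < b <= len(window) and window[a:b] in observed:
                return True
    return False


@dataclass
class GeneModel:
    """One gene with its exon intervals (introns are the gaps)."""

    name: str
    chrom: str
    start: int
    end: int
    exons: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"gene {self.name}: invalid interval")
        for a, b in self.exons:
            if not (self.start <= a < b <= self.end):
                raise ValueError(f"gene {self.name}: exon ({a},{b}) outside gene")


def load_gene_models(gff3_path) -> list[GeneModel]:
    """Read gene/exon features from a GFF3 file (gffutils, in-memory)."""
    import gffutils

    db = gffutils.create_db(
        str(gff3_path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes = []
    for g in db.features_of_type("gene"):
        exons = [
            (e.start - 1, e.end)
            for e in db.children(g, featuretype="exon", order_by="start")
        ]
        genes.append(
            GeneModel(
                name=g.id, chrom=g.seqid, start=g.start - 1, end=g.end, exons=exons
            )
        )
    return genes


def classify_context(locus: GenomicLocus, genes: Sequence[GeneModel]) -> str:
    """Genomic context of a locus relative to a gene model.

    Categories: ``intergenic``, ``exon``, ``intron``,
    ``intron_and_exon_one_gene``, ``intron_and_exon_two_genes``.
    """
    overlapping = [
        g
        for g in genes
        if g.chrom == locus.chrom and g.start < locus.end and locus.start < g.end
    ]
    if not overlapping:
        return "intergenic"
    if len(overlapping) >= 2:
        return "intron_and_exon_two_genes"
    gene = overlapping[0]
    for a, b in gene.exons:
        if a <= locus.start and locus.end <= b:
            return "exon"
    introns = [
        (b1, a2) for (a1, b1), (a2, b2) in zip(gene.exons, gene.exons[1:])
    ]
    for a, b in introns:
        if a <= locus.start and locus.end <= b:
            return "intron"
    return "intron_and_exon_one_gene"


def predict_novel(
    tags: Sequence[CleanTag],
    genome: Mapping[str, str],
    *,
    thresholds: HairpinThresholds = DEFAULT_THRESHOLDS,
    max_hits: int = 20,
    up: int = 70,
    down: int = 20,
    min_reads: int = 1,
) -> list[HairpinCandidate]:
    """Full prediction pass: map each tag, excise both arm windows,
    fold, evaluate; keep the best passing candidate per locus (lower
    MFE wins between the two arm placements)."""
    passing: list[HairpinCandidate] = []
    for tag in tags:
        if tag.total < min_reads:
            continue
        for locus in map_to_genome(tag, genome, max_hits):
            best: Optional[HairpinCandidate] = None
            for win in excise_window(locus, genome, up, down):
                if len(win.sequence) < 40:
                    continue
                cand = evaluate_candidate(
                    win.sequence,
                    win.tag_start,
                    win.tag_end,
                    thresholds=thresholds,
                    window_locus=win.locus,
                )
                cand.truncated = win.truncated
                if cand.passed and (best is None or cand.mfe < best.mfe):
                    best = cand
            if best is not None:
                passing.append(best)
    return passing
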