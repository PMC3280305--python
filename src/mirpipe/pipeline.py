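"""End-to-end orchestration of the small-RNA analysis stages:
preprocess -> annotate -> differential expression -> seed edits ->
novel prediction -> genomic clustering, with plain-file outputs and a
category summary.  Stage outputs are documented TSV/FASTA/GFF3 files
so each stage can also be run on its own.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional

import yaml

from . import annotate as ann_mod
from . import cluster as cluster_mod
from . import diffexp as de_mod
from . import novel as novel_mod
from . import seededit as se_mod
from .io import iter_reads, read_fasta, write_collapsed_fasta
from .novel import HairpinCandidate, HairpinThresholds
from .preprocess import length_distribution, merge_libraries, preprocess_reads
from .regions import GenomicLocus

log = logging.getLogger("mirpipe")


@dataclass
class RunConfig:
    """All inputs and thresholds of a pipeline run.

    Defaults are the pipeline's standard analysis settings: 18-30 nt
    tags, two mismatches with indels counted, -18 kcal/mol MFE cutoff,
    10 kb cluster gap.
    """

    lib1: str = ""
    lib2: str = ""
    mature: str = ""
    hairpin: str = ""
    genome: str = ""
    out: str = "mirpipe_run"
    adapter3: str = "TCGTATGCCGTCTTCTGCTTG"
    adapter5: Optional[str] = None
    other_ncrna: Optional[str] = None
    gff: Optional[str] = None
    min_len: int = 18
    max_len: int = 30
    max_mismatches: int = 2
    end_slack: int = 4
    max_mfe: float = -18.0
    min_duplex_pairs: int = 16
    max_bulge: int = 4
    max_hairpin_len: int = 200
    flank_up: int = 70
    flank_down: int = 20
    max_hits: int = 20
    min_novel_reads: int = 5  # read support required to fold a tag
    max_gap: int = 10_000
    alpha: float = 0.05
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def thresholds(self) -> HairpinThresholds:
        return HairpinThresholds(
            max_mfe=self.max_mfe,
            min_duplex_pairs=self.min_duplex_pairs,
            max_bulge=self.max_bulge,
            max_hairpin_len=self.max_hairpin_len,
        )


def mature_genomic_locus(cand: HairpinCandidate) -> GenomicLocus:
    """Genomic interval of a candidate's mature tag."""
    wl = cand.window_locus
    if wl is None:
        raise ValueError("candidate has no window locus")
    if wl.strand == "+":
        s = wl.start + cand.mature_start
    else:
        s = wl.end - cand.mature_end
    return GenomicLocus(wl.chrom, s, s + (cand.mature_end - cand.mature_start), wl.strand)


def dedupe_candidates(
    candidates: list[HairpinCandidate], merge_dist: int = 30
) -> list[HairpinCandidate]:
    """Collapse candidates whose mature loci overlap or lie within
    ``merge_dist`` nt — one reported hairpin per genomic locus, the
    lowest-MFE representative kept."""
    keyed = sorted(
        candidates, key=lambda c: (mature_genomic_locus(c).chrom, mature_genomic_locus(c).start)
    )
    out: list[HairpinCandidate] = []
    last: Optional[GenomicLocus] = None
    for cand in keyed:
        locus = mature_genomic_locus(cand)
        if last is not None and locus.chrom == last.chrom and locus.start - last.end < merge_dist:
            if cand.mfe < out[-1].mfe:
                out[-1] = cand
            last = GenomicLocus(last.chrom, last.start, max(last.end, locus.end), last.strand)
        else:
            out.append(cand)
            last = locus
    return out


def merge_precursor_loci(
    loci: list[GenomicLocus], merge_dist: int = 120
) -> list[GenomicLocus]:
    """Collapse loci within one precursor footprint (overlapping or
    within ``merge_dist`` nt, e.g. a mature and the miR* of the same
    hairpin) into one independent genomic locus."""
    merged: list[GenomicLocus] = []
    for locus in sorted(loci, key=lambda l: (l.chrom, l.start, l.end)):
        if (
            merged
            and locus.chrom == merged[-1].chrom
            and locus.start - merged[-1].end < merge_dist
        ):
            prev = merged[-1]
            merged[-1] = GenomicLocus(
                prev.chrom, prev.start, max(prev.end, locus.end), prev.strand,
                prev.name or locus.name,
            )
        else:
            merged.append(locus)
    return merged


def run_all(cfg: RunConfig) -> dict:
    """Execute every stage; returns the run summary (also written as
    ``summary.json`` in the output directory)."""
    logging.basicConfig(level=cfg.log_level)
    for name in ("lib1", "lib2", "mature", "genome"):
        path = getattr(cfg, name)
        if not path or not Path(path).exists():
            raise FileNotFoundError(f"required input {name!r} missing: {path!r}")
    for name in ("hairpin", "other_ncrna", "gff"):
        path = getattr(cfg, name)
        if path and not Path(path).exists():
            raise FileNotFoundError(f"input {name!r} does not exist: {path}")
    out = Path(cfg.out)
    out.mkdir(parents=True, exist_ok=True)
    log.info("run parameters: %s", asdict(cfg))

    # --- preprocess ----------------------------------------------------
    tags = {}
    summaries = {}
    for lib_no, path in ((1, cfg.lib1), (2, cfg.lib2)):
        t, summary, reasons = preprocess_reads(
            iter_reads(path), cfg.adapter3, cfg.adapter5,
            min_len=cfg.min_len, max_len=cfg.max_len,
        )
        tags[lib_no], summaries[lib_no] = t, summary
        log.info("lib%d: %d clean reads, %d unique tags, rejected %s",
                 lib_no, summary.total_clean_reads, summary.unique_tag_count, dict(reasons))
        ordered = sorted(t.items(), key=lambda kv: (-kv[1], kv[0]))
        write_collapsed_fasta(ordered, out / f"clean_lib{lib_no}.fa", prefix=f"l{lib_no}t")
        length_distribution(summary).to_csv(
            out / f"length_dist_lib{lib_no}.tsv", sep="\t", index=False
        )
    merged = merge_libraries(tags[1], tags[2])

    # --- annotate ------------------------------------------------------
    ref = ann_mod.MirnaReference.from_fasta(cfg.mature, cfg.hairpin or None)
    other = read_fasta(cfg.other_ncrna) if cfg.other_ncrna else None
    annots = ann_mod.annotate_tags(merged, ref, other, cfg.max_mismatches, cfg.end_slack)
    ann_mod.annotation_table(annots).to_csv(out / "annotation.tsv", sep="\t", index=False)

    # --- differential expression --------------------------------------
    counts: dict[str, tuple[int, int]] = {}
    for a in annots:
        if a.status in ("known_mature", "known_star"):
            x, y = counts.get(a.best_match, (0, 0))
            counts[a.best_match] = (x + a.tag.count_lib1, y + a.tag.count_lib2)
    n1 = max(summaries[1].total_clean_reads, 1)
    n2 = max(summaries[2].total_clean_reads, 1)
    expr = de_mod.build_table(counts, n1, n2)
    expr.to_csv(out / "diffexp.tsv", sep="\t", index=False)

    # --- seed edits ----------------------------------------------------
    # candidates: tags not explained exactly by a known mature
    seed_tags = [
        a.tag
        for a in annots
        if a.status == "unannotated"
        or (a.status.startswith("known") and (a.mismatches or 0) >= 1)
    ]
    events = se_mod.detect_seed_edits(seed_tags, ref, cfg.end_slack)
    spectrum = se_mod.substitution_spectrum(events)
    spectrum.to_csv(out / "seed_edit_spectrum.tsv", sep="\t", index=False)
    with open(out / "seed_edits.tsv", "w") as fh:
        fh.write("tag\tmature\tposition\tfrom\tto\tcount_lib1\tcount_lib2\n")
        for ev in events:
            fh.write(
                f"{ev.tag.sequence}\t{ev.mature}\t{ev.position}\t"
                f"{ev.substitution[0]}\t{ev.substitution[1]}\t"
                f"{ev.tag.count_lib1}\t{ev.tag.count_lib2}\n"
            )

    # --- novel prediction ----------------------------------------------
    genome = read_fasta(cfg.genome)
    unann = [a.tag for a in annots if a.status == "unannotated"]
    raw_candidates = novel_mod.predict_novel(
        unann, genome,
        thresholds=cfg.thresholds(),
        max_hits=cfg.max_hits, up=cfg.flank_up, down=cfg.flank_down,
        min_reads=cfg.min_novel_reads,
    )
    candidates = dedupe_candidates(raw_candidates)
    genes = novel_mod.load_gene_models(cfg.gff) if cfg.gff else []
    with open(out / "novel_candidates.tsv", "w") as fh:
        fh.write("chrom\tstart\tend\tstrand\tmfe\tarm\tcontext\tmature\tstructure\n")
        for cand in candidates:
            locus = mature_genomic_locus(cand)
            context = novel_mod.classify_context(locus, genes) if genes else ""
            fh.write(
                f"{locus.chrom}\t{locus.start}\t{locus.end}\t{locus.strand}\t"
                f"{cand.mfe}\t{cand.mature_arm}\t{context}\t"
                f"{cand.window[cand.mature_start:cand.mature_end]}\t{cand.structure}\n"
            )

    # --- genomic clustering --------------------------------------------
    loci: list[GenomicLocus] = []
    for name in sorted(counts):
        if name in ref.matures:
            for locus in novel_mod.map_to_genome(ref.matures[name], genome, cfg.max_hits):
                loci.append(GenomicLocus(locus.chrom, locus.start, locus.end, locus.strand, name))
    for i, cand in enumerate(candidates, 1):
        locus = mature_genomic_locus(cand)
        loci.append(GenomicLocus(locus.chrom, locus.start, locus.end, locus.strand, f"novel-{i}"))
    loci = merge_precursor_loci(loci)
    with open(out / "mirna_loci.tsv", "w") as fh:
        fh.write("chrom\tstart\tend\tstrand\tname\n")
        for l in loci:
            fh.write(f"{l.chrom}\t{l.start}\t{l.end}\t{l.strand}\t{l.name}\n")
    clusters, singletons = cluster_mod.cluster_loci(loci, cfg.max_gap)
    report, totals = cluster_mod.cluster_report(clusters, singletons)
    report.to_csv(out / "clusters.tsv", sep="\t", index=False)

    # --- summary --------------------------------------------------------
    status_tags: dict[str, int] = {}
    status_reads: dict[str, int] = {}
    for a in annots:
        status_tags[a.status] = status_tags.get(a.status, 0) + 1
        status_reads[a.status] = status_reads.get(a.status, 0) + a.tag.total
    summary = {
        "n1": n1,
        "n2": n2,
        "unique_tags": len(merged),
        "category_tags": status_tags,
        "category_reads": status_reads,
        "known_mirnas_detected": len(counts),
        "significant": int(((expr["sig"] != "") & ~expr["excluded"]).sum()),
        "novel_candidates": len(candidates),
        "seed_edit_events": len(events),
        "clusters": totals,
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    log.info("summary: %s", summary)
    return summary
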