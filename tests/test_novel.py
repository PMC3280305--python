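"""Genome mapping, window excision, folding, hairpin screening,
context classification."""

import pytest

from mirpipe.datasets import load_novel_precursors
from mirpipe.io import revcomp
from mirpipe.novel import (
    GeneModel,
    classify_context,
    evaluate_candidate,
    excise_window,
    fold_hairpin,
    map_to_genome,
    predict_novel,
    star_consistency,
)
from mirpipe.preprocess import CleanTag
from mirpipe.regions import GenomicLocus
from mirpipe.simulate import shuffle_genome


class TestMapToGenome:
    def test_planted_tag_found_once(self, sim):
        truth, _, _ = sim
        hp = next(h for h in truth.hairpins if h.strand == "+")
        loci = map_to_genome(hp.mature, truth.genome)
        expected = hp.mature_locus
        assert any(
            l.chrom == expected.chrom and l.start == expected.start and l.strand == "+"
            for l in loci
        )

    def test_absent_tag_empty(self, sim):
        truth, _, _ = sim
        assert map_to_genome("A" * 25, truth.genome) == []

    def test_minus_strand_hit(self, sim):
        truth, _, _ = sim
        hp = next(h for h in truth.hairpins if h.strand == "-")
        loci = map_to_genome(hp.mature, truth.genome)
        expected = hp.mature_locus
        hits = [l for l in loci if l.chrom == expected.chrom and l.start == expected.start]
        assert hits and hits[0].strand == "-"
        contig = truth.genome[expected.chrom]
        assert revcomp(contig[expected.start : expected.end]) == hp.mature

    def test_repeat_tags_discarded(self):
        genome = {"c": ("TTTT" + "ACGTACGTACGTACGTACGTAA") * 30}
        assert map_to_genome("ACGTACGTACGTACGTACGTAA", genome, max_hits=20) == []


class TestExciseWindow:
    def test_plus_strand_arithmetic(self):
        genome = {"c": "A" * 5000}
        locus = GenomicLocus("c", 1000, 1022, "+")
        w5, w3 = excise_window(locus, genome, up=70, down=20)
        assert (w5.locus.start, w5.locus.end) == (930, 1042)
        assert (w3.locus.start, w3.locus.end) == (980, 1092)
        assert w5.sequence[w5.tag_start : w5.tag_end] == genome["c"][1000:1022]

    def test_contig_edge_truncation_flagged(self):
        genome = {"c": "A" * 500}
        locus = GenomicLocus("c", 10, 32, "+")
        w5, _ = excise_window(locus, genome)
        assert w5.truncated and w5.locus.start == 0

    def test_minus_strand_window_contains_tag(self, sim):
        truth, _, _ = sim
        hp = next(h for h in truth.hairpins if h.strand == "-")
        locus = hp.mature_locus
        for win in excise_window(locus, truth.genome):
            assert win.sequence[win.tag_start : win.tag_end] == hp.mature

    def test_one_window_contains_planted_precursor(self, sim):
        truth, _, _ = sim
        for hp in truth.hairpins[:4]:
            wins = excise_window(hp.mature_locus, truth.genome)
            assert any(hp.precursor in w.sequence for w in wins)


class TestFoldHairpin:
    def test_homopolymer_is_unstructured(self):
        structure, mfe = fold_hairpin("A" * 60)
        assert structure == "." * 60
        assert mfe == 0.0

    def test_strong_inverted_repeat_is_stabilising(self):
        stem = "GCATCGGACTGCATGCAGTC"
        hairpin = stem + "TTTCGA" + revcomp(stem)
        _, mfe = fold_hairpin(hairpin)
        assert mfe < -10

    def test_non_nucleotide_rejected(self):
        with pytest.raises(ValueError):
            fold_hairpin("ACGT" * 10 + "X" + "ACGT" * 5)

    def test_short_window_rejected(self):
        with pytest.raises(ValueError):
            fold_hairpin("ACGT" * 5)

    def test_published_precursor_mfe_within_ten_percent(self):
        row = load_novel_precursors().iloc[0]
        _, mfe = fold_hairpin(row.precursor)
        assert mfe == pytest.approx(row.reported_mfe, rel=0.10)


class TestEvaluateCandidate:
    def test_planted_hairpin_passes(self, sim):
        truth, _, _ = sim
        for hp in truth.hairpins[:6]:
            wins = excise_window(hp.mature_locus, truth.genome)
            results = [
                evaluate_candidate(w.sequence, w.tag_start, w.tag_end) for w in wins
            ]
            assert any(r.passed for r in results), hp.name
            best = next(r for r in results if r.passed)
            assert best.mature_arm == hp.arm

    def test_mature_spanning_loop_fails(self, sim):
        truth, _, _ = sim
        hp = next(h for h in truth.hairpins if h.arm == "5p" and h.strand == "+")
        # center the "mature" on the terminal loop
        contig = truth.genome[hp.chrom]
        mid = (hp.precursor_start + hp.precursor_end) // 2
        locus = GenomicLocus(hp.chrom, mid - 11, mid + 11, "+")
        wins = excise_window(locus, truth.genome)
        for w in wins:
            cand = evaluate_candidate(w.sequence, w.tag_start, w.tag_end)
            assert not cand.passed
            assert "loop_overlap" in cand.reasons or "insufficient_pairing" in cand.reasons

    def test_weak_mfe_fails_with_reason(self, sim):
        truth, _, _ = sim
        hp = truth.hairpins[0]
        w = next(
            w for w in excise_window(hp.mature_locus, truth.genome)
            if hp.precursor in w.sequence
        )
        structure, _ = fold_hairpin(w.sequence)
        cand = evaluate_candidate(
            w.sequence, w.tag_start, w.tag_end, structure=structure, mfe=-10.0
        )
        assert not cand.passed and cand.reasons == ["mfe_above_threshold"]

    def test_published_precursors_pass_screening(self):
        for row in load_novel_precursors().itertuples():
            s = row.precursor.find(row.mature)
            cand = evaluate_candidate(row.precursor, s, s + len(row.mature))
            assert cand.passed, (row.name, cand.reasons)

    def test_strand_symmetry(self, sim):
        """Reverse-complementing the genome and flipping strands yields
        identical candidates."""
        truth, _, _ = sim
        flipped = {c: revcomp(s) for c, s in truth.genome.items()}
        for hp in truth.hairpins[:4]:
            tag = CleanTag(hp.mature, 10, 0)
            direct = predict_novel([tag], truth.genome)
            mirrored = predict_novel([tag], flipped)
            assert len(direct) == len(mirrored)
            assert sorted(c.mfe for c in direct) == pytest.approx(
                sorted(c.mfe for c in mirrored)
            )


class TestStarConsistency:
    def test_generator_star_supported(self, sim):
        truth, _, _ = sim
        found = 0
        for hp in truth.hairpins:
            wins = excise_window(hp.mature_locus, truth.genome)
            cands = [evaluate_candidate(w.sequence, w.tag_start, w.tag_end) for w in wins]
            passing = [c for c in cands if c.passed]
            if not passing:
                continue
            if star_consistency(passing[0], [CleanTag(hp.star, 1, 0)]):
                found += 1
        assert found >= 8  # 2-nt overhang geometry recovered (of 10)

    def test_without_star_reads_still_pass(self, sim):
        truth, _, _ = sim
        hp = truth.hairpins[0]
        w = next(
            w for w in excise_window(hp.mature_locus, truth.genome)
            if hp.precursor in w.sequence
        )
        cand = evaluate_candidate(w.sequence, w.tag_start, w.tag_end)
        assert cand.passed
        assert star_consistency(cand, []) is False

    def test_shifted_star_exceeds_slack(self, sim):
        truth, _, _ = sim
        hp = truth.hairpins[0]
        w = next(
            w for w in excise_window(hp.mature_locus, truth.genome)
            if hp.precursor in w.sequence
        )
        cand = evaluate_candidate(w.sequence, w.tag_start, w.tag_end)
        pos = cand.window.find(cand.star_seq)
        shifted = cand.window[pos + 5 : pos + 5 + len(cand.star_seq)]
        assert star_consistency(cand, [CleanTag(shifted, 1, 0)]) is False


class TestSensitivityAndSpecificity:
    def test_planted_hairpins_recovered(self, sim):
        """>= 90% of planted hairpins pass screening from their mature
        tag alone."""
        truth, lib1, lib2 = sim
        tags = [
            CleanTag(h.mature, lib1.mirna_counts[h.name], lib2.mirna_counts[h.name])
            for h in truth.hairpins
        ]
        supported = [t for t in tags if t.total >= 5]
        cands = predict_novel(supported, truth.genome, min_reads=5)
        recovered = set()
        for c in cands:
            wl = c.window_locus
            for h in truth.hairpins:
                if wl.chrom == h.chrom and wl.start < h.precursor_end and h.precursor_start < wl.end:
                    recovered.add(h.name)
        assert len(recovered) >= 0.9 * len(supported)

    def test_shuffled_genome_negative_control(self, sim):
        truth, _, _ = sim
        shuffled = shuffle_genome(truth.genome, seed=1)
        tags = [CleanTag(h.mature, 10, 10) for h in truth.hairpins]
        assert predict_novel(tags, shuffled) == []


class TestClassifyContext:
    @pytest.fixture
    def genes(self):
        return [
            GeneModel(
                "g1", "chr1", 1000, 9000,
                exons=[(1000, 2000), (4000, 5000), (8000, 9000)],
            ),
            GeneModel("g2", "chr1", 8500, 12000, exons=[(8500, 9500), (11000, 12000)]),
        ]

    def test_intergenic(self, genes):
        assert classify_context(GenomicLocus("chr1", 20000, 20022, "+"), genes) == "intergenic"
        assert classify_context(GenomicLocus("chr2", 1500, 1522, "+"), genes) == "intergenic"

    def test_exon(self, genes):
        assert classify_context(GenomicLocus("chr1", 1100, 1122, "+"), genes) == "exon"

    def test_intron(self, genes):
        assert classify_context(GenomicLocus("chr1", 2500, 2522, "+"), genes) == "intron"

    def test_exon_intron_straddle_one_gene(self, genes):
        assert (
            classify_context(GenomicLocus("chr1", 1990, 2012, "+"), genes)
            == "intron_and_exon_one_gene"
        )

    def test_two_gene_overlap(self, genes):
        assert (
            classify_context(GenomicLocus("chr1", 8600, 8622, "+"), genes)
            == "intron_and_exon_two_genes"
        )

    def test_malformed_gene_rejected(self):
        with pytest.raises(ValueError):
            GeneModel("bad", "chr1", 100, 50)
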