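"""Known-miRNA matching, arm assignment, isomiR profiling."""

import numpy as np
import pytest

from mirpipe.annotate import (
    MirnaReference,
    annotate_other,
    annotate_tags,
    assign_arm,
    match_known,
    profile_isomirs,
)
from mirpipe.preprocess import CleanTag

from .conftest import brute_force_match


class TestMatchKnown:
    def test_exact_match(self, toy_ref):
        ann = match_known(toy_ref.matures["toy-miR-a"], toy_ref)
        assert ann.status == "known_mature"
        assert ann.best_match == "toy-miR-a"
        assert ann.mismatches == 0
        assert ann.end_offsets == (0, 0)

    def test_three_substitutions_unannotated(self, toy_ref):
        seq = list(toy_ref.matures["toy-miR-a"])
        for i in (3, 9, 15):
            seq[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[seq[i]]
        ann = match_known("".join(seq), toy_ref)
        assert ann.status == "unannotated"

    def test_gap_counts_as_mismatch(self, toy_ref):
        """A 1-nt internal deletion plus two substitutions totals three
        mismatches and disqualifies the tag."""
        seq = list(toy_ref.matures["toy-miR-a"])
        del seq[10]
        for i in (3, 15):
            seq[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[seq[i]]
        ann = match_known("".join(seq), toy_ref)
        assert ann.status == "unannotated"

    def test_single_deletion_within_budget(self, toy_ref):
        seq = list(toy_ref.matures["toy-miR-a"])
        del seq[10]
        ann = match_known("".join(seq), toy_ref)
        assert ann.status == "known_mature"
        assert ann.mismatches == 1

    def test_isomir_end_offsets_not_counted_as_mismatches(self, toy_ref):
        hp = toy_ref.hairpins["toy-mir-a"]
        _, s, e = toy_ref.mature_to_hairpin["toy-miR-a"]
        variant = hp[s : e + 2]  # 3' +2 templated extension
        ann = match_known(variant, toy_ref)
        assert ann.status == "known_mature"
        assert ann.mismatches == 0
        assert ann.end_offsets == (0, 2)

    def test_agrees_with_bruteforce_enumeration(self, sim_ref):
        """Banded/gated search equals exhaustive full-DP enumeration on
        random tags derived from the reference by mutation."""
        rng = np.random.default_rng(17)
        bases = "ACGT"
        matures = list(sim_ref.matures.values())
        tags = []
        for _ in range(120):
            m = matures[rng.integers(len(matures))]
            seq = list(m)
            for _ in range(rng.integers(0, 4)):  # 0-3 substitutions
                i = int(rng.integers(len(seq)))
                seq[i] = bases[rng.integers(4)]
            if rng.random() < 0.3:  # occasional indel
                i = int(rng.integers(len(seq)))
                if rng.random() < 0.5 and len(seq) > 18:
                    del seq[i]
                else:
                    seq.insert(i, bases[rng.integers(4)])
            tags.append("".join(seq))
        tags += ["".join(bases[b] for b in rng.integers(0, 4, 22)) for _ in range(20)]

        for tag in tags:
            mine = match_known(tag, sim_ref)
            oracle = brute_force_match(tag, sim_ref)
            if oracle is None:
                assert mine.status == "unannotated", tag
            else:
                d, name, o5, o3 = oracle
                assert mine.best_match == name, tag
                assert mine.mismatches == d, tag


class TestAssignArm:
    def test_first_half_is_5p(self):
        hp = "A" * 90
        ref = MirnaReference(
            {"m": hp[10:31]}, {"h": hp}, {"m": ("h", 10, 31)}
        )
        assert assign_arm("m", ref) == "5p"

    def test_second_half_is_3p(self):
        hp = "A" * 90
        ref = MirnaReference({"m": hp[55:76]}, {"h": hp}, {"m": ("h", 55, 76)})
        assert assign_arm("m", ref) == "3p"

    def test_generator_arm_recovered(self, sim, sim_ref):
        truth, _, _ = sim
        by_name = {h.name: h for h in truth.hairpins}
        for name in sim_ref.matures:
            assert assign_arm(name, sim_ref) == by_name[name].arm

    def test_missing_hairpin_raises(self):
        ref = MirnaReference({"m": "ACGTACGTACGTACGTACGTAC"})
        with pytest.raises(ValueError):
            assign_arm("m", ref)


class TestProfileIsomirs:
    def _ann(self, ref, seq, n):
        return match_known(CleanTag(seq, n, 0), ref)

    def test_three_prime_dominant(self, toy_ref):
        hp = toy_ref.hairpins["toy-mir-a"]
        _, s, e = toy_ref.mature_to_hairpin["toy-miR-a"]
        anns = [
            self._ann(toy_ref, hp[s:e], 10),
            self._ann(toy_ref, hp[s : e + 1], 5),
            self._ann(toy_ref, hp[s : e - 1], 2),
        ]
        table, dominant = profile_isomirs(anns)
        assert dominant is True
        assert table.iloc[0].to_dict() == {"o5": 0, "o3": 0, "n_tags": 1, "n_reads": 10}

    def test_single_canonical_tag(self, toy_ref):
        anns = [self._ann(toy_ref, toy_ref.matures["toy-miR-a"], 4)]
        table, dominant = profile_isomirs(anns)
        assert len(table) == 1
        assert (table.o5[0], table.o3[0]) == (0, 0)
        assert dominant is False

    def test_simulated_offsets_recovered(self, sim, sim_ref):
        """The recovered end-offset histogram tracks the generator's
        isomiR profile within sampling error."""
        truth, lib1, lib2 = sim
        name = max(
            (h.name for h in truth.hairpins if h.known),
            key=lambda n: lib1.mirna_counts[n],
        )
        hp = next(h for h in truth.hairpins if h.name == name)
        counts: dict[tuple[int, int], int] = {}
        for lib in (lib1, lib2):
            for (src, kind, detail), c in lib.class_counts.items():
                if src == name and kind == "isomir":
                    counts[detail] = counts.get(detail, 0) + c
        anns = []
        for (o5, o3), c in counts.items():
            pad = hp.context_pad
            seq = hp.context[pad + o5 : pad + len(hp.mature) + o3]
            anns.append(match_known(CleanTag(seq, c, 0), sim_ref))
        table, dominant = profile_isomirs(anns)
        assert dominant is True
        got = {(r.o5, r.o3): r.n_reads for r in table.itertuples()}
        total = sum(got.values())
        for (o5, o3), c in counts.items():
            assert got.get((o5, o3), 0) == c
        p = truth.isomir_o5[0] * truth.isomir_o3[0]
        canonical = got.get((0, 0), 0)
        assert abs(canonical / total - p) < 3 * np.sqrt(p * (1 - p) / total)


class TestPrecedence:
    def test_mirna_beats_other_ncrna(self, toy_ref):
        seq = toy_ref.matures["toy-miR-a"]
        other = {"rRNA-frag": "GGG" + seq + "CCC"}
        anns = annotate_tags([CleanTag(seq, 1, 0)], toy_ref, other)
        assert anns[0].status == "known_mature"

    def test_other_ncrna_when_not_mirna(self, toy_ref):
        seq = "GTCCTTAGCGTAGCGGTAACGT"
        other = {"rRNA-frag": "AAA" + seq + "TTT"}
        anns = annotate_tags([CleanTag(seq, 1, 0)], toy_ref, other)
        assert anns[0].status == "other_ncRNA"

    def test_statuses_partition_tags(self, sim, sim_ref):
        truth, lib1, lib2 = sim
        from mirpipe.preprocess import CleanTag as CT

        seqs = {}
        for lib_no, lib in ((0, lib1), (1, lib2)):
            for _, seq in lib.reads[:500]:
                insert = seq[: seq.find(truth.adapter3[:8])]
                if 18 <= len(insert) <= 30:
                    counts = seqs.setdefault(insert, [0, 0])
                    counts[lib_no] += 1
        tags = [CT(s, a, b) for s, (a, b) in seqs.items()]
        anns = annotate_tags(tags, sim_ref)
        assert len(anns) == len(tags)
        assert all(
            a.status in {"known_mature", "known_star", "other_ncRNA", "unannotated"}
            for a in anns
        )


def test_annotate_other_substring_rule():
    assert annotate_other("ACGTACGT" * 3, {"x": "TT" + "ACGTACGT" * 3 + "GG"})
    assert not annotate_other("ACGTACGT" * 3, {"x": "TTTTGGGGCCCC"})
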