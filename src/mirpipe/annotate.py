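"""Known-miRNA annotation of clean tags.

Tags are compared against a reference of mature miRNAs (miRBase-style
mature + hairpin FASTA pair) with a banded edit distance: at most two
mismatches, where indels count as mismatches.  IsomiR end variation is
handled separately from mismatches — a tag may start or end up to
``end_slack`` nucleotides away from the canonical mature ends (template
bases for extensions are taken from the hairpin), and those offsets are
recorded, not penalised.

Category precedence when a tag hits several databases:
known miRNA > other ncRNA > unannotated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import edlib
import pandas as pd

from .io import read_fasta
from .preprocess import CleanTag

MAX_MISMATCHES = 2
END_SLACK = 4


@dataclass
class MirnaReference:
    """Mature and hairpin sequences with mature-in-hairpin placements
    (0-based half-open coordinates)."""

    matures: dict[str, str]
    hairpins: dict[str, str] = field(default_factory=dict)
    mature_to_hairpin: dict[str, tuple[str, int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, (hp, s, e) in self.mature_to_hairpin.items():
            if self.hairpins[hp][s:e] != self.matures[name]:
                raise ValueError(f"{name}: recorded placement does not match hairpin {hp}")

    @classmethod
    def from_fasta(cls, mature_path, hairpin_path=None) -> "MirnaReference":
        """Load reference FASTAs; U is normalized to T.  Matures are
        placed in the hairpin sharing their name (case-insensitive,
        ignoring a trailing ``*``/arm suffix) by exact substring search.
        """
        matures = read_fasta(mature_path)
        hairpins = read_fasta(hairpin_path) if hairpin_path else {}
        placement: dict[str, tuple[str, int, int]] = {}
        by_key = { _name_key(n): n for n in hairpins }
        for name, seq in matures.items():
            hp_name = by_key.get(_name_key(name))
            if hp_name is None:
                continue
            pos = hairpins[hp_name].find(seq)
            if pos >= 0:
                placement[name] = (hp_name, pos, pos + len(seq))
        return cls(matures, hairpins, placement)


def _name_key(name: str) -> str:
    key = name.lower().rstrip("*")
    for suffix in ("-5p", "-3p"):
        if key.endswith(suffix):
            key = key[: -len(suffix)]
    return key


@dataclass
class TagAnnotation:
    """Annotation outcome for one clean tag."""

    tag: CleanTag
    status: str  # known_mature | known_star | other_ncRNA | unannotated
    best_match: Optional[str] = None
    mismatches: Optional[int] = None
    arm: Optional[str] = None
    end_offsets: Optional[tuple[int, int]] = None  # (5' offset, 3' offset)


def _segments(
    mature: str,
    placement: Optional[tuple[str, int, int]],
    hairpins: Mapping[str, str],
    end_slack: int,
) -> Iterable[tuple[int, int, str]]:
    """Yield (o5, o3, segment) reference variants of a mature.

    With a hairpin placement, extensions beyond the mature take the
    hairpin's template bases; without one, only trimmed variants
    (o5 >= 0, o3 <= 0) exist.
    """
    if placement is not None:
        hp_name, s, e = placement
        hp = hairpins[hp_name]
        for o5 in range(-end_slack, end_slack + 1):
            a = s + o5
            if a < 0:
                continue
            for o3 in range(-end_slack, end_slack + 1):
                b = e + o3
                if b > len(hp) or b - a < 10:
                    continue
                yield o5, o3, hp[a:b]
    else:
        for o5 in range(0, end_slack + 1):
            for o3 in range(-end_slack, 1):
                b = len(mature) + o3
                if b - o5 < 10:
                    continue
                yield o5, o3, mature[o5:b]


def _edit_distance(a: str, b: str, k: int) -> int:
    """Levenshtein distance, or -1 when it exceeds k."""
    if abs(len(a) - len(b)) > k:
        return -1
    return edlib.align(a, b, mode="NW", task="distance", k=k)["editDistance"]


def match_known(
    tag: CleanTag | str,
    ref: MirnaReference,
    max_mm: int = MAX_MISMATCHES,
    end_slack: int = END_SLACK,
) -> TagAnnotation:
    """Best mature match for a tag under the two-mismatch rule.

    The winning mature minimises the edit distance (substitutions and
    indels each cost 1, capped at ``max_mm``); end offsets within
    ``end_slack`` are free.  Ties break by fewer mismatches, then
    smaller |5' offset|, then mature name.  No qualifying mature
    leaves the tag unannotated.
    """
    if not ref.matures:
        raise ValueError("empty miRNA reference")
    if isinstance(tag, str):
        tag = CleanTag(tag)
    seq = tag.sequence

    best: Optional[tuple[int, int, str, int, int]] = None  # (mm, |o5|, name, o5, o3)
    for name in sorted(ref.matures):
        mature = ref.matures[name]
        placement = ref.mature_to_hairpin.get(name)
        if placement is not None:
            # cheap gate: the infix distance against the whole hairpin
            # lower-bounds the distance against any of its segments
            hp = ref.hairpins[placement[0]]
            if edlib.align(seq, hp, mode="HW", task="distance", k=max_mm)["editDistance"] < 0:
                continue
        for o5, o3, segment in _segments(mature, placement, ref.hairpins, end_slack):
            d = _edit_distance(seq, segment, max_mm)
            if d < 0:
                continue
            key = (d, abs(o5), name, o5, o3)
            if best is None or key[:3] < best[:3]:
                best = key
                if d == 0 and o5 == 0:
                    break

    if best is None:
        return TagAnnotation(tag, "unannotated")
    mm, _, name, o5, o3 = best
    status = "known_star" if "*" in name else "known_mature"
    arm = None
    if name in ref.mature_to_hairpin:
        arm = assign_arm(name, ref)
    return TagAnnotation(tag, status, name, mm, arm, (o5, o3))


def assign_arm(mature_name: str, ref: MirnaReference) -> str:
    """5p when the mature's midpoint lies in the first half of its
    hairpin, 3p otherwise; a mature centred exactly on the hairpin
    midpoint is classified by its start position."""
    placement = ref.mature_to_hairpin.get(mature_name)
    if placement is None:
        raise ValueError(f"{mature_name}: no hairpin placement")
    hp_name, s, e = placement
    half = len(ref.hairpins[hp_name]) / 2
    mid = (s + e) / 2
    if mid == half:
        return "5p" if s < half else "3p"
    return "5p" if mid < half else "3p"


def profile_isomirs(
    annotations: Sequence[TagAnnotation],
) -> tuple[pd.DataFrame, bool]:
    """End-variant table for tags annotated to one mature.

    Returns (table, 3p_dominant): rows (o5, o3, n_tags, n_reads)
    sorted by read count descending; the flag is True when reads with
    only a 3' offset outnumber reads with only a 5' offset.
    """
    matches = {a.best_match for a in annotations}
    if len(matches) > 1:
        raise ValueError(f"tags annotated to several matures: {sorted(matches)}")
    counts: dict[tuple[int, int], list[int]] = {}
    for a in annotations:
        if a.end_offsets is None:
            continue
        slot = counts.setdefault(a.end_offsets, [0, 0])
        slot[0] += 1
        slot[1] += a.tag.total
    rows = [
        {"o5": k[0], "o3": k[1], "n_tags": v[0], "n_reads": v[1]}
        for k, v in counts.items()
    ]
    df = pd.DataFrame(rows, columns=["o5", "o3", "n_tags", "n_reads"])
    df = df.sort_values(["n_reads", "o5", "o3"], ascending=[False, True, True]).reset_index(drop=True)
    three_only = df[(df.o5 == 0) & (df.o3 != 0)]["n_reads"].sum()
    five_only = df[(df.o5 != 0) & (df.o3 == 0)]["n_reads"].sum()
    return df, bool(three_only > five_only)


def annotate_other(tag: CleanTag | str, other_ncrna: Mapping[str, str]) -> bool:
    """True iff the tag is an exact substring of any supplied non-miRNA
    ncRNA sequence (rRNA/tRNA/snoRNA fragments etc.)."""
    seq = tag.sequence if isinstance(tag, CleanTag) else tag
    return any(seq in ref_seq for ref_seq in other_ncrna.values())


def annotate_tags(
    tags: Sequence[CleanTag],
    ref: MirnaReference,
    other_ncrna: Mapping[str, str] | None = None,
    max_mm: int = MAX_MISMATCHES,
    end_slack: int = END_SLACK,
) -> list[TagAnnotation]:
    """Annotate every tag with category precedence
    known miRNA > other ncRNA > unannotated."""
    out = []
    for tag in tags:
        ann = match_known(tag, ref, max_mm, end_slack)
        if ann.status == "unannotated" and other_ncrna and annotate_other(tag, other_ncrna):
            ann = TagAnnotation(tag, "other_ncRNA")
        out.append(ann)
    return out


def annotation_table(annotations: Sequence[TagAnnotation]) -> pd.DataFrame:
    rows = [
        {
            "tag": a.tag.sequence,
            "status": a.status,
            "best_match": a.best_match or "",
            "mismatches": a.mismatches if a.mismatches is not None else "",
            "arm": a.arm or "",
            "o5": a.end_offsets[0] if a.end_offsets else "",
            "o3": a.end_offsets[1] if a.end_offsets else "",
            "count_lib1": a.tag.count_lib1,
            "count_lib2": a.tag.count_lib2,
        }
        for a in annotations
    ]
    return pd.DataFrame(
        rows,
        columns=["tag", "status", "best_match", "mismatches", "arm", "o5", "o3",
                 "count_lib1", "count_lib2"],
    )
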