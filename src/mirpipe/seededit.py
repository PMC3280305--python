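"""Seed-edit detection.

The seed region — positions 2-8 of a mature miRNA, 1-based from the 5'
end — dominates target recognition, so a single nucleotide substitution
there (candidate RNA editing) redirects the miRNA.  A tag is called a
seed-edit candidate when it aligns end-anchored to a mature (the same
end-slack rule as known-miRNA matching, no indels) with exactly one
substitution overall, located in the seed.  Single substitutions
outside the seed are reported separately as non-seed variants.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Optional, Sequence

import pandas as pd

from .annotate import END_SLACK, MirnaReference, _segments
from .preprocess import CleanTag

SEED_START = 2  # 1-based, inclusive
SEED_END = 8

BASES = "ACGT"
#: all 12 ordered substitution types
SUBSTITUTION_TYPES = [(a, b) for a, b in product(BASES, BASES) if a != b]


@dataclass
class SeedEditEvent:
    """One tag explained by a single substitution in a mature's seed."""

    tag: CleanTag
    mature: str
    position: int  # 1-based along the mature, in [2, 8]
    substitution: tuple[str, str]  # (reference base, observed base)
    end_offsets: tuple[int, int] = (0, 0)
    in_seed: bool = True


def _single_sub_match(
    tag_seq: str, mature: str, placement, hairpins, end_slack: int
) -> Optional[tuple[int, int, int]]:
    """Best end-anchored single-substitution alignment of tag vs mature.

    Returns (mature_position_0based, o5, o3) of the lone mismatch, or
    None.  Only same-length (indel-free) alignments qualify; the
    mismatch must fall inside the canonical mature span.
    """
    best: Optional[tuple[int, int, int, int]] = None  # (|o5|, o5, o3, pos)
    for o5, o3, segment in _segments(mature, placement, hairpins, end_slack):
        if len(segment) != len(tag_seq):
            continue
        mism = [i for i, (a, b) in enumerate(zip(tag_seq, segment)) if a != b]
        if len(mism) != 1:
            continue
        pos = mism[0] + o5  # 0-based position on the mature
        if not (0 <= pos < len(mature)):
            continue
        key = (abs(o5), o5, o3, pos)
        if best is None or key < best:
            best = key
    if best is None:
        return None
    _, o5, o3, pos = best
    return pos, o5, o3


def detect_seed_edits(
    tags: Sequence[CleanTag],
    ref: MirnaReference,
    end_slack: int = END_SLACK,
    *,
    include_non_seed: bool = False,
) -> list[SeedEditEvent]:
    """Scan tags for single-substitution variants of known matures.

    Each tag reports at most one event, against the mature with the
    best alignment (tie-break: smaller |5' offset|, then mature name).
    Events whose substitution lies at mature positions 2-8 are seed
    edits; others are returned only when ``include_non_seed`` is set,
    flagged ``in_seed=False``.
    """
    events: list[SeedEditEvent] = []
    for tag in tags:
        hit: Optional[tuple[tuple, SeedEditEvent]] = None
        for name in sorted(ref.matures):
            mature = ref.matures[name]
            placement = ref.mature_to_hairpin.get(name)
            found = _single_sub_match(tag.sequence, mature, placement, ref.hairpins, end_slack)
            if found is None:
                continue
            pos, o5, o3 = found
            ref_base = mature[pos]
            obs_base = tag.sequence[pos - o5]
            event = SeedEditEvent(
                tag=tag,
                mature=name,
                position=pos + 1,
                substitution=(ref_base, obs_base),
                end_offsets=(o5, o3),
                in_seed=SEED_START <= pos + 1 <= SEED_END,
            )
            key = (abs(o5), name)
            if hit is None or key < hit[0]:
                hit = (key, event)
        if hit is None:
            continue
        event = hit[1]
        if event.in_seed or include_non_seed:
            events.append(event)
    return events


def substitution_spectrum(events: Sequence[SeedEditEvent]) -> pd.DataFrame:
    """Substitution-type table over seed-edit events.

    All 12 ordered types are present (zero-filled), sorted by read
    count descending; totals conserve the events' read counts.
    """
    table = {t: [0, 0] for t in SUBSTITUTION_TYPES}
    for ev in events:
        if not ev.in_seed:
            continue
        slot = table[ev.substitution]
        slot[0] += 1
        slot[1] += ev.tag.total
    rows = [
        {"substitution": f"{a}->{b}", "n_events": v[0], "n_reads": v[1]}
        for (a, b), v in table.items()
    ]
    df = pd.DataFrame(rows)
    return df.sort_values(
        ["n_reads", "n_events", "substitution"], ascending=[False, False, True]
    ).reset_index(drop=True)
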