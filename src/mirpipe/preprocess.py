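"""Raw-read preprocessing: adapter trimming, quality/length filtering,
count collapsing.

Small-RNA inserts (18-30 nt) are sequenced into longer reads that run
through the ligated 3' adapter, so the insert is recovered as everything
upstream of the best 3'-adapter match.  Reads still carrying the 5'
adapter at their start are adapter-dimer artefacts and are rejected.
Surviving inserts are filtered (no N, 18-30 nt, mean quality >= Q20 when
qualities exist) and collapsed to unique tags with per-library counts.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

MIN_TAG_LEN = 18
MAX_TAG_LEN = 30


@dataclass
class RawRead:
    """One sequencer read: id, sequence over {A,C,G,T,N}, optional
    per-base Phred scores (same length as the sequence)."""

    identifier: str
    sequence: str
    quality: Optional[list[int]] = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.identifier}: empty sequence")
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValueError(f"{self.identifier}: quality/sequence length mismatch")


@dataclass(frozen=True)
class CleanTag:
    """A unique collapsed clean-tag sequence with per-library counts."""

    sequence: str
    count_lib1: int = 0
    count_lib2: int = 0

    @property
    def total(self) -> int:
        return self.count_lib1 + self.count_lib2


@dataclass
class LibrarySummary:
    """Per-library totals: the clean-read total is the N of the
    count-based differential test."""

    total_clean_reads: int
    unique_tag_count: int
    length_histogram: dict[int, int] = field(default_factory=dict)


@dataclass
class TrimResult:
    insert: Optional[str]
    reason: Optional[str] = None  # set iff insert is None

    @property
    def ok(self) -> bool:
        return self.insert is not None


def _mismatches(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def trim_adapter(
    read: RawRead,
    adapter3: str,
    adapter5: str | None = None,
    *,
    seed_len: int = 8,
    max_mismatch: int = 1,
    min_overlap: int = 5,
) -> TrimResult:
    """Return the insert upstream of the leftmost 3'-adapter match.

    The first ``seed_len`` bases of the 3' adapter are scanned along
    the read: a first pass takes the leftmost exact hit (partial
    adapters hanging off the read end count down to ``min_overlap``
    bases); only if none exists does a second pass accept a full-length
    seed with up to ``max_mismatch`` mismatches.  Exact-first keeps
    chance in-insert near-matches from truncating real inserts.
    Rejection reasons: ``empty_read``, ``adapter5_contamination``
    (read begins with the 5' adapter's 3' end), ``no_adapter``,
    ``empty_insert``.
    """
    if not adapter3:
        raise ValueError("adapter3 must be non-empty")
    seq = read.sequence
    if not seq:
        return TrimResult(None, "empty_read")

    if adapter5:
        # adapter-dimer check: does the read start with a long (>= 10 nt)
        # suffix of the 5' adapter?  Short overlaps are left alone —
        # they collide with real inserts by chance far too often.
        min_dimer_overlap = max(10, min_overlap)
        for olen in range(min(len(adapter5), len(seq)), min_dimer_overlap - 1, -1):
            if _mismatches(adapter5[-olen:], seq[:olen]) <= max_mismatch:
                return TrimResult(None, "adapter5_contamination")

    seed = adapter3[: min(seed_len, len(adapter3))]
    hit = -1
    for pos in range(0, len(seq) - min_overlap + 1):
        piece = seq[pos : pos + len(seed)]
        if seed.startswith(piece):
            hit = pos
            break
    if hit < 0 and max_mismatch > 0:
        for pos in range(0, len(seq) - len(seed) + 1):
            if _mismatches(seed, seq[pos : pos + len(seed)]) <= max_mismatch:
                hit = pos
                break
    if hit < 0:
        return TrimResult(None, "no_adapter")
    if hit == 0:
        return TrimResult(None, "empty_insert")
    return TrimResult(seq[:hit])


def mean_quality_ok(quality: list[int] | None, start: int, end: int, min_q: float = 20.0) -> bool:
    """Mean Phred quality of the insert region; True when no qualities
    are present (FASTA input)."""
    if quality is None:
        return True
    span = quality[start:end]
    if not span:
        return True
    return sum(span) / len(span) >= min_q


def filter_and_collapse(
    sequences: Iterable[tuple[str, int]],
    min_len: int = MIN_TAG_LEN,
    max_len: int = MAX_TAG_LEN,
) -> tuple[dict[str, int], LibrarySummary]:
    """Drop sequences with N or outside [min_len, max_len]; collapse
    identical sequences summing their counts.

    ``sequences`` yields (sequence, count) pairs so that already
    collapsed input is re-collapsed losslessly.  Returns the unique tag
    -> count map and a :class:`LibrarySummary` whose totals cover the
    retained reads only.
    """
    tags: Counter[str] = Counter()
    hist: Counter[int] = Counter()
    total = 0
    for seq, count in sequences:
        if count < 0:
            raise ValueError("negative read count")
        n = len(seq)
        if n < min_len or n > max_len or "N" in seq:
            continue
        tags[seq] += count
        hist[n] += count
        total += count
    summary = LibrarySummary(
        total_clean_reads=total,
        unique_tag_count=len(tags),
        length_histogram=dict(sorted(hist.items())),
    )
    return dict(tags), summary


def length_distribution(summary: LibrarySummary) -> pd.DataFrame:
    """Table of (length, count, fraction); fractions sum to 1."""
    if summary.total_clean_reads <= 0:
        raise ValueError("empty library: no clean reads")
    rows = [
        (length, count, count / summary.total_clean_reads)
        for length, count in sorted(summary.length_histogram.items())
    ]
    return pd.DataFrame(rows, columns=["length", "count", "fraction"])


def preprocess_reads(
    reads: Iterable[RawRead | tuple[str, str, list[int] | None, int]],
    adapter3: str,
    adapter5: str | None = None,
    *,
    min_len: int = MIN_TAG_LEN,
    max_len: int = MAX_TAG_LEN,
    min_quality: float = 20.0,
    **trim_kwargs,
) -> tuple[dict[str, int], LibrarySummary, Counter]:
    """Full per-library preprocessing: trim, quality-filter, collapse.

    Accepts RawRead objects or the (id, seq, qual, count) tuples yielded
    by :func:`mirpipe.io.iter_reads`.  Returns (tags, summary, rejection
    reason counter).
    """
    reasons: Counter[str] = Counter()

    def trimmed() -> Iterable[tuple[str, int]]:
        for item in reads:
            if isinstance(item, RawRead):
                read, count = item, 1
            else:
                ident, seq, qual, count = item
                read = RawRead(ident, seq, qual)
            res = trim_adapter(read, adapter3, adapter5, **trim_kwargs)
            if not res.ok:
                reasons[res.reason] += count
                continue
            if not mean_quality_ok(read.quality, 0, len(res.insert), min_quality):
                reasons["low_quality"] += count
                continue
            yield res.insert, count

    tags, summary = filter_and_collapse(trimmed(), min_len, max_len)
    return tags, summary, reasons


def merge_libraries(tags1: dict[str, int], tags2: dict[str, int]) -> list[CleanTag]:
    """Union of two libraries' tag sets with per-library counts,
    sorted by total count descending then sequence."""
    merged = [
        CleanTag(seq, tags1.get(seq, 0), tags2.get(seq, 0))
        for seq in set(tags1) | set(tags2)
    ]
    merged.sort(key=lambda t: (-t.total, t.sequence))
    return merged
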