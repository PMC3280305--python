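"""Genomic interval types shared by the mapping, clustering and
context-classification stages.  Coordinates are 0-based half-open
throughout; GFF3 emission converts to 1-based inclusive."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional


@dataclass(frozen=True)
class GenomicLocus:
    """A placed sequence (tag or precursor) on the genome."""

    chrom: str
    start: int
    end: int
    strand: str = "+"
    name: str = ""
    sequence: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def to_gff3(self, feature: str = "miRNA_primary_transcript") -> str:
        attrs = f"ID={self.name}" if self.name else "."
        return "\t".join(
            [self.chrom, "mirpipe", feature, str(self.start + 1), str(self.end),
             ".", self.strand, ".", attrs]
        )


@dataclass
class Cluster:
    """A chromosomal group of precursor loci with inter-locus gaps
    below the clustering threshold; at least two members."""

    chrom: str
    members: list[GenomicLocus] = field(default_factory=list)

    @property
    def span(self) -> tuple[int, int]:
        return min(m.start for m in self.members), max(m.end for m in self.members)

    def __len__(self) -> int:
        return len(self.members)
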