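"""Sequence file I/O helpers.

Reads FASTA/FASTQ through Biopython, normalises RNA (U) to DNA (T)
alphabet on request, and understands the count-collapsed FASTA dialect
used for unique small-RNA tags, where the record id carries the read
count as a ``_xN`` suffix (``>tag1_x392``).
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterator

from Bio import SeqIO
from Bio.Seq import Seq

_COLLAPSED_ID = re.compile(r"^(?P<name>.+)_x(?P<count>\d+)$")


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def normalize_nt(seq: str) -> str:
    """Uppercase and convert RNA to DNA alphabet (U -> T)."""
    return seq.upper().replace("U", "T")


def sniff_format(path: str | Path) -> str:
    """Return 'fasta' or 'fastq' from the first non-blank character."""
    with open(path) as fh:
        for line in fh:
            if line.strip():
                if line.startswith(">"):
                    return "fasta"
                if line.startswith("@"):
                    return "fastq"
                raise ValueError(f"{path}: not FASTA or FASTQ")
    raise ValueError(f"{path}: empty file")


def read_fasta(path: str | Path, *, to_dna: bool = True) -> dict[str, str]:
    """Read a FASTA file into an ordered name -> sequence mapping."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        out[rec.id] = normalize_nt(seq) if to_dna else seq.upper()
    return out


def parse_collapsed_id(identifier: str) -> tuple[str, int]:
    """Split a ``name_xN`` collapsed-read id into (name, count).

    Ids without the suffix count as a single read.
    """
    m = _COLLAPSED_ID.match(identifier)
    if m:
        return m.group("name"), int(m.group("count"))
    return identifier, 1


def iter_reads(path: str | Path) -> Iterator[tuple[str, str, list[int] | None, int]]:
    """Yield (identifier, sequence, quality or None, count) per record.

    FASTQ records always have count 1; FASTA records may be collapsed
    (``_xN``) and carry no qualities.
    """
    fmt = sniff_format(path)
    for rec in SeqIO.parse(str(path), fmt):
        seq = normalize_nt(str(rec.seq))
        if fmt == "fastq":
            qual = rec.letter_annotations["phred_quality"]
            yield rec.id, seq, qual, 1
        else:
            name, count = parse_collapsed_id(rec.id)
            yield name, seq, None, count


def write_fasta(records: dict[str, str] | list[tuple[str, str]], path: str | Path) -> None:
    items = records.items() if isinstance(records, dict) else records
    with open(path, "w") as fh:
        for name, seq in items:
            fh.write(f">{name}\n{seq}\n")


def write_collapsed_fasta(
    tags: list[tuple[str, int]], path: str | Path, prefix: str = "tag"
) -> None:
    """Write unique tags as ``>prefixI_xCOUNT`` records."""
    with open(path, "w") as fh:
        for i, (seq, count) in enumerate(tags, start=1):
            fh.write(f">{prefix}{i}_x{count}\n{seq}\n")
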