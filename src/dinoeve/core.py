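"""Shared sequence records and FASTA input/output.

Coordinates are 0-based half-open on the forward strand everywhere in
memory; 1-based inclusive conversions happen only at the GFF3/TSV
boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class InputError(ValueError):
    """Malformed or inconsistent user input (CLI exit code 2)."""


@dataclass
class Scaffold:
    """A nucleotide sequence record with provenance labels."""

    id: str
    seq: str
    assembly: str | None = None
    genus: str | None = None
    source: str | None = None

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()

    def __len__(self) -> int:
        return len(self.seq)


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _parse_header_tags(description: str) -> dict[str, str]:
    tags = {}
    for token in description.split()[1:]:
        if "=" in token:
            key, _, value = token.partition("=")
            tags[key] = value
    return tags


def read_fasta(path: str | Path) -> list[Scaffold]:
    """Read scaffolds; ``assembly=`` / ``genus=`` header tokens are honored."""
    path = Path(path)
    records = []
    try:
        for rec in SeqIO.parse(str(path), "fasta"):
            tags = _parse_header_tags(rec.description)
            records.append(
                Scaffold(
                    id=rec.id,
                    seq=str(rec.seq),
                    assembly=tags.get("assembly"),
                    genus=tags.get("genus"),
                    source=str(path),
                )
            )
    except (ValueError, FileNotFoundError) as exc:
        raise InputError(f"cannot parse FASTA {path}: {exc}") from exc
    if not records:
        raise InputError(f"no sequence records in {path}")
    for rec in records:
        if not rec.seq:
            raise InputError(f"empty sequence for record {rec.id!r} in {path}")
    return records


def write_fasta(scaffolds: Iterable[Scaffold], path: str | Path, width: int = 70) -> None:
    records = []
    for sc in scaffolds:
        desc = []
        if sc.assembly:
            desc.append(f"assembly={sc.assembly}")
        if sc.genus:
            desc.append(f"genus={sc.genus}")
        records.append(SeqRecord(Seq(sc.seq), id=sc.id, description=" ".join(desc)))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)
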