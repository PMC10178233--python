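"""Reading and writing ITS2 sequence-structure records.

The on-disk dialect is a Vienna-style triplet FASTA: a header line starting
with ``>``, the aligned sequence, and a dot-bracket structure line of the same
length.  An allele copy count may be encoded in the header as ``count=N``.
A plain FASTA reader is also provided for sequence-only regions (5.8S).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

logger = logging.getLogger(__name__)

_VALID_SEQ = frozenset("ACGU-N")
_VALID_STRUCT = frozenset("().")
_COUNT_RE = re.compile(r"\bcount=(\d+)\b")


class ViennaParseError(ValueError):
    """Raised when a sequence-structure file or record is malformed."""


def check_balanced(structure: str) -> None:
    """Validate that a dot-bracket string is balanced and properly nested.

    Raises :class:`ViennaParseError` naming the offending position.
    """
    depth = 0
    for pos, ch in enumerate(structure):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise ViennaParseError(
                    f"unbalanced structure: unmatched ')' at position {pos}"
                )
        elif ch != ".":
            raise ViennaParseError(
                f"invalid structure character {ch!r} at position {pos}"
            )
    if depth != 0:
        raise ViennaParseError(
            f"unbalanced structure: {depth} unmatched '(' at end of string"
        )


@dataclass
class SeqStructRecord:
    """One ITS2 allele: aligned RNA sequence plus its dot-bracket structure.

    Input sequences are case-folded to upper case and T is mapped to U on
    construction.  ``copy_count`` is the number of identical reads/copies the
    allele was observed with (defaults to 1 for plain Vienna files).
    """

    id: str
    sequence: str
    structure: str
    copy_count: int = 1

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper().replace("T", "U")
        bad = set(self.sequence) - _VALID_SEQ
        if bad:
            raise ViennaParseError(
                f"record {self.id!r}: invalid sequence characters {sorted(bad)}"
            )
        if len(self.sequence) != len(self.structure):
            raise ViennaParseError(
                f"record {self.id!r}: sequence length {len(self.sequence)} != "
                f"structure length {len(self.structure)}"
            )
        try:
            check_balanced(self.structure)
        except ViennaParseError as err:
            raise ViennaParseError(f"record {self.id!r}: {err}") from None
        if self.copy_count < 1:
            raise ViennaParseError(
                f"record {self.id!r}: copy_count must be >= 1, got {self.copy_count}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class SpeciesMatrix:
    """All retained alleles of one species as an aligned sequence-structure matrix."""

    species_name: str
    records: list[SeqStructRecord] = field(default_factory=list)
    consensus_structure: str | None = None

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError(f"species {self.species_name!r}: no records")
        lengths = {len(r) for r in self.records}
        if len(lengths) != 1:
            raise ValueError(
                f"species {self.species_name!r}: unequal aligned lengths {sorted(lengths)}"
            )
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError(f"species {self.species_name!r}: duplicate record ids")
        if self.consensus_structure is not None and len(
            self.consensus_structure
        ) != len(self.records[0]):
            raise ValueError(
                f"species {self.species_name!r}: consensus structure length mismatch"
            )

    @property
    def ncols(self) -> int:
        return len(self.records[0])

    def __len__(self) -> int:
        return len(self.records)


def read_seqstruct(path: str | Path) -> list[SeqStructRecord]:
    """Read a Vienna-triplet file (header / sequence / dot-bracket groups)."""
    path = Path(path)
    lines = [ln.rstrip("\n") for ln in path.read_text().splitlines()]
    lines = [ln for ln in lines if ln.strip()]
    if not lines:
        raise ViennaParseError(f"{path}: empty file")
    records: list[SeqStructRecord] = []
    i = 0
    while i < len(lines):
        header = lines[i]
        if not header.startswith(">"):
            raise ViennaParseError(f"{path}: expected '>' header at line {i + 1}")
        if i + 2 >= len(lines):
            raise ViennaParseError(
                f"{path}: truncated record {header[1:].split()[0]!r} at end of file"
            )
        name = header[1:].split()[0]
        m = _COUNT_RE.search(header)
        count = int(m.group(1)) if m else 1
        records.append(
            SeqStructRecord(
                id=name, sequence=lines[i + 1], structure=lines[i + 2], copy_count=count
            )
        )
        i += 3
    return records


def write_seqstruct(records: Sequence[SeqStructRecord], path: str | Path) -> None:
    """Write records as Vienna triplets; round-trips through :func:`read_seqstruct`."""
    if not records:
        raise ValueError("nothing to write: empty record collection")
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            fh.write(f">{rec.id} count={rec.copy_count}\n")
            fh.write(rec.sequence + "\n")
            fh.write(rec.structure + "\n")


def read_fasta(path: str | Path) -> list[SeqStructRecord]:
    """Read a plain FASTA file as structure-less records (all-unpaired).

    Used for sequence-only regions such as 5.8S; the attached structure is a
    run of dots so that composition statistics apply unchanged.
    """
    seqs = list(SeqIO.parse(str(path), "fasta"))
    if not seqs:
        raise ViennaParseError(f"{path}: empty file")
    out = []
    for sr in seqs:
        m = _COUNT_RE.search(sr.description)
        out.append(
            SeqStructRecord(
                id=sr.id,
                sequence=str(sr.seq),
                structure="." * len(sr.seq),
                copy_count=int(m.group(1)) if m else 1,
            )
        )
    return out


def filter_singleton_alleles(
    records: Iterable[SeqStructRecord],
) -> list[SeqStructRecord]:
    """Drop alleles observed with a single copy (possible assembly artifacts).

    Keeps exactly the records with ``copy_count >= 2`` in their original
    order.  Idempotent; an empty result is legal and logged as a warning.
    """
    records = list(records)
    kept = [r for r in records if r.copy_count >= 2]
    removed = len(records) - len(kept)
    if kept:
        logger.info("singleton filter: removed %d, kept %d alleles", removed, len(kept))
    else:
        logger.warning(
            "singleton filter: all %d alleles were singletons; nothing kept", removed
        )
    return kept
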