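"""Consensus secondary structure and paired/unpaired column partitioning.

Alignment columns are split by the consensus structure into *paired* columns
(sides of retained base pairs, encoded jointly as 16-state doublets) and
*unpaired* columns (single nucleotides).  Coordinates are 0-based internally;
report writers print 1-based positions.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alphabet import DOUBLET_INDEX, MISSING, NUC_INDEX
from .io_seqstruct import SpeciesMatrix, ViennaParseError


def parse_dotbracket(structure: str) -> list[tuple[int, int]]:
    """Stack-parse Vienna notation into a list of (i, j) pairs with i < j.

    Pairs are returned sorted by opening position.  Raises
    :class:`ViennaParseError` at the first unbalanced bracket.
    """
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for pos, ch in enumerate(structure):
        if ch == "(":
            stack.append(pos)
        elif ch == ")":
            if not stack:
                raise ViennaParseError(
                    f"unbalanced structure: unmatched ')' at position {pos}"
                )
            pairs.append((stack.pop(), pos))
        elif ch != ".":
            raise ViennaParseError(
                f"invalid structure character {ch!r} at position {pos}"
            )
    if stack:
        raise ViennaParseError(
            f"unbalanced structure: unmatched '(' at position {stack[-1]}"
        )
    return sorted(pairs)


def pairs_to_dotbracket(pairs: list[tuple[int, int]], ncols: int) -> str:
    chars = ["."] * ncols
    for i, j in pairs:
        chars[i] = "("
        chars[j] = ")"
    return "".join(chars)


@dataclass
class ConsensusStructure:
    """Consensus structure: retained pairs with their per-record support."""

    dotbracket: str
    pair_support: dict[tuple[int, int], float]

    def __len__(self) -> int:
        return len(self.dotbracket)


@dataclass
class StructurePartition:
    """Paired column pairs and unpaired columns of a consensus structure."""

    paired: list[tuple[int, int]]
    unpaired: list[int]
    ncols: int

    def __post_init__(self) -> None:
        seen = [c for i, j in self.paired for c in (i, j)] + list(self.unpaired)
        if sorted(seen) != list(range(self.ncols)):
            raise ValueError("partition does not cover each column exactly once")

    @property
    def n_sites(self) -> int:
        """Number of likelihood sites: one per pair plus one per unpaired column."""
        return len(self.paired) + len(self.unpaired)

    def to_frame(self) -> pd.DataFrame:
        """Tabular view (1-based positions): column, role, partner."""
        rows = []
        partner = {}
        for i, j in self.paired:
            partner[i], partner[j] = j, i
        for c in range(self.ncols):
            if c in partner:
                rows.append((c + 1, "paired", partner[c] + 1))
            else:
                rows.append((c + 1, "unpaired", 0))
        return pd.DataFrame(rows, columns=["column", "role", "partner"])


def _crosses(a: tuple[int, int], b: tuple[int, int]) -> bool:
    (i, j), (k, l) = sorted((a, b))
    return i < k < j < l


def consensus_structure(
    matrix: SpeciesMatrix, threshold: float = 0.70
) -> ConsensusStructure:
    """Derive the consensus structure retaining pairs of sufficient support.

    A candidate pair (i, j) is retained iff the fraction of records whose
    structure contains it is >= ``threshold``.  The retained set is made
    non-crossing (and one-pairing-per-column) greedily in order of decreasing
    support, ties broken by smaller opening then closing position.
    """
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    n = len(matrix.records)
    counts: Counter[tuple[int, int]] = Counter()
    for rec in matrix.records:
        counts.update(parse_dotbracket(rec.structure))
    candidates = [
        (pair, cnt / n) for pair, cnt in counts.items() if cnt / n >= threshold
    ]
    candidates.sort(key=lambda ps: (-ps[1], ps[0]))
    accepted: list[tuple[int, int]] = []
    used: set[int] = set()
    support: dict[tuple[int, int], float] = {}
    for pair, sup in candidates:
        i, j = pair
        if i in used or j in used:
            continue
        if any(_crosses(pair, other) for other in accepted):
            continue
        accepted.append(pair)
        used.update(pair)
        support[pair] = sup
    accepted.sort()
    return ConsensusStructure(
        dotbracket=pairs_to_dotbracket(accepted, matrix.ncols),
        pair_support={p: support[p] for p in accepted},
    )


def partition_columns(
    consensus: ConsensusStructure | str, ncols: int
) -> StructurePartition:
    """Split columns 0..ncols-1 into paired pairs and unpaired singles."""
    dotbracket = (
        consensus.dotbracket
        if isinstance(consensus, ConsensusStructure)
        else consensus
    )
    if len(dotbracket) != ncols:
        raise ValueError(
            f"consensus length {len(dotbracket)} != alignment columns {ncols}"
        )
    pairs = parse_dotbracket(dotbracket)
    in_pair = {c for ij in pairs for c in ij}
    unpaired = [c for c in range(ncols) if c not in in_pair]
    return StructurePartition(paired=pairs, unpaired=unpaired, ncols=ncols)


@dataclass
class DoubletAlignment:
    """Encoded alignment: 16-state codes at pair sites, 4-state at unpaired.

    ``paired`` has shape (n_records, n_pairs), ``unpaired`` shape
    (n_records, n_unpaired); gaps/N are :data:`~its2gc.alphabet.MISSING`.
    """

    taxa: list[str]
    paired: np.ndarray
    unpaired: np.ndarray


def encode_doublets(
    matrix: SpeciesMatrix, partition: StructurePartition
) -> DoubletAlignment:
    """Encode each record over the partition; gap/N on either side -> missing."""
    if partition.ncols != matrix.ncols:
        raise ValueError("partition does not match matrix width")
    n = len(matrix.records)
    paired = np.full((n, len(partition.paired)), MISSING, dtype=np.int64)
    unpaired = np.full((n, len(partition.unpaired)), MISSING, dtype=np.int64)
    for r, rec in enumerate(matrix.records):
        seq = rec.sequence
        for s, (i, j) in enumerate(partition.paired):
            d = seq[i] + seq[j]
            paired[r, s] = DOUBLET_INDEX.get(d, MISSING)
        for s, c in enumerate(partition.unpaired):
            unpaired[r, s] = NUC_INDEX.get(seq[c], MISSING)
    return DoubletAlignment(
        taxa=[rec.id for rec in matrix.records], paired=paired, unpaired=unpaired
    )
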