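"""Nucleotide and base-pair (doublet) state spaces shared across the package.

The internal alphabet is RNA; DNA input is normalized on read (T -> U).
Doublets are ordered pairs of nucleotides occupying the two sides of a stem
position, indexed 0..15 in the order AA, AC, ..., UU (first base major).
"""

from __future__ import annotations

NUC = "ACGU"
NUC_INDEX = {b: i for i, b in enumerate(NUC)}

DOUBLETS = tuple(a + b for a in NUC for b in NUC)
DOUBLET_INDEX = {d: i for i, d in enumerate(DOUBLETS)}

#: Watson-Crick pairs split by composition; wobble G.U is an intermediate.
GC_TYPE = ("GC", "CG")
AU_TYPE = ("AU", "UA")
WOBBLE = ("GU", "UG")
CANONICAL = GC_TYPE + AU_TYPE + WOBBLE
MISMATCH_DOUBLETS = tuple(d for d in DOUBLETS if d not in CANONICAL)

#: The four unordered heteroduplex mismatches repairable by a one-side change.
MISMATCHES = ("AG", "AC", "CU", "GU")

#: 7-state lumped space: the six canonical/wobble pairs plus one mismatch state.
STATES7 = ("AU", "GU", "GC", "UA", "UG", "CG", "MM")
STATE7_INDEX = {s: i for i, s in enumerate(STATES7)}

#: Code used for gap/N (unknown) observations in encoded alignments.
MISSING = -1

GAP_CHARS = frozenset("-N")


def gc_fraction(doublet: str) -> float:
    """Fraction of G/C nucleotides in a doublet (0, 0.5 or 1)."""
    return sum(b in "GC" for b in doublet) / 2.0


def doublet_to_7state(code: int) -> int:
    """Map a 16-state doublet code onto the 7-state lumped space."""
    if code == MISSING:
        return MISSING
    d = DOUBLETS[code]
    return STATE7_INDEX[d] if d in STATE7_INDEX else STATE7_INDEX["MM"]
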