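"""Equilibrium GC (GC*), base-pair formation rates, and mismatch-conversion bias.

GC* is the GC content a region converges to if the fitted substitution process
stays constant: for unpaired regions it is the AT->GC flux share
u / (u + v) with u, v the stationary fluxes from A/U into G/C and back; for
paired regions it is the GC composition of the doublet chain's stationary
distribution.  Formation rates compare the rate-matrix entries of the six
single-change routes into GC-type pairs (GC, CG) with the six into AU-type
pairs (AU, UA) - the substitution-pattern signature of GC-biased gene
conversion.  Mismatch conversion scores the one-side repairs of the four
heteroduplex mismatches (A.G, A.C, C.U, G.U) toward GC-type vs AU-type pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alphabet import (
    AU_TYPE,
    DOUBLET_INDEX,
    GC_TYPE,
    MISMATCHES,
    NUC,
    NUC_INDEX,
    STATE7_INDEX,
    gc_fraction,
)
from .rates import NucRateModel, PairRateModel, stationary_distribution


@dataclass
class GcStarEstimate:
    region: str  # "paired" | "unpaired"
    gc_current: float
    gc_star: float
    trend: str  # "increasing" | "decreasing" | "stable"


@dataclass
class TransformationSummary:
    """Single-change formation routes into GC-type vs AU-type pairs."""

    routes: pd.DataFrame  # columns: target, source, rate
    total_to_gc: float
    total_to_au: float
    ratio: float
    gc_pair_freq: float
    au_pair_freq: float


@dataclass
class MismatchConversion:
    """One-side repair rates of the four heteroduplex mismatches."""

    table: pd.DataFrame  # mismatch, gc_destination, au_destination, rate_to_gc, rate_to_au
    aggregate_ratio: float


def gc_star_nucleotide(model: NucRateModel) -> float:
    """GC* percent from the 4-state model: 100 * u / (u + v).

    u is the stationary substitution rate from A/U into G/C per A/U base,
    v the reverse per G/C base.  For any reversible model this equals
    100 * (pi_G + pi_C).
    """
    pi, Q = model.freqs, model.Q
    at = [NUC_INDEX["A"], NUC_INDEX["U"]]
    gc = [NUC_INDEX["G"], NUC_INDEX["C"]]
    pi_at = pi[at].sum()
    pi_gc = pi[gc].sum()
    if pi_at <= 0 or pi_gc <= 0:
        raise ValueError("GC* undefined: zero AT or GC stationary mass")
    u = sum(pi[i] * Q[i, j] for i in at for j in gc) / pi_at
    v = sum(pi[i] * Q[i, j] for i in gc for j in at) / pi_gc
    return 100.0 * u / (u + v)


def gc_star_pair(model: PairRateModel) -> float:
    """GC* percent of the doublet chain's stationary composition.

    Solves pi Q = 0 and returns 100 * sum_d pi_d g(d) with g(d) the G/C
    fraction of doublet d (the lumped MM state counts 0.5).
    """
    pi = stationary_distribution(model.Q)
    g = np.array(
        [0.5 if lab == "MM" else gc_fraction(lab) for lab in model.state_labels]
    )
    return float(100.0 * np.dot(pi, g))


def gc_trend(
    gc_current: float, gc_star: float, tolerance: float = 0.1, region: str = ""
) -> GcStarEstimate:
    """Classify the GC evolutionary trend of a region at a percent tolerance."""
    for v in (gc_current, gc_star):
        if not 0.0 <= v <= 100.0:
            raise ValueError(f"GC percent out of [0, 100]: {v}")
    delta = gc_star - gc_current
    if delta > tolerance:
        trend = "increasing"
    elif delta < -tolerance:
        trend = "decreasing"
    else:
        trend = "stable"
    return GcStarEstimate(
        region=region, gc_current=gc_current, gc_star=gc_star, trend=trend
    )


def formation_routes_16(target: str) -> list[str]:
    """The six single-change source doublets of a 16-state target doublet."""
    routes = []
    for pos in (0, 1):
        for b in NUC:
            if b != target[pos]:
                src = b + target[1] if pos == 0 else target[0] + b
                routes.append(src)
    return routes


def formation_rates(model: PairRateModel) -> TransformationSummary:
    """Formation rates into GC-type vs AU-type pairs and their ratio.

    Rates are the rate-matrix entries q(source -> target) of single-change
    routes (not fluxes); stationary frequencies of GC-type and AU-type pairs
    are reported alongside for the frequency-mutability view.  On the 7-state
    space the lumped MM state is the single mismatch source.
    """
    Q = model.Q
    rows = []
    if model.n_states == 16:
        for target in GC_TYPE + AU_TYPE:
            for src in formation_routes_16(target):
                rows.append(
                    (target, src, Q[DOUBLET_INDEX[src], DOUBLET_INDEX[target]])
                )
    else:
        neighbors = {"GC": ["GU", "MM"], "CG": ["UG", "MM"],
                     "AU": ["GU", "MM"], "UA": ["UG", "MM"]}
        for target, srcs in neighbors.items():
            for src in srcs:
                rows.append((target, src, Q[STATE7_INDEX[src], STATE7_INDEX[target]]))
    routes = pd.DataFrame(rows, columns=["target", "source", "rate"])
    total_gc = float(routes.loc[routes.target.isin(GC_TYPE), "rate"].sum())
    total_au = float(routes.loc[routes.target.isin(AU_TYPE), "rate"].sum())
    labels = list(model.state_labels)
    pi = model.freqs
    gc_freq = float(sum(pi[labels.index(s)] for s in GC_TYPE))
    au_freq = float(sum(pi[labels.index(s)] for s in AU_TYPE))
    return TransformationSummary(
        routes=routes,
        total_to_gc=total_gc,
        total_to_au=total_au,
        ratio=total_gc / total_au if total_au > 0 else np.inf,
        gc_pair_freq=gc_freq,
        au_pair_freq=au_freq,
    )


#: For each unordered mismatch X.Y (given as the ordered doublet "XY"), the
#: Watson-Crick destinations reached by changing one side: (GC-type, AU-type).
MISMATCH_DESTINATIONS = {
    "AG": ("CG", "AU"),
    "AC": ("GC", "AU"),
    "CU": ("CG", "AU"),
    "GU": ("GC", "AU"),
}


def _one_side_rate(Q: np.ndarray, src: str, dst: str) -> float:
    """Rate entry for the single-position change src -> dst."""
    return float(Q[DOUBLET_INDEX[src], DOUBLET_INDEX[dst]])


def _swap(d: str) -> str:
    return d[1] + d[0]


def mismatch_conversion(model: PairRateModel) -> MismatchConversion:
    """Repair bias of the four heteroduplex mismatches toward GC vs AU pairs.

    Each unordered mismatch maps to its two ordered doublets; the one-side
    repair rates into the GC-type and AU-type destinations are averaged over
    the two orderings.  Requires the 16-state model - the 7-state space lumps
    mismatch identities and cannot resolve the four repairs.
    """
    if model.n_states != 16:
        raise ValueError(
            "mismatch_conversion needs the 16-state model: the 7-state space "
            "lumps all mismatches into MM and loses their identities"
        )
    Q = model.Q
    rows = []
    for mm in MISMATCHES:
        gc_dst, au_dst = MISMATCH_DESTINATIONS[mm]
        r_gc = 0.5 * (
            _one_side_rate(Q, mm, gc_dst) + _one_side_rate(Q, _swap(mm), _swap(gc_dst))
        )
        r_au = 0.5 * (
            _one_side_rate(Q, mm, au_dst) + _one_side_rate(Q, _swap(mm), _swap(au_dst))
        )
        rows.append((f"{mm[0]}.{mm[1]}", gc_dst, au_dst, r_gc, r_au))
    table = pd.DataFrame(
        rows,
        columns=["mismatch", "gc_destination", "au_destination", "rate_to_gc", "rate_to_au"],
    )
    tot_au = table["rate_to_au"].sum()
    return MismatchConversion(
        table=table,
        aggregate_ratio=float(table["rate_to_gc"].sum() / tot_au)
        if tot_au > 0
        else np.inf,
    )
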