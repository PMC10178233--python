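"""Nucleotide and base-pair (doublet) substitution rate matrices.

All models are continuous-time Markov models given as a rate matrix Q with
stationary frequencies pi, normalized so that the average substitution rate
-sum_i pi_i q_ii equals 1 (branch lengths are then expected substitutions per
site).  Doublet models forbid double substitutions: a rate between doublets
differing at both positions is zero, so base-pair change proceeds through an
intermediate state (e.g. GC - GU - AU).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm, null_space

from .alphabet import DOUBLETS, GC_TYPE, STATES7, STATE7_INDEX

_NORM_TOL = 1e-10


@dataclass
class NucRateModel:
    """4-state nucleotide model (HKY85 or REV/GTR) over A, C, G, U."""

    kind: str
    freqs: np.ndarray
    Q: np.ndarray
    params: dict = field(default_factory=dict)

    @property
    def n_states(self) -> int:
        return 4


@dataclass
class PairRateModel:
    """Doublet model over the 16 ordered pairs, or the 7-state lumped space."""

    state_labels: tuple[str, ...]
    freqs: np.ndarray
    Q: np.ndarray
    no_double_substitution: bool = True
    reversible: bool = True
    params: dict = field(default_factory=dict)

    @property
    def n_states(self) -> int:
        return len(self.state_labels)


def _check_freqs(freqs: np.ndarray, n: int) -> np.ndarray:
    freqs = np.asarray(freqs, dtype=float)
    if freqs.shape != (n,):
        raise ValueError(f"expected {n} frequencies, got shape {freqs.shape}")
    if np.any(freqs <= 0):
        raise ValueError("stationary frequencies must be positive")
    if abs(freqs.sum() - 1.0) > 1e-6:
        raise ValueError(f"frequencies must sum to 1, got {freqs.sum():.8f}")
    return freqs / freqs.sum()


def _finalize_q(S: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    """Assemble q_ij = s_ij * pi_j, set the diagonal, rescale to unit mean rate."""
    Q = S * freqs[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -np.dot(freqs, np.diag(Q))
    if mu <= 0:
        raise ValueError("degenerate rate matrix: zero mean rate")
    return Q / mu


def hky85(kappa: float, freqs) -> NucRateModel:
    """HKY85: transitions (A<->G, C<->U) scaled by kappa over transversions."""
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    freqs = _check_freqs(freqs, 4)
    S = np.ones((4, 4))
    S[0, 2] = S[2, 0] = kappa  # A<->G
    S[1, 3] = S[3, 1] = kappa  # C<->U
    return NucRateModel(
        kind="HKY85", freqs=freqs, Q=_finalize_q(S, freqs), params={"kappa": kappa}
    )


#: Order of the six REV exchangeabilities: AC, AG, AU, CG, CU, GU.
REV_PAIRS = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))


def rev(rates, freqs) -> NucRateModel:
    """General time-reversible (REV/GTR) nucleotide model."""
    rates = np.asarray(rates, dtype=float)
    if rates.shape != (6,) or np.any(rates < 0):
        raise ValueError("REV needs 6 nonnegative exchangeabilities")
    freqs = _check_freqs(freqs, 4)
    S = np.zeros((4, 4))
    for r, (i, j) in zip(rates, REV_PAIRS):
        S[i, j] = S[j, i] = r
    return NucRateModel(
        kind="REV", freqs=freqs, Q=_finalize_q(S, freqs), params={"rates": rates}
    )


def doublet_change_mask() -> np.ndarray:
    """16x16 boolean mask of single-position doublet changes."""
    mask = np.zeros((16, 16), dtype=bool)
    for i, a in enumerate(DOUBLETS):
        for j, b in enumerate(DOUBLETS):
            if i != j and sum(x != y for x, y in zip(a, b)) == 1:
                mask[i, j] = True
    return mask


def seven_state_mask() -> np.ndarray:
    """Allowed 7-state transitions: single-base moves among the six pairs,
    plus every pair <-> the lumped mismatch state MM."""
    edges = [("AU", "GU"), ("GU", "GC"), ("UA", "UG"), ("UG", "CG")]
    edges += [(s, "MM") for s in STATES7 if s != "MM"]
    mask = np.zeros((7, 7), dtype=bool)
    for a, b in edges:
        i, j = STATE7_INDEX[a], STATE7_INDEX[b]
        mask[i, j] = mask[j, i] = True
    return mask


_MASK16 = doublet_change_mask()
_MASK7 = seven_state_mask()


def allowed_mask(n_states: int) -> np.ndarray:
    if n_states == 16:
        return _MASK16
    if n_states == 7:
        return _MASK7
    raise ValueError("state space must be 16 or 7")


def n_exchangeabilities(n_states: int) -> int:
    return int(allowed_mask(n_states).sum()) // 2


def make_pair_model(state_space: int, freqs, exch) -> PairRateModel:
    """Reversible doublet model q_ij = s_ij pi_j on allowed single changes.

    ``exch`` is a vector of exchangeabilities over the allowed unordered state
    pairs, ordered by (i, j) with i < j over the allowed mask, or a full
    symmetric matrix.  Disallowed (double-change) entries are zero.
    """
    if state_space == 16:
        labels = DOUBLETS
    elif state_space == 7:
        labels = STATES7
    else:
        raise ValueError("state space must be 16 or 7")
    n = len(labels)
    freqs = _check_freqs(freqs, n)
    mask = allowed_mask(n)
    exch = np.asarray(exch, dtype=float)
    S = np.zeros((n, n))
    if exch.shape == (n, n):
        S[mask] = exch[mask]
    else:
        pairs = [(i, j) for i in range(n) for j in range(i + 1, n) if mask[i, j]]
        if exch.shape != (len(pairs),):
            raise ValueError(
                f"expected {len(pairs)} exchangeabilities, got {exch.shape}"
            )
        for s, (i, j) in zip(exch, pairs):
            S[i, j] = S[j, i] = s
    if np.any(S < 0):
        raise ValueError("exchangeabilities must be nonnegative")
    return PairRateModel(
        state_labels=labels,
        freqs=freqs,
        Q=_finalize_q(S, freqs),
        params={"exch": exch},
    )


def stationary_distribution(Q: np.ndarray) -> np.ndarray:
    """Solve pi Q = 0, sum(pi) = 1; error on reducible chains."""
    ns = null_space(Q.T)
    if ns.shape[1] != 1:
        raise ValueError("rate matrix is reducible: stationary distribution not unique")
    pi = ns[:, 0]
    pi = pi / pi.sum()
    if np.any(pi < -1e-6 * pi.max()):
        raise ValueError("invalid stationary distribution (negative mass)")
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def transition_probabilities(model, t: float) -> np.ndarray:
    """P(t) = expm(Q t); rows sum to 1, entries clipped at 0 for roundoff."""
    if t < 0:
        raise ValueError(f"branch length must be nonnegative, got {t}")
    Q = model.Q if hasattr(model, "Q") else np.asarray(model)
    if t == 0:
        return np.eye(Q.shape[0])
    P = expm(Q * t)
    P = np.clip(P, 0.0, None)
    return P / P.sum(axis=1, keepdims=True)


def gbgc_bias(model: PairRateModel, strength: float) -> PairRateModel:
    """Scale all rates *into* GC-type states (GC, CG) by ``strength``.

    Destination-column scaling of a reversible chain stays reversible with
    stationary pi'_j proportional to c_j pi_j; the result is renormalized to
    unit mean rate.  strength > 1 models GC-biased gene conversion.
    """
    if strength < 0:
        raise ValueError("gBGC strength must be nonnegative")
    labels = model.state_labels
    c = np.array([strength if lab in GC_TYPE else 1.0 for lab in labels])
    Q = model.Q.copy()
    np.fill_diagonal(Q, 0.0)
    Q = Q * c[None, :]
    pi = model.freqs * c
    pi = pi / pi.sum()
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -np.dot(pi, np.diag(Q))
    return PairRateModel(
        state_labels=labels,
        freqs=pi,
        Q=Q / mu,
        no_double_substitution=model.no_double_substitution,
        reversible=model.reversible,
        params={**model.params, "gbgc_strength": strength},
    )


def assert_valid_rate_model(model) -> None:
    """Numerical invariants: zero row sums, stationarity, unit mean rate,
    detailed balance for reversible models, forbidden double changes."""
    Q, pi = model.Q, model.freqs
    assert np.all(np.abs(Q.sum(axis=1)) < _NORM_TOL), "rows must sum to 0"
    off = Q - np.diag(np.diag(Q))
    assert np.all(off >= -_NORM_TOL), "off-diagonal rates must be >= 0"
    assert np.all(np.abs(pi @ Q) < 1e-8), "pi Q = 0 must hold"
    assert abs(-np.dot(pi, np.diag(Q)) - 1.0) < 1e-8, "mean rate must be 1"
    if getattr(model, "reversible", True):
        flux = pi[:, None] * Q
        assert np.allclose(flux, flux.T, atol=1e-10), "detailed balance violated"
    if getattr(model, "no_double_substitution", False):
        mask = allowed_mask(model.n_states)
        forbidden = ~mask & ~np.eye(model.n_states, dtype=bool)
        assert np.all(Q[forbidden] == 0.0), "double substitutions must be forbidden"
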