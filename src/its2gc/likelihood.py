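"""Felsenstein pruning likelihood, ML fitting and AICc model selection.

Mixed models score unpaired alignment columns under a 4-state nucleotide model
and paired column-pairs under a doublet model (one likelihood site per pair).
DNA-only candidates score every column, including both sides of each pair,
under the nucleotide model.  For AICc the sample size is always the number of
partition sites (one per pair + one per unpaired column) so that mixed and
DNA-only candidates are ranked on the same footing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from skbio import TreeNode

from .alphabet import MISSING, NUC, NUC_INDEX, doublet_to_7state
from .io_seqstruct import SpeciesMatrix
from .rates import (
    NucRateModel,
    PairRateModel,
    hky85,
    make_pair_model,
    n_exchangeabilities,
    rev,
    transition_probabilities,
)
from .structure import StructurePartition, encode_doublets
from .trees import build_nj_tree, get_branch_lengths, set_branch_lengths


# ---------------------------------------------------------------------------
# pruning core
# ---------------------------------------------------------------------------

def compress_patterns(data: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Collapse identical site columns; returns (patterns, weights)."""
    pats, counts = np.unique(np.asarray(data), axis=1, return_counts=True)
    return pats, counts.astype(float)


def _pruned_patterns(
    tree: TreeNode,
    taxa: Sequence[str],
    pats: np.ndarray,
    wts: np.ndarray,
    Q: np.ndarray,
    freqs: np.ndarray,
) -> float:
    n_states = len(freqs)
    npat = pats.shape[1]
    tip_row = {t: k for k, t in enumerate(taxa)}
    scale = np.zeros(npat)

    def partial(node: TreeNode) -> np.ndarray:
        nonlocal scale
        if node.is_tip():
            codes = pats[tip_row[node.name]]
            L = np.zeros((npat, n_states))
            L[codes == MISSING] = 1.0  # missing data: marginalize over states
            obs = codes >= 0
            L[np.nonzero(obs)[0], codes[obs]] = 1.0
            return L
        L = np.ones((npat, n_states))
        for child in node.children:
            P = transition_probabilities(Q, child.length or 0.0)
            L = L * (partial(child) @ P.T)
        m = L.max(axis=1)
        safe = np.where(m > 0, m, 1.0)
        scale += np.log(safe)
        return L / safe[:, None]

    site = partial(tree) @ freqs
    ll = np.log(np.clip(site, 1e-300, None)) + scale
    return float(np.dot(wts, ll))


def pruned_loglik(
    tree: TreeNode,
    taxa: Sequence[str],
    data: np.ndarray,
    Q: np.ndarray,
    freqs: np.ndarray,
) -> float:
    """Pruning log-likelihood of an encoded (n_taxa, n_sites) data matrix."""
    if data.size == 0:
        return 0.0
    pats, wts = compress_patterns(data)
    return _pruned_patterns(tree, taxa, pats, wts, Q, np.asarray(freqs, dtype=float))


def encode_nucleotides(matrix: SpeciesMatrix) -> np.ndarray:
    """4-state codes for every alignment column (gap/N -> missing)."""
    out = np.full((len(matrix.records), matrix.ncols), MISSING, dtype=np.int64)
    for r, rec in enumerate(matrix.records):
        for c, b in enumerate(rec.sequence):
            out[r, c] = NUC_INDEX.get(b, MISSING)
    return out


def _check_taxa(tree: TreeNode, taxa: Sequence[str]) -> None:
    tips = sorted(t.name for t in tree.tips())
    if tips != sorted(taxa):
        raise ValueError(
            f"tree taxa do not match matrix allele ids: {tips} vs {sorted(taxa)}"
        )


def log_likelihood(
    matrix: SpeciesMatrix,
    partition: StructurePartition,
    nuc_model: NucRateModel | None,
    pair_model: PairRateModel | None,
    tree: TreeNode,
) -> float:
    """Total log-likelihood under a mixed (or DNA-only) model.

    With ``pair_model`` None the nucleotide model scores all columns
    (DNA-only).  With both models given, unpaired columns are 4-state sites
    and each base pair is one doublet site; gaps/N are marginalized.
    """
    enc = encode_doublets(matrix, partition)
    _check_taxa(tree, enc.taxa)
    if pair_model is None:
        if nuc_model is None:
            raise ValueError("need at least one model")
        data = encode_nucleotides(matrix)
        return pruned_loglik(tree, enc.taxa, data, nuc_model.Q, nuc_model.freqs)
    total = 0.0
    if enc.unpaired.shape[1]:
        if nuc_model is None:
            raise ValueError("unpaired columns present but no nucleotide model")
        total += pruned_loglik(
            tree, enc.taxa, enc.unpaired, nuc_model.Q, nuc_model.freqs
        )
    if enc.paired.shape[1]:
        codes = enc.paired
        if pair_model.n_states == 7:
            codes = np.vectorize(doublet_to_7state)(codes)
        total += pruned_loglik(tree, enc.taxa, codes, pair_model.Q, pair_model.freqs)
    return total


# ---------------------------------------------------------------------------
# parameterized model families
# ---------------------------------------------------------------------------

def _softmax_freqs(weights: np.ndarray, n: int) -> np.ndarray:
    w = np.concatenate([[0.0], np.asarray(weights, dtype=float)])
    if len(w) != n:
        raise ValueError("wrong number of frequency weights")
    e = np.exp(w - w.max())
    return e / e.sum()


def _pair_freqs_from_nuc(p: np.ndarray, n_states: int) -> np.ndarray:
    """Doublet frequencies as products of nucleotide frequencies."""
    prod = np.outer(p, p).ravel()
    if n_states == 16:
        return prod
    # lump: AU,GU,GC,UA,UG,CG then MM = the 10 remaining products
    from .alphabet import DOUBLET_INDEX, STATES7

    out = np.empty(7)
    lumped = 1.0
    for k, s in enumerate(STATES7[:-1]):
        out[k] = prod[DOUBLET_INDEX[s]]
        lumped -= out[k]
    out[6] = lumped
    return out


@dataclass(frozen=True)
class NucFamily:
    """HKY85 (kappa) or REV (6 exchangeabilities), free stationary frequencies."""

    kind: str  # "HKY85" | "REV"

    @property
    def n_params(self) -> int:
        return (1 if self.kind == "HKY85" else 5) + 3

    def initial(self) -> np.ndarray:
        return np.zeros(self.n_params)

    def build(self, theta: np.ndarray) -> NucRateModel:
        if self.kind == "HKY85":
            return hky85(float(np.exp(theta[0])), _softmax_freqs(theta[1:4], 4))
        rates = np.concatenate([[1.0], np.exp(theta[:5])])
        return rev(rates, _softmax_freqs(theta[5:8], 4))


@dataclass(frozen=True)
class PairFamily:
    """Reversible no-double-substitution doublet family.

    ``product_pi`` constrains doublet frequencies to products of nucleotide
    frequencies (3 free parameters instead of n_states - 1).
    """

    state_space: int  # 16 | 7
    product_pi: bool = False

    @property
    def n_exch(self) -> int:
        return n_exchangeabilities(self.state_space)

    @property
    def n_params(self) -> int:
        nfree = 3 if self.product_pi else self.state_space - 1
        return (self.n_exch - 1) + nfree

    def initial(self) -> np.ndarray:
        return np.zeros(self.n_params)

    def build(self, theta: np.ndarray) -> PairRateModel:
        ne = self.n_exch - 1
        exch = np.concatenate([[1.0], np.exp(theta[:ne])])
        w = theta[ne:]
        if self.product_pi:
            freqs = _pair_freqs_from_nuc(_softmax_freqs(w, 4), self.state_space)
        else:
            freqs = _softmax_freqs(w, self.state_space)
        return make_pair_model(self.state_space, freqs, exch)


@dataclass(frozen=True)
class ModelFamily:
    """A mixed (nucleotide + doublet) or DNA-only candidate."""

    name: str
    nuc: NucFamily
    pair: PairFamily | None = None

    @property
    def n_params(self) -> int:
        return self.nuc.n_params + (self.pair.n_params if self.pair else 0)

    def initial(self) -> np.ndarray:
        parts = [self.nuc.initial()]
        if self.pair:
            parts.append(self.pair.initial())
        return np.concatenate(parts)

    def build(self, theta: np.ndarray) -> tuple[NucRateModel, PairRateModel | None]:
        k = self.nuc.n_params
        nuc = self.nuc.build(theta[:k])
        pair = self.pair.build(theta[k:]) if self.pair else None
        return nuc, pair


#: Named candidate families; RNA16 (free pi) is the default doublet family.
FAMILIES: dict[str, ModelFamily] = {
    "HKY85": ModelFamily("HKY85", NucFamily("HKY85")),
    "REV": ModelFamily("REV", NucFamily("REV")),
    "HKY85+RNA16": ModelFamily("HKY85+RNA16", NucFamily("HKY85"), PairFamily(16)),
    "REV+RNA16": ModelFamily("REV+RNA16", NucFamily("REV"), PairFamily(16)),
    "HKY85+RNA16P": ModelFamily(
        "HKY85+RNA16P", NucFamily("HKY85"), PairFamily(16, product_pi=True)
    ),
    "HKY85+RNA7": ModelFamily("HKY85+RNA7", NucFamily("HKY85"), PairFamily(7)),
    "HKY85+RNA7P": ModelFamily(
        "HKY85+RNA7P", NucFamily("HKY85"), PairFamily(7, product_pi=True)
    ),
}


def get_family(name: str | ModelFamily) -> ModelFamily:
    if isinstance(name, ModelFamily):
        return name
    try:
        return FAMILIES[name]
    except KeyError:
        raise ValueError(
            f"unknown model family {name!r}; known: {sorted(FAMILIES)}"
        ) from None


# ---------------------------------------------------------------------------
# ML fitting and AICc selection
# ---------------------------------------------------------------------------

@dataclass
class FittedModel:
    family: str
    nuc_model: NucRateModel | None
    pair_model: PairRateModel | None
    tree: TreeNode
    logL: float
    n_params: int
    n_sites: int
    aicc: float
    converged: bool
    message: str = ""


def aicc(logL: float, k: int, n: int) -> float:
    """Small-sample Akaike information criterion."""
    if n - k - 1 <= 0:
        return np.inf
    return -2.0 * logL + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def fit_ml(
    matrix: SpeciesMatrix,
    partition: StructurePartition,
    family: str | ModelFamily,
    tree: TreeNode | None = None,
    optimize_branch_lengths: bool = False,
    maxiter: int = 500,
    n_starts: int = 1,
    seed: int = 1,
    ridge: float = 0.01,
) -> FittedModel:
    """Maximize the pruning likelihood over model parameters.

    Branch lengths default to the NJ estimates (fixed); set
    ``optimize_branch_lengths`` to fit them jointly.  Multi-start jitter is
    seeded, so fits are deterministic.  Non-convergence is flagged on the
    result, not raised.

    ``ridge`` adds a weak quadratic penalty on the transformed model
    parameters (not branch lengths), anchoring exchangeabilities that the data
    leave unidentified at 1 instead of letting them drift to the bounds; its
    effect on well-identified parameters is negligible.  The reported ``logL``
    is the unpenalized log-likelihood at the optimum.
    """
    family = get_family(family)
    if tree is None:
        tree = build_nj_tree(matrix)
    tree = tree.copy()
    enc = encode_doublets(matrix, partition)
    _check_taxa(tree, enc.taxa)
    taxa = enc.taxa

    if family.pair is None:
        nuc_pats = compress_patterns(encode_nucleotides(matrix))
        pair_pats = None
    else:
        nuc_pats = (
            compress_patterns(enc.unpaired) if enc.unpaired.shape[1] else None
        )
        codes = enc.paired
        if family.pair.state_space == 7:
            codes = np.vectorize(doublet_to_7state)(codes)
        pair_pats = compress_patterns(codes) if codes.shape[1] else None

    bl0 = np.clip(get_branch_lengths(tree), 1e-6, None)
    n_model = family.n_params

    def loglik(theta: np.ndarray) -> float:
        try:
            nuc, pair = family.build(theta[:n_model])
        except (ValueError, FloatingPointError):
            return -np.inf
        if optimize_branch_lengths:
            set_branch_lengths(tree, np.exp(theta[n_model:]))
        ll = 0.0
        if nuc_pats is not None:
            ll += _pruned_patterns(tree, taxa, *nuc_pats, nuc.Q, nuc.freqs)
        if pair_pats is not None and pair is not None:
            ll += _pruned_patterns(tree, taxa, *pair_pats, pair.Q, pair.freqs)
        return ll

    def objective(theta: np.ndarray) -> float:
        ll = loglik(theta)
        if not np.isfinite(ll):
            return 1e12
        return -ll + ridge * float(np.sum(theta[:n_model] ** 2))

    theta0 = family.initial()
    if optimize_branch_lengths:
        theta0 = np.concatenate([theta0, np.log(bl0)])
    bounds = [(-15.0, 15.0)] * len(theta0)

    rng = np.random.default_rng(seed)
    best = None
    for s in range(n_starts):
        start = theta0 if s == 0 else theta0 + rng.normal(0.0, 0.5, len(theta0))
        res = minimize(
            objective,
            start,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": maxiter, "ftol": 1e-10},
        )
        if best is None or res.fun < best.fun:
            best = res
    nuc, pair = family.build(best.x[:n_model])
    if optimize_branch_lengths:
        set_branch_lengths(tree, np.exp(best.x[n_model:]))
    logL = float(loglik(best.x))
    k = len(best.x)
    n = partition.n_sites
    return FittedModel(
        family=family.name,
        nuc_model=nuc,
        pair_model=pair,
        tree=tree,
        logL=logL,
        n_params=k,
        n_sites=n,
        aicc=aicc(logL, k, n),
        converged=bool(best.success),
        message=str(best.message),
    )


def select_model(
    matrix: SpeciesMatrix,
    partition: StructurePartition,
    candidates: Sequence[str | ModelFamily],
    tree: TreeNode | None = None,
    **fit_kwargs,
) -> tuple[FittedModel, pd.DataFrame]:
    """Fit every candidate and rank by AICc; returns (best fit, ranking table)."""
    if not candidates:
        raise ValueError("need at least one candidate family")
    if tree is None:
        tree = build_nj_tree(matrix)
    fits: list[FittedModel] = []
    errors: list[str] = []
    for cand in candidates:
        try:
            fits.append(fit_ml(matrix, partition, cand, tree=tree, **fit_kwargs))
        except Exception as err:  # noqa: BLE001 - per-candidate isolation
            errors.append(f"{cand}: {err}")
    if not fits:
        raise RuntimeError("all model fits failed: " + "; ".join(errors))
    fits.sort(key=lambda f: f.aicc)
    table = pd.DataFrame(
        {
            "family": [f.family for f in fits],
            "logL": [f.logL for f in fits],
            "k": [f.n_params for f in fits],
            "n_sites": [f.n_sites for f in fits],
            "AICc": [f.aicc for f in fits],
            "converged": [f.converged for f in fits],
        }
    )
    table["delta_AICc"] = table["AICc"] - table["AICc"].min()
    return fits[0], table
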