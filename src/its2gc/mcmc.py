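"""Metropolis-Hastings sampling of substitution-model parameters.

The tree (topology and branch lengths) is held fixed; the chain moves over the
same transformed coordinates used by the ML optimizer (log exchangeabilities,
log kappa, softmax frequency weights).  The prior is iid Normal(0, prior_scale)
on those coordinates, which gives a proper prior-only mode for validation.

Equilibrium is declared by a doubling rule: the run is repeated with twice the
iterations and the chain is considered converged when every posterior-mean
parameter changes by less than 1% relative (absolute for means near zero).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

from .alphabet import doublet_to_7state
from .io_seqstruct import SpeciesMatrix
from .likelihood import (
    ModelFamily,
    _check_taxa,
    _pruned_patterns,
    compress_patterns,
    get_family,
)
from .structure import StructurePartition, encode_doublets


@dataclass
class McmcResult:
    samples: pd.DataFrame  # one row per retained draw, columns theta_*
    acceptance_rate: float
    posterior_mean: np.ndarray
    converged: bool | None
    warnings: list[str] = field(default_factory=list)

    def mean_models(self, family: ModelFamily):
        """Models built from the posterior-mean parameters."""
        return family.build(self.posterior_mean)


def _run_chain(loglik, logprior, theta0, n_iter, thin, burn_in_fraction, rng):
    theta = theta0.copy()
    lp = loglik(theta) + logprior(theta)
    n_burn = int(n_iter * burn_in_fraction)
    step = 0.1
    accepted = 0
    proposed = 0
    draws = []
    for it in range(n_iter):
        prop = theta + rng.normal(0.0, step, len(theta))
        lp_prop = loglik(prop) + logprior(prop)
        proposed += 1
        if np.log(rng.random()) < lp_prop - lp:
            theta, lp = prop, lp_prop
            accepted += 1
        # Robbins-Monro style step adaptation during burn-in, frozen after
        if it < n_burn and (it + 1) % 50 == 0:
            rate = accepted / proposed
            step *= np.exp(0.5 * (rate - 0.3))
            step = float(np.clip(step, 1e-4, 5.0))
            accepted = 0
            proposed = 0
        if it >= n_burn and (it - n_burn) % thin == 0:
            draws.append(theta.copy())
    rate = accepted / max(proposed, 1)
    return np.array(draws), rate


def mcmc_sample(
    matrix: SpeciesMatrix,
    partition: StructurePartition,
    family: str | ModelFamily,
    tree: TreeNode,
    n_iter: int = 20000,
    thin: int = 10,
    burn_in_fraction: float = 0.3,
    seed: int = 0,
    prior_scale: float = 2.0,
    likelihood_on: bool = True,
    check_convergence: bool = False,
) -> McmcResult:
    """Posterior samples of model parameters with the tree fixed.

    ``likelihood_on=False`` samples the prior alone (validation mode).  With
    ``check_convergence`` the run is repeated at 2x iterations and compared.
    """
    if n_iter < 10 * thin:
        raise ValueError("n_iter must be at least 10 * thin")
    family = get_family(family)
    enc = encode_doublets(matrix, partition)
    _check_taxa(tree, enc.taxa)
    taxa = enc.taxa
    nuc_pats = compress_patterns(enc.unpaired) if enc.unpaired.shape[1] else None
    pair_pats = None
    if family.pair is not None and enc.paired.shape[1]:
        codes = enc.paired
        if family.pair.state_space == 7:
            codes = np.vectorize(doublet_to_7state)(codes)
        pair_pats = compress_patterns(codes)
    elif family.pair is None:
        from .likelihood import encode_nucleotides

        nuc_pats = compress_patterns(encode_nucleotides(matrix))

    def loglik(theta: np.ndarray) -> float:
        if not likelihood_on:
            return 0.0
        try:
            nuc, pair = family.build(theta)
        except ValueError:
            return -np.inf
        ll = 0.0
        if nuc_pats is not None:
            ll += _pruned_patterns(tree, taxa, *nuc_pats, nuc.Q, nuc.freqs)
        if pair_pats is not None and pair is not None:
            ll += _pruned_patterns(tree, taxa, *pair_pats, pair.Q, pair.freqs)
        return ll if np.isfinite(ll) else -np.inf

    def logprior(theta: np.ndarray) -> float:
        return float(-0.5 * np.sum((theta / prior_scale) ** 2))

    def run(n: int, seed_: int):
        rng = np.random.default_rng(seed_)
        return _run_chain(
            loglik, logprior, family.initial(), n, thin, burn_in_fraction, rng
        )

    draws, rate = run(n_iter, seed)
    warnings = []
    if not 0.05 <= rate <= 0.8:
        warnings.append(f"acceptance rate {rate:.3f} outside [0.05, 0.8]")
    mean = draws.mean(axis=0)
    converged = None
    if check_convergence:
        # doubling rule: equilibrium iff doubling the run leaves every
        # posterior-mean parameter within 1% relative (floored near zero)
        draws2, _ = run(2 * n_iter, seed + 1)
        mean2 = draws2.mean(axis=0)
        rel = np.abs(mean2 - mean) / np.maximum(np.abs(mean2), 0.1)
        converged = bool(np.all(rel < 0.01))
        mean = mean2
    cols = [f"theta_{i}" for i in range(draws.shape[1])]
    return McmcResult(
        samples=pd.DataFrame(draws, columns=cols),
        acceptance_rate=rate,
        posterior_mean=mean,
        converged=converged,
        warnings=warnings,
    )
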