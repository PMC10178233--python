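"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's pruning code path: likelihoods are
computed by explicit enumeration over all internal-node state assignments.
"""

from itertools import product

import numpy as np
from scipy.linalg import expm


def enumeration_loglik(tree, codes, Q, freqs):
    """Brute-force log-likelihood by summing over internal-node states.

    ``codes`` maps tip name -> integer array of site codes (-1 = missing).
    Only feasible for very small trees and state spaces.
    """
    n_states = len(freqs)
    nodes = list(tree.postorder())
    internals = [n for n in nodes if not n.is_tip()]
    P = {
        id(n): expm(Q * (n.length or 0.0)) for n in nodes if not n.is_root()
    }
    n_sites = len(next(iter(codes.values())))
    total = 0.0
    for site in range(n_sites):
        lik = 0.0
        for assignment in product(range(n_states), repeat=len(internals)):
            state_of = {id(n): s for n, s in zip(internals, assignment)}
            term = freqs[state_of[id(tree)]]
            for n in nodes:
                if n.is_root():
                    continue
                parent_state = state_of[id(n.parent)]
                if n.is_tip():
                    obs = codes[n.name][site]
                    if obs == -1:
                        term *= 1.0  # marginalize: sum over tip states = row sum = 1
                    else:
                        term *= P[id(n)][parent_state, obs]
                else:
                    term *= P[id(n)][parent_state, state_of[id(n)]]
            lik += term
        total += np.log(lik)
    return total
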