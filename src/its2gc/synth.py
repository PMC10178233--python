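"""Synthetic ITS2 allele-family generator.

Emulates the statistical structure the analysis assumes: a four-stem
('four-fingered hand') consensus structure, GC-rich paired regions, a Yule
species tree, structure-constrained substitution (HKY85 on unpaired columns,
a 16-state no-double-substitution doublet model on stem pairs), a tunable
GC-biased gene conversion multiplier, and incomplete within-species
homogenization of allele copies.

gBGC and homogenization are coupled through one parameter: a species with
homogenization h experiences effective bias lambda_eff = 1 + (lambda - 1) * h,
encoding that gene conversion (which homogenizes) is the same event that
converts mismatches with a GC bias.  Alleles of a species diverge on a star
tree of depth (1 - h) * allele_divergence, so h -> 1 gives identical alleles
(K = 0) and maximal gBGC exposure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .alphabet import DOUBLETS, NUC
from .io_seqstruct import SeqStructRecord, SpeciesMatrix, write_seqstruct
from .rates import (
    gbgc_bias,
    hky85,
    make_pair_model,
    n_exchangeabilities,
    stationary_distribution,
    transition_probabilities,
)
from .structure import partition_columns

#: Enrichment of canonical over mismatch doublets in the stem equilibrium;
#: with the default GC-rich base frequencies this puts paired-region GC near
#: 70% at lambda=1 and ~85% at lambda=3.
WC_BONUS = 20.0
WOBBLE_BONUS = 8.0


@dataclass
class SynthConfig:
    """Study conditions of the generator (defaults emulate the target system:
    29-ish allele families, ITS2-length alignments, ~46% paired columns,
    GC-rich stems, within-species allele heterogeneity)."""

    n_species: int = 12
    alleles_per_species: int | tuple[int, int] = (2, 13)
    seq_length: int = 260
    paired_fraction: float = 0.46
    n_stems: int = 4
    species_tree_depth: float = 0.3
    homogenization: float | Sequence[float] = 0.7
    allele_divergence: float = 0.1
    gbgc_strength: float = 3.0
    kappa: float = 4.0
    base_freqs: tuple[float, float, float, float] = (0.18, 0.32, 0.32, 0.18)
    concerted_branch: float = 0.5
    copy_count_mean: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.seq_length < 40:
            raise ValueError("seq_length must be >= 40")
        if not 0.0 <= self.paired_fraction <= 1.0:
            raise ValueError("paired_fraction must be in [0, 1]")
        if self.gbgc_strength < 0:
            raise ValueError("gbgc_strength must be >= 0")
        h = np.atleast_1d(np.asarray(self.homogenization, dtype=float))
        if np.any((h < 0) | (h > 1)):
            raise ValueError("homogenization must be in [0, 1]")


def simulate_structure(
    seq_length: int,
    paired_fraction: float,
    n_stems: int = 4,
    seed: int = 0,
) -> str:
    """A nested dot-bracket with ``n_stems`` stems separated by unpaired linkers.

    The realized number of paired columns is within 2 of
    ``paired_fraction * seq_length``; deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    n_pairs = int(round(paired_fraction * seq_length / 2.0))
    if n_pairs == 0:
        return "." * seq_length
    n_unpaired = seq_length - 2 * n_pairs
    min_loop = 3
    if n_unpaired < min_loop * n_stems:
        raise ValueError(
            f"infeasible geometry: {n_unpaired} unpaired columns cannot host "
            f"{n_stems} loops of >= {min_loop}"
        )
    base, extra = divmod(n_pairs, n_stems)
    stem_sizes = [base + (1 if k < extra else 0) for k in range(n_stems)]
    if min(stem_sizes) == 0:
        raise ValueError("infeasible geometry: more stems than base pairs")
    # distribute leftover unpaired columns over loops and the n_stems+1 linkers
    slots = 2 * n_stems + 1  # linker, (stem, loop)*, ..., final linker
    leftover = n_unpaired - min_loop * n_stems
    add = rng.multinomial(leftover, np.full(slots, 1.0 / slots))
    parts: list[str] = []
    for k in range(n_stems):
        parts.append("." * add[2 * k])  # linker before stem k
        loop = min_loop + add[2 * k + 1]
        parts.append("(" * stem_sizes[k] + "." * loop + ")" * stem_sizes[k])
    parts.append("." * add[-1])
    structure = "".join(parts)
    assert len(structure) == seq_length
    return structure


def _default_pair_freqs(base_freqs: np.ndarray) -> np.ndarray:
    """Stem doublet frequencies: nucleotide products boosted for WC/wobble pairs."""
    p = np.asarray(base_freqs, dtype=float)
    prod = np.outer(p, p).ravel()
    bonus = np.ones(16)
    for d, w in (("GC", WC_BONUS), ("CG", WC_BONUS), ("AU", WC_BONUS),
                 ("UA", WC_BONUS), ("GU", WOBBLE_BONUS), ("UG", WOBBLE_BONUS)):
        bonus[DOUBLETS.index(d)] = w
    freqs = prod * bonus
    return freqs / freqs.sum()


def _sample_categorical(rng: np.random.Generator, probs: np.ndarray, n: int) -> np.ndarray:
    cum = np.cumsum(probs)
    cum[-1] = 1.0
    return np.searchsorted(cum, rng.random(n), side="right")


def _evolve(rng: np.random.Generator, states: np.ndarray, P: np.ndarray) -> np.ndarray:
    cum = np.cumsum(P, axis=1)
    cum[:, -1] = 1.0
    u = rng.random(len(states))
    return np.array(
        [np.searchsorted(cum[s], x, side="right") for s, x in zip(states, u)],
        dtype=np.int64,
    )


@dataclass
class _Node:
    children: list["_Node"] = field(default_factory=list)
    length: float = 0.0
    name: str | None = None


def _yule_tree(n: int, depth: float, rng: np.random.Generator) -> tuple[_Node, list[_Node]]:
    """Ultrametric Yule tree with root-to-tip depth scaled to ``depth``."""
    root = _Node()
    if n == 1:
        root.name = "sp01"
        return root, [root]
    # forward simulation: split a random active lineage at exponential waits
    active = [(root, 0.0)]
    t = 0.0
    events: list[tuple[_Node, float]] = []
    while len(active) < n:
        t += rng.exponential(1.0 / len(active))
        k = int(rng.integers(len(active)))
        node, born = active.pop(k)
        node.length = t - born if node is not root else 0.0
        events.append((node, t))
        a, b = _Node(), _Node()
        node.children = [a, b]
        active += [(a, t), (b, t)]
    t_end = t + rng.exponential(1.0 / n)
    tips = []
    for i, (node, born) in enumerate(active):
        node.length = t_end - born
        node.name = f"sp{i + 1:02d}"
        tips.append(node)
    # rescale so root-to-tip distance equals depth
    scale = depth / t_end if t_end > 0 else 1.0
    stack = [root]
    while stack:
        nd = stack.pop()
        nd.length *= scale
        stack.extend(nd.children)
    tips.sort(key=lambda nd: nd.name)
    return root, tips


def _newick(node: _Node) -> str:
    if not node.children:
        return f"{node.name}:{node.length:.6f}"
    inner = ",".join(_newick(c) for c in node.children)
    return f"({inner}):{node.length:.6f}"


def simulate_family(config: SynthConfig) -> tuple[list[SpeciesMatrix], dict]:
    """Generate per-species allele matrices plus a ground-truth record.

    Returns ``(matrices, truth)`` where truth holds the bias parameters, the
    species tree (newick), the shared structure and per-species realized GC.
    """
    rng = np.random.default_rng(config.seed)
    structure = simulate_structure(
        config.seq_length, config.paired_fraction, config.n_stems,
        seed=int(rng.integers(2**31 - 1)),
    )
    partition = partition_columns(structure, config.seq_length)
    n_pairs, n_unp = len(partition.paired), len(partition.unpaired)

    nuc = hky85(config.kappa, np.asarray(config.base_freqs))
    pair0 = make_pair_model(
        16, _default_pair_freqs(np.asarray(config.base_freqs)),
        np.ones(n_exchangeabilities(16)),
    )
    h = np.broadcast_to(
        np.atleast_1d(np.asarray(config.homogenization, dtype=float)),
        (config.n_species,),
    ).copy()
    lam_eff = 1.0 + (config.gbgc_strength - 1.0) * h
    pair_models = [gbgc_bias(pair0, lam) for lam in lam_eff]
    lam_bar = float(np.mean(lam_eff))
    pair_bar = gbgc_bias(pair0, lam_bar)

    root, tips = _yule_tree(config.n_species, config.species_tree_depth, rng)

    # root sequence at the (mean-bias) stationary state: a long run-in
    pi_bar = stationary_distribution(pair_bar.Q)
    root_paired = _sample_categorical(rng, pi_bar, n_pairs)
    root_unpaired = _sample_categorical(rng, nuc.freqs, n_unp)

    # evolve down the species tree; internal branches use the mean bias,
    # each terminal branch the species' own lambda_eff
    tip_states: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    tip_index = {tip.name: i for i, tip in enumerate(tips)}

    def descend(node: _Node, paired: np.ndarray, unpaired: np.ndarray) -> None:
        for child in node.children:
            Q_pair = (
                pair_models[tip_index[child.name]].Q
                if child.name is not None
                else pair_bar.Q
            )
            cp = _evolve(rng, paired, transition_probabilities(Q_pair, child.length))
            cu = _evolve(rng, unpaired, transition_probabilities(nuc.Q, child.length))
            if child.name is not None:
                tip_states[child.name] = (cp, cu)
            else:
                descend(child, cp, cu)
        if not node.children and node.name is not None:  # single-species tree
            tip_states[node.name] = (paired, unpaired)

    descend(root, root_paired, root_unpaired)

    lo, hi = (
        (config.alleles_per_species, config.alleles_per_species)
        if isinstance(config.alleles_per_species, int)
        else config.alleles_per_species
    )
    matrices: list[SpeciesMatrix] = []
    truth_species = {}
    for i, tip in enumerate(tips):
        name = tip.name
        Q_s = pair_models[i].Q
        sp_paired, sp_unpaired = tip_states[name]
        # concerted-evolution branch under the species' own gBGC bias
        if config.concerted_branch > 0:
            sp_paired = _evolve(
                rng, sp_paired, transition_probabilities(Q_s, config.concerted_branch)
            )
            sp_unpaired = _evolve(
                rng,
                sp_unpaired,
                transition_probabilities(nuc.Q, config.concerted_branch),
            )
        n_alleles = int(rng.integers(lo, hi + 1)) if hi > lo else lo
        depth = (1.0 - h[i]) * config.allele_divergence
        P_pair = transition_probabilities(Q_s, depth)
        P_nuc = transition_probabilities(nuc.Q, depth)
        records = []
        for a in range(n_alleles):
            ap = _evolve(rng, sp_paired, P_pair) if depth > 0 else sp_paired
            au = _evolve(rng, sp_unpaired, P_nuc) if depth > 0 else sp_unpaired
            chars = [""] * config.seq_length
            for s, (x, y) in enumerate(partition.paired):
                d = DOUBLETS[ap[s]]
                chars[x], chars[y] = d[0], d[1]
            for s, c in enumerate(partition.unpaired):
                chars[c] = NUC[au[s]]
            records.append(
                SeqStructRecord(
                    id=f"{name}_allele{a + 1:02d}",
                    sequence="".join(chars),
                    structure=structure,
                    copy_count=int(rng.geometric(1.0 / config.copy_count_mean)),
                )
            )
        matrices.append(
            SpeciesMatrix(species_name=name, records=records, consensus_structure=structure)
        )
        gc_pair_true = (
            float(np.mean([sum(b in "GC" for b in DOUBLETS[s]) / 2 for s in sp_paired]))
            if len(sp_paired)
            else float("nan")
        )
        gc_unp_true = (
            float(np.mean([NUC[s] in "GC" for s in sp_unpaired]))
            if len(sp_unpaired)
            else float("nan")
        )
        truth_species[name] = {
            "h": float(h[i]),
            "lambda_eff": float(lam_eff[i]),
            "n_alleles": n_alleles,
            "gc_paired_founder": 100.0 * gc_pair_true,
            "gc_unpaired_founder": 100.0 * gc_unp_true,
        }
    truth = {
        "seed": config.seed,
        "gbgc_strength": config.gbgc_strength,
        "kappa": config.kappa,
        "structure": structure,
        "tree": _newick(root) + ";",
        "species": truth_species,
    }
    return matrices, truth


def write_family(
    matrices: Sequence[SpeciesMatrix], truth: dict, outdir: str | Path
) -> None:
    """Write one Vienna-triplet file per species plus a truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for m in matrices:
        write_seqstruct(m.records, outdir / f"{m.species_name}.vienna")
    (outdir / "truth.json").write_text(json.dumps(truth, indent=2))


def read_family(indir: str | Path) -> list[SpeciesMatrix]:
    """Read back a directory of per-species Vienna-triplet files."""
    from .io_seqstruct import read_seqstruct

    indir = Path(indir)
    matrices = []
    for path in sorted(indir.glob("*.vienna")):
        recs = read_seqstruct(path)
        matrices.append(SpeciesMatrix(species_name=path.stem, records=recs))
    if not matrices:
        raise FileNotFoundError(f"no .vienna files under {indir}")
    return matrices
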