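import io

import numpy as np
import pytest
from skbio import TreeNode

from its2gc.alphabet import DOUBLET_INDEX
from its2gc.io_seqstruct import SpeciesMatrix
from its2gc.likelihood import (
    FAMILIES,
    aicc,
    fit_ml,
    log_likelihood,
    pruned_loglik,
    select_model,
)
from its2gc.rates import (
    assert_valid_rate_model,
    gbgc_bias,
    hky85,
    make_pair_model,
    n_exchangeabilities,
    rev,
    transition_probabilities,
)
from its2gc.structure import partition_columns
from its2gc.trees import build_nj_tree, jc_distance

from conftest import make_records
from oracles import enumeration_loglik


def random_nuc_model(rng):
    freqs = rng.dirichlet(np.ones(4) * 5)
    if rng.random() < 0.5:
        return hky85(float(rng.uniform(0.5, 8)), freqs)
    return rev(rng.uniform(0.2, 3.0, size=6), freqs)


def random_pair_model(rng, n_states=16):
    freqs = rng.dirichlet(np.ones(n_states) * 5)
    exch = rng.uniform(0.2, 3.0, size=n_exchangeabilities(n_states))
    return make_pair_model(n_states, freqs, exch)


class TestNjTree:
    def test_two_taxa_single_edge_of_corrected_distance(self):
        a = "A" * 90 + "G" * 10
        b = "A" * 100
        recs = make_records([a, b], "." * 100)
        tree = build_nj_tree(recs)
        tips = list(tree.tips())
        d = sum(t.length for t in tips)
        assert d == pytest.approx(jc_distance(0.1))

    def test_identical_sequences_give_zero_branch_lengths(self):
        recs = make_records(["GCAU" * 5] * 4, "." * 20)
        tree = build_nj_tree(recs)
        assert all((n.length or 0.0) == 0.0 for n in tree.traverse() if not n.is_root())

    def test_recovers_path_lengths_on_nearly_additive_data(self):
        # disjoint mutation blocks per edge -> additive hamming distances;
        # p is small so the JC correction is near-linear and path lengths on
        # the NJ tree match the corrected pairwise distances closely
        L = 2000
        base = ["A"] * L
        blocks = {"t1": (0, 6), "t2": (10, 14), "t3": (20, 28), "t4": (30, 35)}
        shared_12 = (40, 47)  # internal edge separating {t1,t2} from {t3,t4}
        seqs = {}
        for name, (lo, hi) in blocks.items():
            s = base.copy()
            for k in range(lo, hi):
                s[k] = "G"
            if name in ("t1", "t2"):
                for k in range(*shared_12):
                    s[k] = "C"
            seqs[name] = "".join(s)
        recs = make_records([seqs[f"t{i}"] for i in (1, 2, 3, 4)], "." * L)
        for rec, name in zip(recs, ("t1", "t2", "t3", "t4")):
            rec.id = name
        tree = build_nj_tree(recs)
        tips = {t.name: t for t in tree.tips()}
        for x, y, hamming in [("t1", "t2", 10), ("t1", "t3", 21), ("t3", "t4", 13)]:
            want = jc_distance(hamming / L)
            got = tips[x].distance(tips[y])
            assert got == pytest.approx(want, rel=0.02)

    def test_saturated_distance_names_the_pair(self):
        recs = make_records(["AAAA", "CCCC", "AAAC"], "....")
        with pytest.raises(ValueError, match="a1.*a2|saturated"):
            build_nj_tree(recs)


class TestRateMatrices:
    def test_invariants_hold_for_random_models(self, rng):
        for _ in range(25):
            assert_valid_rate_model(random_nuc_model(rng))
            assert_valid_rate_model(random_pair_model(rng, 16))
            assert_valid_rate_model(random_pair_model(rng, 7))

    def test_uniform_model_has_equal_allowed_rates(self):
        m = make_pair_model(16, np.full(16, 1 / 16), np.ones(48))
        off = m.Q[~np.eye(16, dtype=bool)]
        positive = off[off > 0]
        assert np.allclose(positive, positive[0])
        assert np.allclose(m.Q.sum(axis=1), 0.0)

    def test_double_substitution_rate_is_zero(self):
        m = random_pair_model(np.random.default_rng(0))
        assert m.Q[DOUBLET_INDEX["AU"], DOUBLET_INDEX["GC"]] == 0.0
        assert m.Q[DOUBLET_INDEX["UA"], DOUBLET_INDEX["CG"]] == 0.0

    def test_detailed_balance_for_random_parameters(self, rng):
        for _ in range(10):
            m = random_pair_model(rng)
            flux = m.freqs[:, None] * m.Q
            assert np.allclose(flux, flux.T, atol=1e-12)

    def test_nonpositive_frequency_rejected(self):
        freqs = np.full(16, 1 / 16)
        freqs[0] = 0.0
        freqs[1] += 1 / 16
        with pytest.raises(ValueError, match="positive"):
            make_pair_model(16, freqs, np.ones(48))

    def test_gbgc_bias_preserves_invariants_and_shifts_gc_mass(self, rng):
        m = random_pair_model(rng)
        b = gbgc_bias(m, 3.0)
        assert_valid_rate_model(b)
        gc_idx = [DOUBLET_INDEX["GC"], DOUBLET_INDEX["CG"]]
        assert b.freqs[gc_idx].sum() > m.freqs[gc_idx].sum()


class TestTransitionProbabilities:
    def test_zero_time_is_identity(self, rng):
        m = random_nuc_model(rng)
        assert np.allclose(transition_probabilities(m, 0.0), np.eye(4))

    def test_negative_time_rejected(self, rng):
        with pytest.raises(ValueError):
            transition_probabilities(random_nuc_model(rng), -0.1)

    def test_long_time_limit_is_stationary(self, rng):
        m = random_pair_model(rng)
        P = transition_probabilities(m, 1e4)
        assert np.max(np.abs(P - m.freqs[None, :])) < 1e-6

    def test_semigroup_property(self, rng):
        m = random_nuc_model(rng)
        t1, t2 = rng.uniform(0.05, 1.0, 2)
        P = transition_probabilities(m, t1 + t2)
        assert np.allclose(
            P, transition_probabilities(m, t1) @ transition_probabilities(m, t2),
            atol=1e-10,
        )


def read_tree(newick):
    return TreeNode.read(io.StringIO(newick))


class TestLikelihood:
    def test_single_taxon_single_column_is_log_pi(self):
        m = hky85(2.0, [0.1, 0.2, 0.3, 0.4])
        tree = read_tree("(a:0.0);")
        ll = pruned_loglik(tree, ["a"], np.array([[0]]), m.Q, m.freqs)
        assert ll == pytest.approx(np.log(0.1))

    def test_two_taxa_paired_site_matches_direct_sum(self, rng):
        m = random_pair_model(rng)
        t1, t2 = 0.3, 0.7
        tree = read_tree(f"(a:{t1},b:{t2});")
        obs1, obs2 = DOUBLET_INDEX["GC"], DOUBLET_INDEX["GU"]
        data = np.array([[obs1], [obs2]])
        ll = pruned_loglik(tree, ["a", "b"], data, m.Q, m.freqs)
        P1 = transition_probabilities(m, t1)
        P2 = transition_probabilities(m, t2)
        direct = sum(
            m.freqs[i] * P1[i, obs1] * P2[i, obs2] for i in range(16)
        )
        assert ll == pytest.approx(np.log(direct), abs=1e-10)

    def test_pruning_matches_enumeration_with_missing_data(self, rng):
        m = random_nuc_model(rng)
        tree = read_tree("((a:0.2,b:0.4):0.1,(c:0.3,d:0.5):0.2);")
        codes = {
            "a": np.array([0, 2, -1]),
            "b": np.array([1, 2, 3]),
            "c": np.array([0, -1, 3]),
            "d": np.array([2, 2, 0]),
        }
        data = np.vstack([codes[t] for t in ("a", "b", "c", "d")])
        ll = pruned_loglik(tree, ["a", "b", "c", "d"], data, m.Q, m.freqs)
        assert ll == pytest.approx(enumeration_loglik(tree, codes, m.Q, m.freqs),
                                   abs=1e-8)

    def test_invariant_under_rerooting_of_reversible_model(self, rng):
        m = random_nuc_model(rng)
        newick = "((a:0.2,b:0.4):0.1,(c:0.3,d:0.5):0.2);"
        tree = read_tree(newick)
        data = np.array([[0, 2, 1], [1, 2, 3], [0, 1, 3], [2, 2, 0]])
        taxa = ["a", "b", "c", "d"]
        ll = pruned_loglik(tree, taxa, data, m.Q, m.freqs)
        tree2 = read_tree(newick)
        target = next(t for t in tree2.tips() if t.name == "a").parent
        rerooted = tree2.root_at(target)
        ll2 = pruned_loglik(rerooted, taxa, data, m.Q, m.freqs)
        assert ll == pytest.approx(ll2, abs=1e-8)

    def test_mixed_likelihood_sums_partitions(self, small_matrix):
        part = partition_columns(small_matrix.records[0].structure, 10)
        tree = build_nj_tree(small_matrix)
        nuc = hky85(2.0, [0.25] * 4)
        pair = make_pair_model(16, np.full(16, 1 / 16), np.ones(48))
        ll = log_likelihood(small_matrix, part, nuc, pair, tree)
        assert np.isfinite(ll) and ll < 0

    def test_taxon_mismatch_rejected(self, small_matrix):
        part = partition_columns(small_matrix.records[0].structure, 10)
        tree = read_tree("(x:0.1,y:0.1);")
        with pytest.raises(ValueError, match="taxa"):
            log_likelihood(small_matrix, part, hky85(2.0, [0.25] * 4), None, tree)


class TestFitAndSelect:
    def test_identical_sequences_fit_without_crash(self):
        recs = make_records(["GCAUGCAU"] * 3, "((..))..")
        mat = SpeciesMatrix("s", recs)
        part = partition_columns("((..))..", 8)
        fit = fit_ml(mat, part, "HKY85", maxiter=50)
        assert np.isfinite(fit.logL)

    def test_multistart_logl_stability(self, small_matrix):
        part = partition_columns(small_matrix.records[0].structure, 10)
        fits = [
            fit_ml(small_matrix, part, "HKY85", maxiter=300, n_starts=1, seed=s)
            for s in range(5)
        ]
        best = [f.logL for f in fits]
        assert max(best) - min(best) < 1e-4

    def test_single_candidate_is_returned_as_best(self, small_matrix):
        part = partition_columns(small_matrix.records[0].structure, 10)
        best, table = select_model(small_matrix, part, ["HKY85"], maxiter=50)
        assert best.family == "HKY85" and len(table) == 1

    def test_aicc_formula_and_ranking_shift_invariance(self):
        # AICc = -2logL + 2k + 2k(k+1)/(n-k-1); a common shift of all logL
        # values leaves the ranking unchanged
        assert aicc(-100.0, 4, 50) == pytest.approx(200 + 8 + 2 * 4 * 5 / 45)
        lls = [-120.0, -100.0, -110.0]
        ks = [3, 8, 5]
        base = np.argsort([aicc(ll, k, 60) for ll, k in zip(lls, ks)])
        shifted = np.argsort([aicc(ll + 17.3, k, 60) for ll, k in zip(lls, ks)])
        assert np.array_equal(base, shifted)

    def test_simpler_nested_model_wins_on_its_own_data(self, rng):
        # data simulated under HKY85: REV should rarely beat it by AICc
        from its2gc.synth import SynthConfig, simulate_family
        from its2gc.structure import partition_columns as pc

        wins = 0
        n_rep = 10
        for rep in range(n_rep):
            cfg = SynthConfig(
                n_species=6, alleles_per_species=1, seq_length=400,
                paired_fraction=0.0, n_stems=0, homogenization=1.0,
                gbgc_strength=1.0, kappa=5.0, seed=100 + rep,
            )
            mats, truth = simulate_family(cfg)
            recs = [m.records[0] for m in mats]
            for r, m in zip(recs, mats):
                r.id = m.species_name
            fam = SpeciesMatrix("fam", recs)
            part = pc(truth["structure"], cfg.seq_length)
            best, _ = select_model(fam, part, ["HKY85", "REV"], maxiter=150)
            wins += best.family == "HKY85"
        assert wins >= 8

    def test_pair_correlation_favors_mixed_over_dna_only(self):
        # strong within-pair correlation (doublet process on stems): the
        # mixed candidate must beat the DNA-only candidate by AICc
        from its2gc.synth import SynthConfig, simulate_family
        from its2gc.structure import partition_columns as pc

        cfg = SynthConfig(
            n_species=8, alleles_per_species=1, seq_length=400,
            homogenization=1.0, gbgc_strength=3.0, kappa=4.0, seed=11,
        )
        mats, truth = simulate_family(cfg)
        recs = [m.records[0] for m in mats]
        for r, m in zip(recs, mats):
            r.id = m.species_name
        fam = SpeciesMatrix("fam", recs)
        part = pc(truth["structure"], cfg.seq_length)
        best, table = select_model(
            fam, part, ["HKY85+RNA7", "HKY85"], maxiter=150
        )
        row = table.set_index("family")
        assert row.loc["HKY85+RNA7", "AICc"] < row.loc["HKY85", "AICc"]
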