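import numpy as np
import pytest

from its2gc.composition import (
    avg_nucleotide_differences,
    base_frequency_profile,
    gc_content,
    gc_homogeneity,
    shapiro_wilk,
    spearman_correlation,
)

from conftest import make_records


class TestGcContent:
    def test_all_gc(self):
        assert gc_content(make_records(["GGCC"], "....")) == 100.0

    def test_gap_excluded_from_denominator(self):
        assert gc_content(make_records(["GC-AU"], ".....")) == 50.0

    def test_unweighted_mean_over_alleles(self):
        recs = make_records(["GGGG", "AAAA"], "....", counts=[10, 1])
        assert gc_content(recs) == 50.0  # copy counts ignored

    def test_column_subset(self):
        recs = make_records(["GCAU"], "....")
        assert gc_content(recs, columns=[0, 1]) == 100.0
        assert gc_content(recs, columns=[2, 3]) == 0.0

    def test_all_gap_selection_is_an_error(self):
        recs = make_records(["GC--"], "....")
        with pytest.raises(ValueError, match="no countable bases"):
            gc_content(recs, columns=[2, 3])

    def test_invariant_under_reversal_and_strand_swap(self, rng):
        # single-record GC is unchanged by reversing the sequence or by the
        # complement-pair swap G<->C, A<->U
        for _ in range(10):
            seq = "".join(rng.choice(list("ACGU"), size=30))
            base = gc_content(make_records([seq], "." * 30))
            rev = gc_content(make_records([seq[::-1]], "." * 30))
            swap = seq.translate(str.maketrans("GCAU", "CGUA"))
            swapped = gc_content(make_records([swap], "." * 30))
            assert base == pytest.approx(rev) == pytest.approx(swapped)


class TestGcHomogeneity:
    def test_identical_alleles_have_zero_sd(self):
        assert gc_homogeneity(make_records(["GCAU", "GCAU"], "....")) == 0.0

    def test_two_alleles_80_and_82_percent(self):
        # GC 80% and 82% over 50 columns -> sample SD = sqrt(2)
        a = "G" * 40 + "A" * 10
        b = "G" * 41 + "A" * 9
        assert gc_homogeneity(make_records([a, b], "." * 50)) == pytest.approx(
            np.sqrt(2.0)
        )

    def test_matches_two_pass_oracle_on_random_input(self, rng):
        seqs = ["".join(rng.choice(list("ACGU"), size=40)) for _ in range(6)]
        recs = make_records(seqs, "." * 40)
        per_allele = [100.0 * sum(b in "GC" for b in s) / 40 for s in seqs]
        mean = sum(per_allele) / len(per_allele)
        sd = (sum((x - mean) ** 2 for x in per_allele) / (len(per_allele) - 1)) ** 0.5
        assert gc_homogeneity(recs) == pytest.approx(sd)

    def test_single_record_is_an_error(self):
        with pytest.raises(ValueError):
            gc_homogeneity(make_records(["GCAU"], "...."))


class TestK:
    def test_identical_sequences_give_zero(self):
        assert avg_nucleotide_differences(make_records(["GCAU", "GCAU"], "....")) == 0.0

    def test_three_allele_example(self):
        recs = make_records(["AAAA", "AAAU", "AAUU"], "....")
        assert avg_nucleotide_differences(recs) == pytest.approx((1 + 2 + 1) / 3)

    def test_invariant_under_record_permutation(self, rng):
        seqs = ["".join(rng.choice(list("ACGU"), size=20)) for _ in range(5)]
        k1 = avg_nucleotide_differences(make_records(seqs, "." * 20))
        k2 = avg_nucleotide_differences(make_records(seqs[::-1], "." * 20))
        assert k1 == pytest.approx(k2)

    def test_doubling_every_pairwise_difference_doubles_k(self):
        # constructed input: each pair differs at d positions vs 2d positions
        one = make_records(["AAAA", "AAAC", "AACA"], "....")
        two = make_records(["AAAAAAAA", "AAACAAAC", "AACAAACA"], "." * 8)
        assert avg_nucleotide_differences(two) == pytest.approx(
            2 * avg_nucleotide_differences(one)
        )

    def test_gap_positions_excluded_pairwise(self):
        recs = make_records(["GC-U", "GCAU"], "....")
        assert avg_nucleotide_differences(recs) == 0.0

    def test_fewer_than_two_records_is_an_error(self):
        with pytest.raises(ValueError):
            avg_nucleotide_differences(make_records(["GCAU"], "...."))


class TestSpearman:
    def test_monotone_increasing_is_one(self):
        rho, _ = spearman_correlation([1, 2, 3, 4, 5], [10, 20, 25, 30, 100])
        assert rho == pytest.approx(1.0)

    def test_textbook_four_point_example(self):
        rho, _ = spearman_correlation([1, 2, 3, 4], [1, 3, 2, 4])
        assert rho == pytest.approx(0.8)

    def test_constant_vector_is_an_error(self):
        with pytest.raises(ValueError, match="constant"):
            spearman_correlation([1, 1, 1], [1, 2, 3])

    def test_matches_rank_formula_on_tie_free_vectors(self, rng):
        for _ in range(10):
            x = rng.permutation(12).astype(float)
            y = rng.permutation(12).astype(float)
            rho, _ = spearman_correlation(x, y)
            rx = np.argsort(np.argsort(x))
            ry = np.argsort(np.argsort(y))
            d2 = np.sum((rx - ry) ** 2)
            n = len(x)
            assert rho == pytest.approx(1 - 6 * d2 / (n * (n**2 - 1)))


class TestShapiroWilk:
    def test_accepts_normal_samples(self, rng):
        hits = sum(
            shapiro_wilk(rng.normal(70, 2, size=29))[1] > 0.05 for _ in range(100)
        )
        assert hits >= 90

    def test_rejects_bimodal_samples(self, rng):
        hits = 0
        for _ in range(100)[:100]:
            x = np.concatenate([rng.normal(-6, 1, 15), rng.normal(6, 1, 15)])
            hits += shapiro_wilk(x)[1] < 0.05
        assert hits >= 90

    def test_constant_data_is_an_error(self):
        with pytest.raises(ValueError):
            shapiro_wilk([5.0] * 10)

    def test_sample_size_limits(self):
        with pytest.raises(ValueError):
            shapiro_wilk([1.0, 2.0])


class TestBaseFrequencyProfile:
    def test_identical_records_give_unit_frequencies(self):
        df = base_frequency_profile(make_records(["GCAU", "GCAU"], "...."))
        assert df.loc[0, "G"] == 1.0 and df.loc[1, "C"] == 1.0
        assert np.allclose(df[["A", "C", "G", "U"]].sum(axis=1), 1.0)

    def test_mixed_column(self):
        df = base_frequency_profile(make_records(["A", "A", "G"], "."))
        assert df.loc[0, "A"] == pytest.approx(2 / 3)
        assert df.loc[0, "G"] == pytest.approx(1 / 3)

    def test_rows_sum_to_one_on_random_input(self, rng):
        seqs = ["".join(rng.choice(list("ACGU-"), size=15)) for _ in range(8)]
        df = base_frequency_profile(make_records(seqs, "." * 15))
        sums = df[["A", "C", "G", "U"]].sum(axis=1)
        assert np.all((np.abs(sums - 1.0) < 1e-12) | (sums == 0.0))

    def test_gap_fraction_reported(self):
        df = base_frequency_profile(make_records(["A-", "AA"], ".."))
        assert df.loc[1, "gap"] == 0.5
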