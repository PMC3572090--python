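"""Diversity and neutrality statistics against independent oracles."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from isoscope import errors
from isoscope.datasets import SequenceDataset, SequenceRecord
from isoscope.stats import (
    collapse_haplotypes,
    ewens_log_pmf,
    fu_fs,
    fu_fs_statistic,
    haplotype_diversity,
    mismatch_and_raggedness,
    pairwise_differences,
    tajimas_d,
    theta_estimators,
)

import oracles
from conftest import make_sequence_dataset, make_str_dataset, random_sequence_dataset


class TestCollapseHaplotypes:
    def test_counts_within_one_population(self):
        ds = make_sequence_dataset({"p": ["ACGT"] * 3 + ["ACGA"] * 2})
        table = collapse_haplotypes(ds)
        assert table.n_haplotypes == 2
        assert sorted(table.counts[0]) == [2, 3]

    def test_identical_sequences_shared_across_populations(self):
        ds = make_sequence_dataset({"p1": ["ACGT"] * 4, "p2": ["ACGT"] * 2})
        table = collapse_haplotypes(ds)
        assert table.n_haplotypes == 1
        assert table.counts.tolist() == [[4], [2]]

    def test_ambiguous_base_never_merges(self):
        ds = make_sequence_dataset({"p": ["ACGT", "ACGN"]})
        assert collapse_haplotypes(ds).n_haplotypes == 2

    def test_str_haplotypes(self):
        ds = make_str_dataset(["a", "b"], {"p": [(14, 23), (14, 23), (15, 23)]})
        table = collapse_haplotypes(ds)
        assert table.n_haplotypes == 2


class TestHaplotypeDiversity:
    def test_monomorphic_is_zero(self):
        res = haplotype_diversity([5])
        assert res.hd == 0.0 and res.k == 1

    def test_two_unique_haplotypes_give_one(self):
        assert haplotype_diversity([1, 1]).hd == pytest.approx(1.0)

    def test_frozen_321_example(self):
        # oracle: (6/5) * (1 - 14/36) = 0.7333...
        expected, expected_sd = oracles.hd_nei([3, 2, 1])
        res = haplotype_diversity([3, 2, 1])
        assert res.hd == pytest.approx(expected, abs=1e-12)
        assert res.hd == pytest.approx(0.7333333333333334, abs=1e-12)
        assert res.hd_sd == pytest.approx(expected_sd, abs=1e-12)

    def test_requires_two_individuals(self):
        with pytest.raises(errors.UndefinedStatisticError):
            haplotype_diversity([1])

    @given(
        st.lists(st.integers(min_value=1, max_value=30), min_size=1, max_size=12).filter(
            lambda c: sum(c) >= 2
        )
    )
    def test_bounds_and_permutation_invariance(self, counts):
        res = haplotype_diversity(counts)
        assert 0.0 <= res.hd <= 1.0
        assert (res.hd == 0.0) == (len(counts) == 1)
        shuffled = list(reversed(sorted(counts)))
        assert haplotype_diversity(shuffled).hd == pytest.approx(res.hd, abs=1e-12)


class TestPairwiseDifferences:
    def test_single_site_difference(self):
        ds = make_sequence_dataset({"p": ["AAA", "AAT"]})
        assert pairwise_differences(ds)[0, 1] == 1

    def test_gap_sites_excluded_pairwise(self):
        ds = make_sequence_dataset({"p": ["A-A", "ATA"]})
        assert pairwise_differences(ds)[0, 1] == 0

    def test_str_absolute_difference(self):
        ds = make_str_dataset(["a", "b"], {"p": [(14, 23), (16, 23)]})
        assert pairwise_differences(ds)[0, 1] == 2

    def test_matches_oracle_on_random_data(self, rng):
        ds = random_sequence_dataset(rng, n_pops=1, n_per_pop=(6, 6))
        mat = pairwise_differences(ds)
        seqs = [r.sequence for r in ds.records]
        for i in range(len(seqs)):
            for j in range(len(seqs)):
                assert mat[i, j] == oracles.hamming_pairwise_deletion(seqs[i], seqs[j])


class TestMismatchAndRaggedness:
    def test_point_mass_distribution(self):
        ds = make_sequence_dataset({"p": ["AAAA", "AAAT"]})
        mm, r = mismatch_and_raggedness(ds)
        assert mm.classes.tolist() == [0, 1]
        assert r == pytest.approx(2.0)

    def test_flat_distribution_frozen_from_oracle(self):
        # Four classes 0..3 at frequency 1/4 each; by direct summation of
        # Harpending's formula only the trailing (0 - 1/4)^2 term is nonzero.
        from isoscope.stats import MismatchDistribution, raggedness

        mm = MismatchDistribution(classes=np.array([2, 2, 2, 2]), n_pairs=8)
        assert raggedness(mm) == pytest.approx(0.0625, abs=1e-15)

    def test_matches_oracle_on_random_data(self, rng):
        for _ in range(10):
            ds = random_sequence_dataset(rng, n_pops=1, n_per_pop=(5, 9))
            _, r = mismatch_and_raggedness(ds)
            seqs = [x.sequence for x in ds.records]
            assert r == pytest.approx(oracles.raggedness_harpending(seqs), abs=1e-12)

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_classes_sum_to_pair_count(self, seed):
        ds = random_sequence_dataset(np.random.default_rng(seed), n_pops=1,
                                     n_per_pop=(3, 10))
        mm, _ = mismatch_and_raggedness(ds)
        n = len(ds)
        assert mm.classes.sum() == n * (n - 1) // 2 == mm.n_pairs


class TestTajimasD:
    def test_monomorphic_is_undefined(self):
        ds = make_sequence_dataset({"p": ["ACGT"] * 5})
        with pytest.raises(errors.UndefinedStatisticError):
            tajimas_d(ds)

    def test_singleton_heavy_alignment_is_negative(self):
        ref = "A" * 20
        seqs = [ref]
        for i in range(6):
            seqs.append(ref[:i] + "T" + ref[i + 1:])
        ds = make_sequence_dataset({"p": seqs})
        assert tajimas_d(ds) < 0

    def test_matches_scripted_oracle_on_random_fixtures(self):
        rng = np.random.default_rng(777)
        checked = 0
        for _ in range(100):
            ds = random_sequence_dataset(rng, n_pops=1, n_per_pop=(4, 12))
            seqs = [r.sequence for r in ds.records]
            expected = oracles.tajima_d(seqs)
            if expected is None:
                continue
            assert tajimas_d(ds) == pytest.approx(expected, abs=1e-9)
            checked += 1
        assert checked > 50


class TestThetaEstimators:
    def test_two_sequences_one_difference(self):
        ds = make_sequence_dataset({"p": ["AAAA", "AAAT"]})
        theta_pi, theta_s, theta_h = theta_estimators(ds)
        assert theta_pi == pytest.approx(1.0)
        assert theta_s == pytest.approx(1.0)  # a1 = 1 at n = 2
        assert theta_h == pytest.approx(1.0)  # F = 1/2 for two unique haplotypes

    def test_monomorphic_gives_zeroes(self):
        ds = make_sequence_dataset({"p": ["ACGT"] * 4})
        assert theta_estimators(ds) == (0.0, 0.0, pytest.approx(0.0))

    def test_matches_oracles_on_random_fixtures(self):
        rng = np.random.default_rng(4242)
        for _ in range(100):
            ds = random_sequence_dataset(rng, n_pops=1, n_per_pop=(4, 10))
            seqs = [r.sequence for r in ds.records]
            theta_pi, theta_s, theta_h = theta_estimators(ds)
            assert theta_pi == pytest.approx(
                oracles.mean_pairwise_differences(seqs), abs=1e-9
            )
            assert theta_s == pytest.approx(oracles.theta_watterson(seqs), abs=1e-9)
            assert theta_h == pytest.approx(oracles.theta_homozygosity(seqs), abs=1e-9)


class TestFuFs:
    def test_n2_closed_form_is_zero(self):
        # S' = theta/(1+theta) = 1/2 at theta = 1 -> Fs = 0
        assert fu_fs_statistic(2, 2, 1.0) == pytest.approx(0.0, abs=1e-12)

    def test_monomorphic_is_undefined(self):
        with pytest.raises(errors.UndefinedStatisticError):
            fu_fs_statistic(5, 1, 0.0)

    @pytest.mark.parametrize("n", [2, 10, 50])
    @pytest.mark.parametrize("theta", [0.5, 2.0, 5.0])
    def test_ewens_probabilities_sum_to_one(self, n, theta):
        total = float(np.exp(ewens_log_pmf(n, theta)).sum())
        assert total == pytest.approx(1.0, abs=1e-10)

    @pytest.mark.parametrize("n", [3, 5, 8])
    @pytest.mark.parametrize("theta", [0.7, 1.0, 3.0])
    def test_matches_exhaustive_partition_enumeration(self, n, theta):
        pk_oracle = oracles.ewens_k_distribution(n, theta)
        pk = np.exp(ewens_log_pmf(n, theta))
        assert pk[1:] == pytest.approx(pk_oracle[1:], abs=1e-12)
        for k_obs in range(2, n + 1):
            assert fu_fs_statistic(n, k_obs, theta) == pytest.approx(
                oracles.fu_fs(n, k_obs, theta), abs=1e-9
            )

    def test_p_value_behaviour_for_haplotype_excess(self):
        # many singleton haplotypes at moderate theta -> strongly negative Fs
        # and a small simulation p-value
        ref = "A" * 40
        seqs = [ref[:i] + "G" + ref[i + 1:] for i in range(12)]
        ds = make_sequence_dataset({"p": seqs})
        fs, p = fu_fs(ds, p_reps=200, seed=3)
        assert fs < -3
        assert p < 0.1

    def test_deterministic_given_seed(self):
        ds = make_sequence_dataset(
            {"p": ["AAAA", "AAAT", "AATT", "AAAA", "TAAA", "AAAT"]}
        )
        assert fu_fs(ds, p_reps=100, seed=9) == fu_fs(ds, p_reps=100, seed=9)
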