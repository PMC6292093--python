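import math
from itertools import permutations, product

import numpy as np
import pytest

from replicheck import (
    BELL_NUMBERS,
    GenotypeCode,
    ReplicateDataset,
    SiteAlleleDepth,
    SiteRecord,
    SourceVector,
    canonicalize,
    enumerate_source_vectors,
    genotype_log_likelihood,
    genotype_vector_log_prior,
    hwe_genotype_log_prior,
    joint_posterior,
    non_replicate_rate,
    posterior_odds,
    site_log_likelihood,
    source_vector_classes,
)
from replicheck.partition_model import _coerce_prior

from ._oracles import brute_force_site_loglik, canonical_partition_labels

from .conftest import random_dataset


class TestSourceVector:
    def test_valid_vectors(self):
        for labels in [(1,), (1, 1), (1, 2), (1, 2, 1), (1, 2, 3)]:
            assert SourceVector(labels).labels == labels

    @pytest.mark.parametrize(
        "labels", [(), (2,), (0, 1), (1, 3), (1, 2, 4), (1, 1, 3)]
    )
    def test_invalid_vectors_rejected(self, labels):
        with pytest.raises(ValueError):
            SourceVector(labels)

    def test_groups(self):
        assert SourceVector((1, 2, 1)).groups() == {1: (0, 2), 2: (1,)}

    def test_string_round_trip(self):
        sv = SourceVector((1, 2, 2, 3))
        assert SourceVector.from_string(str(sv)) == sv

    def test_canonicalize(self):
        assert canonicalize([7, 3, 7]) == SourceVector((1, 2, 1))
        assert canonicalize([2, 2, 2]) == SourceVector((1, 1, 1))


class TestEnumeration:
    def test_k3_matches_worked_example(self):
        expected = [(1, 1, 1), (1, 1, 2), (1, 2, 1), (1, 2, 2), (1, 2, 3)]
        assert [sv.labels for sv in enumerate_source_vectors(3)] == expected

    def test_k1_single_partition(self):
        assert enumerate_source_vectors(1) == (SourceVector((1,)),)

    def test_k4_has_15_vectors(self):
        assert len(enumerate_source_vectors(4)) == 15

    @pytest.mark.parametrize("k", range(1, 9))
    def test_counts_match_bell_numbers(self, k):
        vectors = enumerate_source_vectors(k)
        assert len(vectors) == BELL_NUMBERS[k]
        assert len(set(vectors)) == len(vectors)

    @pytest.mark.parametrize("k", range(1, 9))
    def test_matches_brute_force_partition_enumerator(self, k):
        assert {sv.labels for sv in enumerate_source_vectors(k)} == (
            canonical_partition_labels(k)
        )

    def test_lexicographic_order(self):
        for k in range(2, 7):
            vectors = [sv.labels for sv in enumerate_source_vectors(k)]
            assert vectors == sorted(vectors)

    @pytest.mark.parametrize("k", [0, -1, 9, 12])
    def test_out_of_range_k_rejected(self, k):
        with pytest.raises(ValueError, match="between 1 and 8"):
            enumerate_source_vectors(k)

    def test_class_representatives(self):
        assert [sv.labels for sv in source_vector_classes(3)] == [
            (1, 1, 1),
            (1, 1, 2),
            (1, 2, 3),
        ]
        assert len(source_vector_classes(4)) == 5  # integer partitions of 4


class TestGenotypeLogLikelihood:
    def test_zero_depth_is_log_one(self):
        for g in GenotypeCode:
            assert genotype_log_likelihood(SiteAlleleDepth(0, 0), g, 0.01) == 0.0

    def test_het_one_each(self):
        # C(2,1) * 0.5 * 0.5 = 0.5
        value = genotype_log_likelihood((1, 1), GenotypeCode.AB, 0.01)
        assert value == pytest.approx(math.log(0.5), rel=1e-12)

    def test_homref_two_ref_reads(self):
        value = genotype_log_likelihood((2, 0), GenotypeCode.AA, 0.01)
        assert value == pytest.approx(math.log(0.99**2), rel=1e-12)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            genotype_log_likelihood((-1, 2), GenotypeCode.AA, 0.01)

    @pytest.mark.parametrize("e", [0.0, 0.5, 0.7, -0.1])
    def test_error_rate_domain(self, e):
        with pytest.raises(ValueError):
            genotype_log_likelihood((1, 1), GenotypeCode.AA, e)

    @pytest.mark.parametrize("g", list(GenotypeCode))
    @pytest.mark.parametrize("n", [1, 3, 7])
    def test_binomial_normalization(self, g, n):
        total = sum(
            math.exp(genotype_log_likelihood((n - n_b, n_b), g, 0.02))
            for n_b in range(n + 1)
        )
        assert total == pytest.approx(1.0, abs=1e-12)


class TestHwePrior:
    def test_symmetric_frequency(self):
        assert np.exp(hwe_genotype_log_prior(0.5)) == pytest.approx(
            [0.25, 0.5, 0.25], abs=1e-12
        )

    def test_f_01(self):
        assert np.exp(hwe_genotype_log_prior(0.1)) == pytest.approx(
            [0.81, 0.18, 0.01], rel=1e-12
        )

    def test_sums_to_one(self):
        for f in [0.001, 0.3, 0.77, 0.999]:
            assert np.exp(hwe_genotype_log_prior(f)).sum() == pytest.approx(
                1.0, abs=1e-12
            )

    def test_aa_prior_decreasing_in_f(self):
        grid = np.linspace(0.01, 0.99, 25)
        aa = [hwe_genotype_log_prior(f)[0] for f in grid]
        assert all(b < a for a, b in zip(aa, aa[1:]))

    @pytest.mark.parametrize("f", [0.0, 1.0, -0.2, 1.5])
    def test_degenerate_frequency_rejected(self, f):
        with pytest.raises(ValueError):
            hwe_genotype_log_prior(f)


class TestGenotypeVectorPrior:
    def test_inconsistent_vector_has_zero_prior(self):
        value = genotype_vector_log_prior(
            (GenotypeCode.AA, GenotypeCode.AB, GenotypeCode.AA),
            SourceVector((1, 1, 2)),
            0.3,
        )
        assert value == float("-inf")

    def test_consistent_count_s111_is_3(self):
        S = SourceVector((1, 1, 1))
        count = sum(
            genotype_vector_log_prior(G, S, 0.3) > float("-inf")
            for G in product(range(3), repeat=3)
        )
        assert count == 3

    def test_consistent_count_s112_is_9(self):
        S = SourceVector((1, 1, 2))
        count = sum(
            genotype_vector_log_prior(G, S, 0.3) > float("-inf")
            for G in product(range(3), repeat=3)
        )
        assert count == 9

    @pytest.mark.parametrize("k", [2, 3, 4])
    def test_prior_normalizes_over_all_genotype_vectors(self, k):
        f = 0.37
        for S in enumerate_source_vectors(k):
            total = sum(
                math.exp(genotype_vector_log_prior(G, S, f))
                for G in product(range(3), repeat=k)
            )
            assert total == pytest.approx(1.0, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            genotype_vector_log_prior((0, 1), SourceVector((1, 2, 3)), 0.3)


def _site(depths, f=0.3):
    return SiteRecord(
        chrom="chr1",
        pos=1000,
        freq_B=f,
        depths=tuple(SiteAlleleDepth(a, b) for a, b in depths),
    )


class TestSiteLogLikelihood:
    def test_all_zero_depths_identical_across_partitions(self):
        site = _site([(0, 0)] * 3)
        values = {
            round(site_log_likelihood(site, S, 0.01), 12)
            for S in enumerate_source_vectors(3)
        }
        assert values == {0.0}

    def test_independent_sources_factorize(self, rng):
        depths = [(2, 1), (0, 3)]
        site = _site(depths, f=0.42)
        joint = site_log_likelihood(site, SourceVector((1, 2)), 0.01)
        parts = sum(
            site_log_likelihood(_site([d], f=0.42), SourceVector((1,)), 0.01)
            for d in depths
        )
        assert joint == pytest.approx(parts, rel=1e-12)

    def test_matches_brute_force_oracle_k3(self, rng):
        for _ in range(25):
            depths = [tuple(rng.integers(0, 5, 2)) for _ in range(3)]
            f = float(rng.uniform(0.05, 0.95))
            site = _site(depths, f=f)
            for S in enumerate_source_vectors(3):
                fast = site_log_likelihood(site, S, 0.01)
                slow = brute_force_site_loglik(depths, f, S.labels, 0.01)
                assert fast == pytest.approx(slow, rel=1e-10)

    def test_mismatched_k_rejected(self):
        with pytest.raises(ValueError):
            site_log_likelihood(_site([(1, 0)] * 2), SourceVector((1, 2, 3)), 0.01)

    def test_degenerate_frequency_rejected(self):
        with pytest.raises(ValueError):
            site_log_likelihood(_site([(1, 0)], f=0.0), SourceVector((1,)), 0.01)


class TestJointPosterior:
    def test_k1_trivial(self):
        data = ReplicateDataset(
            sample_ids=["a"],
            chrom=["chr1"],
            pos=[100],
            freq_B=[0.4],
            depths=np.array([[[2, 1]]]),
        )
        result = joint_posterior(data)
        assert result.posterior == pytest.approx([1.0])
        assert result.called == SourceVector((1,))

    def test_uninformative_site_gives_uniform_posterior_and_no_call(self):
        data = ReplicateDataset(
            sample_ids=["a", "b", "c"],
            chrom=["chr1"],
            pos=[100],
            freq_B=[0.4],
            depths=np.zeros((1, 3, 2), dtype=int),
        )
        result = joint_posterior(data, threshold=0.99)
        assert result.posterior == pytest.approx([0.2] * 5, abs=1e-12)
        assert result.called is None

    def test_posterior_sums_to_one(self, small_dataset):
        result = joint_posterior(small_dataset)
        assert result.posterior.sum() == pytest.approx(1.0, abs=1e-9)

    def test_log_likelihoods_sum_site_values(self, small_dataset):
        result = joint_posterior(small_dataset)
        S = SourceVector((1, 2, 1))
        expected = sum(
            site_log_likelihood(site, S, small_dataset.error_rate)
            for site in small_dataset.sites()
        )
        assert result.log_likelihood_of(S) == pytest.approx(expected, rel=1e-10)

    def test_posterior_is_normalized_exponential_of_logliks(self, small_dataset):
        result = joint_posterior(small_dataset)
        ll = result.log_likelihoods
        expected = np.exp(ll - ll.max())
        expected /= expected.sum()
        assert result.posterior == pytest.approx(expected, rel=1e-9)

    def test_custom_prior_accepted_and_applied(self, small_dataset):
        n = 5
        prior = np.full(n, 1.0 / n)
        uniform = joint_posterior(small_dataset, prior=prior)
        skewed = np.array([0.9, 0.025, 0.025, 0.025, 0.025])
        tilted = joint_posterior(small_dataset, prior=skewed)
        ratio = tilted.posterior / uniform.posterior
        assert ratio / ratio[1] == pytest.approx(
            skewed / skewed[1] * (prior[1] / prior), rel=1e-6
        )

    @pytest.mark.parametrize(
        "bad_prior",
        [np.ones(5), np.full(4, 0.25), np.array([0.5, 0.5, 0.2, -0.1, -0.1])],
    )
    def test_bad_priors_rejected(self, small_dataset, bad_prior):
        with pytest.raises(ValueError):
            joint_posterior(small_dataset, prior=bad_prior)

    def test_prior_mapping_form(self, small_dataset):
        vectors = enumerate_source_vectors(3)
        prior = {sv: 0.2 for sv in vectors}
        result = joint_posterior(small_dataset, prior=prior)
        assert result.posterior.sum() == pytest.approx(1.0, abs=1e-9)

    def test_tie_yields_no_call(self):
        # Two-sample all-zero-depth data: both partitions equally likely.
        data = ReplicateDataset(
            sample_ids=["a", "b"],
            chrom=["chr1"],
            pos=[100],
            freq_B=[0.5],
            depths=np.zeros((1, 2, 2), dtype=int),
        )
        result = joint_posterior(data, threshold=0.5)
        assert result.posterior == pytest.approx([0.5, 0.5])
        assert result.called is None

    def test_permutation_equivariance(self, rng):
        data = random_dataset(rng, k=3, L=30)
        base = joint_posterior(data)
        for perm in permutations(range(3)):
            permuted = joint_posterior(data.reorder_samples(list(perm)))
            for S in base.vectors:
                relabeled = canonicalize([S.labels[p] for p in perm])
                assert permuted.posterior_of(relabeled) == pytest.approx(
                    base.posterior_of(S), rel=1e-9, abs=1e-12
                )


class TestPosteriorOdds:
    def test_identity(self, small_dataset):
        result = joint_posterior(small_dataset)
        S = SourceVector((1, 1, 2))
        assert posterior_odds(result, S, S) == 1.0

    def test_uniform_posterior_unit_odds(self):
        data = ReplicateDataset(
            sample_ids=["a", "b", "c"],
            chrom=["chr1"],
            pos=[100],
            freq_B=[0.4],
            depths=np.zeros((1, 3, 2), dtype=int),
        )
        result = joint_posterior(data)
        vs = result.vectors
        for S1 in vs:
            for S2 in vs:
                assert posterior_odds(result, S1, S2) == pytest.approx(1.0)

    def test_matches_likelihood_ratio_under_uniform_prior(self, small_dataset):
        result = joint_posterior(small_dataset)
        vs = result.vectors
        for S1, S2 in [(vs[0], vs[2]), (vs[3], vs[4])]:
            lr = math.exp(
                result.log_likelihood_of(S1) - result.log_likelihood_of(S2)
            )
            assert posterior_odds(result, S1, S2) == pytest.approx(lr, rel=1e-9)

    def test_matches_posterior_ratio(self, small_dataset):
        result = joint_posterior(small_dataset)
        vs = result.vectors
        for S1, S2 in [(vs[1], vs[3]), (vs[4], vs[0])]:
            expected = result.posterior_of(S1) / result.posterior_of(S2)
            assert posterior_odds(result, S1, S2) == pytest.approx(expected, rel=1e-9)

    def test_cycle_of_odds_telescopes_to_one(self, small_dataset):
        result = joint_posterior(small_dataset)
        v = result.vectors
        cycle = (
            posterior_odds(result, v[0], v[2])
            * posterior_odds(result, v[2], v[4])
            * posterior_odds(result, v[4], v[0])
        )
        assert cycle == pytest.approx(1.0, rel=1e-9)

    def test_unknown_vector_rejected(self, small_dataset):
        result = joint_posterior(small_dataset)
        with pytest.raises(ValueError):
            posterior_odds(result, SourceVector((1, 2)), result.vectors[0])


class TestNonReplicateRate:
    def test_uniform_k3_is_point_eight(self):
        data = ReplicateDataset(
            sample_ids=["a", "b", "c"],
            chrom=["chr1"],
            pos=[100],
            freq_B=[0.4],
            depths=np.zeros((1, 3, 2), dtype=int),
        )
        assert non_replicate_rate(joint_posterior(data)) == pytest.approx(0.8)

    def test_concentrated_posterior_gives_zero(self):
        rng = np.random.default_rng(5)
        from replicheck.simulator import SimConfig, simulate_dataset

        cfg = SimConfig.create("1,1,1", 500, (0.4, 0.5), 15.0, seed=11)
        data, _ = simulate_dataset(cfg)
        assert non_replicate_rate(joint_posterior(data)) == pytest.approx(
            0.0, abs=1e-9
        )

    def test_k2_definition(self, rng):
        data = random_dataset(rng, k=2, L=15)
        result = joint_posterior(data)
        assert non_replicate_rate(result) == pytest.approx(
            1.0 - result.posterior_of(SourceVector((1, 1)))
        )


class TestDatasetContainer:
    def test_error_rate_zero_rejected(self, rng):
        with pytest.raises(ValueError):
            random_dataset(rng, error_rate=0.0)

    def test_depth_shape_validated(self):
        with pytest.raises(ValueError):
            ReplicateDataset(
                sample_ids=["a", "b"],
                chrom=["chr1"],
                pos=[1],
                freq_B=[0.5],
                depths=np.zeros((1, 3, 2), dtype=int),
            )

    def test_site_round_trip(self, small_dataset):
        rebuilt = ReplicateDataset.from_sites(
            small_dataset.sample_ids,
            list(small_dataset.sites()),
            small_dataset.error_rate,
        )
        assert np.array_equal(rebuilt.depths, small_dataset.depths)
        assert rebuilt.freq_B == pytest.approx(small_dataset.freq_B)

    def test_coerce_prior_uniform_default(self):
        vectors = enumerate_source_vectors(3)
        log_prior = _coerce_prior(None, vectors)
        assert np.exp(log_prior) == pytest.approx([0.2] * 5)
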