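import itertools
import math
from collections import Counter

import numpy as np
import pandas as pd
import pytest

import popdiff as pop

from conftest import make_alignment, make_micro


class TestPermuteIndividuals:
    def test_label_multiset_preserved(self, sim_dataset):
        rng = np.random.default_rng(0)
        perm = pop.permute_individuals(sim_dataset, rng)
        assert Counter(perm.populations) == Counter(sim_dataset.populations)
        assert np.array_equal(perm.genotypes, sim_dataset.genotypes)

    def test_single_population_unchanged(self):
        ds = make_micro({"A": [((1, 2),), ((1, 1),), ((2, 2),)]})
        perm = pop.permute_individuals(ds, np.random.default_rng(1))
        assert perm.populations == ds.populations

    def test_assignments_uniform_over_partitions(self):
        # 4 individuals in demes of 2+2: 6 distinct assignments, each with
        # probability 1/6; check 10000 permutations against a 3-sigma bound
        ds = make_micro({"A": [((1, 1),), ((2, 2),)], "B": [((3, 3),), ((4, 4),)]})
        rng = np.random.default_rng(42)
        counts = Counter()
        n = 10_000
        for _ in range(n):
            perm = pop.permute_individuals(ds, rng)
            in_a = tuple(sorted(i for i, p in enumerate(perm.populations) if p == "A"))
            counts[in_a] += 1
        assert len(counts) == 6
        sigma = math.sqrt(n * (1 / 6) * (5 / 6))
        for c in counts.values():
            assert abs(c - n / 6) < 3 * sigma


class TestPermutationTest:
    def test_identical_pops_p_one(self):
        # plain-mode D is non-negative, so every permuted value ties or
        # exceeds the observed 0 and p = 1 exactly
        inds = [((1, 2),), ((1, 1),), ((2, 2),)]
        ds = make_micro({"A": inds, "B": inds})
        stat = pop.MultilocusDGST(ds, mode="plain")
        out = pop.permutation_test(ds, stat, pop.PermutationConfig(200, seed=3))
        assert out.observed_D == pytest.approx(0.0, abs=1e-12)
        assert out.p_D == 1.0

    def test_toy_exact_third_and_mc_convergence(self, toy_haploid):
        stat = pop.SequenceDGST(toy_haploid, mode="plain")
        exact = pop.exact_permutation_pvalue(toy_haploid, stat, key="D")
        assert exact == pytest.approx(1 / 3)
        out = pop.permutation_test(
            toy_haploid, stat, pop.PermutationConfig(10_000, seed=17)
        )
        assert out.p_D == pytest.approx(exact, abs=0.03)

    def test_undefined_statistic_rejected_before_permuting(self):
        aln = make_alignment({"A": ["AAAA"] * 2, "B": ["AAAA"] * 2})
        stat = pop.SequenceDGST(aln, mode="plain")
        with pytest.raises(ValueError, match="undefined"):
            pop.permutation_test(aln, stat, pop.PermutationConfig(10, seed=0))

    def test_same_stream_for_d_and_gst(self, sim_dataset):
        # a bundle reporting the same value under both names must get
        # identical p-values, proving one shared permutation stream
        base = pop.MultilocusDGST(sim_dataset, mode="plain")

        class Mirror(pop.LabelStatistic):
            def __call__(self, labels):
                d = base(labels)["D"]
                return {"D": d, "G_ST": d}

        out = pop.permutation_test(
            sim_dataset, Mirror(), pop.PermutationConfig(100, seed=9)
        )
        assert out.p_D == out.p_GST
        assert np.array_equal(out.null_values["D"], out.null_values["G_ST"])

    def test_ht_constant_over_permutations(self, sim_dataset):
        # permutation only redistributes individuals, so the pooled allele
        # table and hence plain-mode H_T are invariant at every locus
        rng = np.random.default_rng(5)
        locus = sim_dataset.loci[0]
        ref = pop.hs_ht(pop.allele_frequencies(sim_dataset, locus), "plain")
        labels = np.asarray(sim_dataset.populations)
        sizes = Counter(sim_dataset.populations)
        for _ in range(20):
            perm = pop.permute_individuals(sim_dataset, rng)
            res = pop.hs_ht(pop.allele_frequencies(perm, locus), "plain")
            assert res.H_T == pytest.approx(ref.H_T, abs=1e-12)
            assert Counter(perm.populations) == sizes

    def test_reproducible_under_seed(self, sim_dataset):
        stat = pop.MultilocusDGST(sim_dataset, mode="plain")
        cfg = pop.PermutationConfig(100, seed=21)
        a = pop.permutation_test(sim_dataset, stat, cfg)
        b = pop.permutation_test(sim_dataset, stat, cfg)
        assert a.p_values == b.p_values
        assert a.null_quantiles == b.null_quantiles

    def test_add_one_variant(self, toy_haploid):
        stat = pop.SequenceDGST(toy_haploid, mode="plain")
        out = pop.permutation_test(
            toy_haploid, stat, pop.PermutationConfig(6, seed=1, add_one=True)
        )
        assert out.p_D > 0

    def test_dataset_level_bundle_supported(self, toy_haploid):
        def bundle(data):
            row = pop.sequence_differentiation(data, mode="plain")
            return {"D": row.D}

        out = pop.permutation_test(
            toy_haploid, bundle, pop.PermutationConfig(300, seed=2)
        )
        assert out.p_D == pytest.approx(1 / 3, abs=0.1)


class TestExactEnumeration:
    def test_identical_pops_give_one(self):
        aln = make_alignment({"A": ["AAAA", "TTTT"], "B": ["AAAA", "TTTT"]})
        stat = pop.SequenceDGST(aln, mode="plain")
        assert pop.exact_permutation_pvalue(aln, stat, key="D") == 1.0

    def test_enumeration_bound(self):
        aln = make_alignment({"A": ["AA"] * 7, "B": ["TT"] * 7})
        stat = pop.SequenceDGST(aln, mode="plain")
        with pytest.raises(ValueError, match="Monte-Carlo"):
            pop.exact_permutation_pvalue(aln, stat, key="D")

    def test_three_group_count(self):
        # 6 individuals in 2+2+2 -> 6!/(2!2!2!) = 90 ordered assignments
        aln = make_alignment(
            {"A": ["AA", "AA"], "B": ["TT", "TT"], "C": ["CC", "CC"]}
        )
        stat = pop.SequenceDGST(aln, mode="plain")
        p = pop.exact_permutation_pvalue(aln, stat, key="D")
        # observed D = 1 is attained only when each pair stays intact:
        # 3! x (identical-pair swaps) = 6 of 90
        assert p == pytest.approx(6 / 90)


class TestMantel:
    @staticmethod
    def _random_distance(rng, k):
        M = rng.uniform(1, 10, size=(k, k))
        M = (M + M.T) / 2
        np.fill_diagonal(M, 0)
        return M

    def test_self_correlation(self):
        rng = np.random.default_rng(0)
        A = self._random_distance(rng, 5)
        res = pop.mantel_test(A, A, n_perm=99, seed=1)
        assert res.r == pytest.approx(1.0)

    def test_affine_invariance(self):
        rng = np.random.default_rng(1)
        A = self._random_distance(rng, 5)
        B = 2 * A + 3
        np.fill_diagonal(B, 0)
        assert pop.mantel_test(A, B, n_perm=9, seed=1).r == pytest.approx(1.0)

    def test_p_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(3)
        A = self._random_distance(rng, 4)
        B = self._random_distance(rng, 4)
        tril = np.tril_indices(4, -1)
        a = A[tril]
        r_obs = np.corrcoef(a, B[tril])[0, 1]
        hits = total = 0
        for perm in itertools.permutations(range(4)):
            Bp = B[np.ix_(perm, perm)]
            r = np.corrcoef(a, Bp[tril])[0, 1]
            total += 1
            hits += abs(r) >= abs(r_obs) - 1e-12
        exact = hits / total
        res = pop.mantel_test(A, B, n_perm=20_000, seed=11)
        assert res.p_value == pytest.approx(exact, abs=0.02)

    def test_label_and_shape_validation(self):
        A = pd.DataFrame(np.zeros((3, 3)), index=list("abc"), columns=list("abc"))
        B = pd.DataFrame(np.zeros((3, 3)), index=list("abd"), columns=list("abd"))
        with pytest.raises(ValueError, match="label"):
            pop.mantel_test(A, B)
        with pytest.raises(ValueError, match=">= 3"):
            pop.mantel_test(np.zeros((2, 2)), np.zeros((2, 2)))

    def test_agrees_with_skbio_r(self):
        # cross-check the correlation statistic against an independent
        # implementation
        from skbio.stats.distance import DistanceMatrix, mantel

        rng = np.random.default_rng(8)
        A = self._random_distance(rng, 6)
        B = A + self._random_distance(rng, 6)
        np.fill_diagonal(B, 0)
        r_skbio = mantel(DistanceMatrix(A), DistanceMatrix(B),
                         permutations=0)[0]
        res = pop.mantel_test(A, B, n_perm=10, seed=0)
        assert res.r == pytest.approx(float(r_skbio), abs=1e-9)


class TestGeography:
    def test_great_circle_known_distance(self):
        # one degree of latitude is ~111.2 km
        d = pop.great_circle_km(40.0, -75.0, 41.0, -75.0)
        assert d == pytest.approx(111.2, rel=0.01)

    def test_matrix_properties(self):
        table = pop.PopulationTable(
            pd.DataFrame(
                {"latitude": [40.0, 42.0, 44.0],
                 "longitude": [-75.0, -77.0, -73.0]},
                index=pd.Index(["a", "b", "c"], name="population"),
            )
        )
        M = pop.geographic_distance_matrix(table)
        arr = M.to_numpy()
        assert np.allclose(arr, arr.T) and np.allclose(np.diag(arr), 0)
        assert (arr[np.triu_indices(3, 1)] > 0).all()

    def test_child_seeds_deterministic_and_bounded(self):
        a = pop.child_seeds(123, 5)
        b = pop.child_seeds(123, 5)
        assert a == b and len(set(a)) == 5
        assert all(0 <= s < 2**31 for s in a)
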