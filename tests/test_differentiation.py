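import math

import numpy as np
import pytest

import popdiff as pop

from conftest import make_alignment, make_micro


class TestGst:
    def test_complete_fixation(self):
        assert pop.gst(0.5, 0.0) == 1.0

    def test_no_differentiation(self):
        assert pop.gst(0.3, 0.3) == 0.0

    def test_arithmetic(self):
        assert pop.gst(0.77, 0.74) == pytest.approx(0.03 / 0.77, abs=1e-12)

    def test_undefined_marker_not_exception(self):
        assert math.isnan(pop.gst(0.0, 0.0))


class TestJostD:
    def test_two_fixed_pops(self):
        assert pop.jost_d(0.5, 0.0, 2) == 1.0

    def test_no_differentiation(self):
        assert pop.jost_d(0.4, 0.4, 5) == 0.0

    def test_arithmetic(self):
        assert pop.jost_d(0.77, 0.74, 8) == pytest.approx(
            (8 / 7) * (0.03 / 0.26), abs=1e-12
        )

    def test_saturated_hs_is_error(self):
        with pytest.raises(ValueError, match="saturated"):
            pop.jost_d(1.0, 1.0, 3)

    def test_ne_formulation_examples(self):
        assert pop.jost_d_from_ne(1.0, 4.0, 4) == pytest.approx(1.0)
        assert pop.jost_d_from_ne(3.3, 3.3, 6) == 0.0

    def test_equivalence_of_both_formulations(self):
        # D from (H_T, H_S, N) must equal D from the derived n_e values
        rng = np.random.default_rng(7)
        for _ in range(100):
            hs = rng.uniform(0, 0.99)
            ht = rng.uniform(hs, 0.995)
            N = int(rng.integers(2, 12))
            d1 = pop.jost_d(ht, hs, N)
            d2 = pop.jost_d_from_ne(1 / (1 - hs), 1 / (1 - ht), N)
            assert d1 == pytest.approx(d2, abs=1e-12)


class TestLocusDifferentiation:
    def test_identical_pops_plain(self):
        inds = [((1, 2),), ((1, 1),), ((2, 2),)]
        ds = make_micro({"A": inds, "B": inds})
        row = pop.locus_differentiation(ds, "L1", mode="plain")
        assert row.D == pytest.approx(0.0, abs=1e-12)
        assert row.G_ST == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_allele_sets_plain(self):
        # pops {a,a,b,b} and {c,c,d,d}: H_S=0.5, H_T=0.75 -> D = 2*0.25/0.5 = 1
        ds = make_micro({"A": [((1, 1),), ((2, 2),)], "B": [((3, 3),), ((4, 4),)]})
        row = pop.locus_differentiation(ds, "L1", mode="plain")
        assert row.H_S == 0.5 and row.H_T == 0.75
        assert row.D == pytest.approx(1.0, abs=1e-12)
        assert row.N == 2

    def test_migration_lowers_mean_D(self):
        def mean_d(m, seed):
            params = pop.IslandModelParams(
                K=4, N_deme=40, m=m, mu=0.005, marker_model="stepwise",
                sample_n=15, seed=seed,
            )
            ds = pop.simulate_microsats(params, 4)
            return pop.differentiation_table(ds, mode="plain").mean_D

        seeds = [11, 12, 13]
        low = np.mean([mean_d(0.002, s) for s in seeds])
        high = np.mean([mean_d(0.2, s) for s in seeds])
        assert low > high

    def test_single_population_is_flagged_missing(self):
        ds = make_micro({"A": [((1, 2),), ((1, 1),)], "B": [((0, 0),), ((0, 0),)]})
        with pytest.warns(UserWarning):
            row = pop.locus_differentiation(ds, "L1", mode="plain")
        assert math.isnan(row.D) and "fewer than 2" in row.note


class TestMultilocusMean:
    def test_published_table_means(self):
        host = [0.62, 0.23, 0.16, 0.07, 0.32, 0.24, 0.31, 0.02]
        parasite = [0.60, 0.67, 0.33, 0.59, 0.55, 0.75]
        assert round(pop.multilocus_mean(host), 2) == 0.25
        assert round(pop.multilocus_mean(parasite), 2) == 0.58
        assert pop.multilocus_mean(host) == pytest.approx(0.24625)

    def test_single_value_and_missing_handling(self):
        assert pop.multilocus_mean([0.4]) == 0.4
        assert pop.multilocus_mean([0.4, float("nan")]) == 0.4
        with pytest.raises(ValueError):
            pop.multilocus_mean([float("nan")])


class TestSequenceDifferentiation:
    def test_monomorphic(self):
        aln = make_alignment({"A": ["AAAA"] * 2, "B": ["AAAA"] * 2})
        row = pop.sequence_differentiation(aln, mode="plain")
        assert row.D == 0.0 and math.isnan(row.G_ST)

    def test_private_haplotypes(self):
        aln = make_alignment({"A": ["AAAA"] * 2, "B": ["TTTT"] * 2})
        row = pop.sequence_differentiation(aln, mode="plain")
        assert row.D == pytest.approx(1.0)

    def test_matches_haplotype_count_oracle(self, sim_alignment):
        # independent route: tabulate haplotype counts per population and
        # apply the plug-in formulas directly
        row = pop.sequence_differentiation(sim_alignment, mode="plain")
        haps = {}
        counts = {}
        for s, p in zip(sim_alignment.seqs, sim_alignment.populations):
            h = haps.setdefault(s, len(haps))
            counts.setdefault(p, {}).setdefault(h, 0)
            counts[p][h] += 1
        pops = list(counts)
        A = len(haps)
        freqs = np.zeros((len(pops), A))
        for i, p in enumerate(pops):
            tot = sum(counts[p].values())
            for h, c in counts[p].items():
                freqs[i, h] = c / tot
        hs = float(np.mean(1 - (freqs**2).sum(axis=1)))
        pbar = freqs.mean(axis=0)
        ht = float(1 - (pbar**2).sum())
        expected = (len(pops) / (len(pops) - 1)) * (ht - hs) / (1 - hs)
        assert row.D == pytest.approx(expected, abs=1e-12)
        assert row.G_ST == pytest.approx((ht - hs) / ht, abs=1e-12)


class TestGammaST:
    def test_full_fixation_every_site(self):
        aln = make_alignment({"A": ["AAAA"] * 2, "B": ["TTTT"] * 2})
        res = pop.gamma_st(aln)
        assert res.gamma_ST == pytest.approx(1.0)

    def test_identical_composition(self):
        aln = make_alignment({"A": ["AATT", "TTAA"], "B": ["AATT", "TTAA"]})
        res = pop.gamma_st(aln)
        assert res.gamma_ST == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_two_site_case(self):
        # pop1 = {AA, AA}, pop2 = {AT, AT}: per-site H_S = 0; site 2 has
        # pbar(T) = 0.5 so H_T = 0.5 there; averaged over both sites
        # H_Tnuc = 0.25 and gamma_ST = 1
        aln = make_alignment({"A": ["AA", "AA"], "B": ["AT", "AT"]})
        res = pop.gamma_st(aln)
        assert res.H_Snuc == 0.0
        assert res.H_Tnuc == pytest.approx(0.25)
        assert res.gamma_ST == pytest.approx(1.0)

    def test_no_variation_is_undefined(self):
        aln = make_alignment({"A": ["AAAA"] * 2, "B": ["AAAA"] * 2})
        assert math.isnan(pop.gamma_st(aln).gamma_ST)

    def test_ambiguity_excluded_per_site(self):
        # the N in pop A leaves only one usable sequence at site 1 there
        aln = make_alignment({"A": ["NA", "TA"], "B": ["CA", "CA"]})
        res = pop.gamma_st(aln)
        # site 1: pop A freq T=1 (N excluded), pop B freq C=1 -> H_S=0,
        # pbar=(0.5 T, 0.5 C) -> H_T=0.5; site 2 monomorphic
        assert res.H_Snuc == pytest.approx(0.0)
        assert res.H_Tnuc == pytest.approx(0.25)


class TestPairwiseD:
    def test_diagonal_and_symmetry(self, sim_dataset):
        res = pop.pairwise_d(sim_dataset, mode="plain")
        M = res.matrix.to_numpy()
        assert np.allclose(np.diag(M), 0)
        assert np.allclose(M, M.T, equal_nan=True)

    def test_identical_pops_zero(self):
        inds = [((1, 2),), ((1, 1),), ((2, 2),)]
        ds = make_micro({"A": inds, "B": inds})
        res = pop.pairwise_d(ds, mode="plain")
        assert res.matrix.loc["A", "B"] == pytest.approx(0.0, abs=1e-12)

    def test_cells_match_two_population_computation(self, sim_dataset):
        res = pop.pairwise_d(sim_dataset, mode="plain")
        pops = list(res.matrix.columns)
        for i in range(len(pops)):
            for j in range(i + 1, len(pops)):
                sub = sim_dataset.restrict_to_populations([pops[i], pops[j]])
                vals = [
                    pop.locus_differentiation(sub, loc, mode="plain").D
                    for loc in sub.loci
                ]
                vals = [v for v in vals if np.isfinite(v)]
                assert res.matrix.iloc[i, j] == pytest.approx(np.mean(vals))


class TestFragmentLengthAnalysis:
    def test_full_length_fragments_equal_full_data(self, sim_alignment):
        full = pop.sequence_differentiation(sim_alignment, mode="plain")
        res = pop.fragment_length_analysis(
            sim_alignment, lengths=(sim_alignment.length,), n_frag=3,
            n_perm=50, seed=5, mode="plain",
        )
        assert np.allclose(res.records["D"], full.D)
        assert res.summary["power"].iloc[0] in (0.0, 1.0)

    def test_no_variation_zero_power(self):
        aln = make_alignment({"A": ["AAAAAAAA"] * 3, "B": ["AAAAAAAA"] * 3})
        res = pop.fragment_length_analysis(
            aln, lengths=(4,), n_frag=5, n_perm=20, seed=1
        )
        assert res.summary["power"].iloc[0] == 0.0
        assert res.records["p_value"].isna().all()

    def test_overlong_fragment_is_error(self, sim_alignment):
        with pytest.raises(ValueError, match="exceeds"):
            pop.fragment_length_analysis(sim_alignment,
                                         lengths=(sim_alignment.length + 1,))

    def test_gst_suppressed_relative_to_d_under_high_diversity(self):
        # the core methodological contrast: with high within-population
        # diversity, G_ST is pinned near zero while D stays high
        params = pop.IslandModelParams(
            K=6, N_deme=100, m=0.005, mu=0.03, marker_model="infinite_alleles",
            sample_n=20, seed=3, burn_in=4000,
        )
        ds = pop.simulate_microsats(params, 4)
        table = pop.differentiation_table(ds, mode="plain")
        hs = np.mean([r.H_S for r in table.rows])
        assert hs > 0.8
        assert table.mean_GST < 0.2
        assert table.mean_D > table.mean_GST * 3
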