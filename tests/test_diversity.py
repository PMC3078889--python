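import itertools

import numpy as np
import pytest
from scipy import stats

from temporalpop.diversity import (
    allelic_richness,
    f_is,
    f_st,
    he_resampling_test,
    observed_heterozygosity,
    unbiased_expected_heterozygosity,
    diversity_report,
)
from temporalpop.genotype import GenotypeTable


def make_table(genos_by_sample, n_loci=1):
    individuals, calls = [], []
    k = 0
    for lab, genos in genos_by_sample.items():
        for g in genos:
            k += 1
            individuals.append((f"i{k}", lab))
            calls.append(list(g) if isinstance(g, list) else [g] * n_loci)
    return GenotypeTable(
        locus_names=[f"L{j}" for j in range(n_loci)], individuals=individuals, calls=calls
    )


class TestHeterozygosity:
    def test_observed_hand_count(self):
        t = make_table({"s": [(10, 12), (10, 10), (12, 12), (10, 12)]})
        per, mean = observed_heterozygosity(t, "s")
        assert per["L0"] == 0.5 and mean == 0.5

    def test_observed_all_homozygous(self):
        t = make_table({"s": [(10, 10), (12, 12)]})
        assert observed_heterozygosity(t, "s")[1] == 0.0

    def test_expected_unbiased_arithmetic(self):
        """p = (0.75, 0.25) from n=4 gene copies: (4/3)(1 - 0.625) = 0.5."""
        t = make_table({"s": [(12, 14), (12, 12)]})
        per, mean = unbiased_expected_heterozygosity(t, "s")
        assert per["L0"] == pytest.approx(0.5)

    def test_expected_monomorphic_is_zero_and_large_n_limit(self):
        t = make_table({"s": [(9, 9)] * 4})
        assert unbiased_expected_heterozygosity(t, "s")[1] == 0.0
        big = make_table({"s": [(1, 2)] * 500})  # p = 0.5/0.5, n -> large
        assert unbiased_expected_heterozygosity(big, "s")[1] == pytest.approx(0.5, abs=2e-3)


class TestAllelicRichness:
    def test_identity_at_full_sample(self):
        assert allelic_richness([3, 5, 2], g=10) == pytest.approx(3.0)

    def test_binomial_arithmetic(self):
        """Counts {2,2} rarefied to g=2: 2 (1 - C(2,2)/C(4,2)) = 5/3."""
        assert allelic_richness([2, 2], g=2) == pytest.approx(5.0 / 3.0)

    def test_monomorphic_is_one(self):
        for g in (1, 3, 8):
            assert allelic_richness([8], g=g) == pytest.approx(1.0)

    def test_monotone_in_g(self):
        counts = [5, 3, 2, 1, 1]
        values = [allelic_richness(counts, g) for g in range(1, 13)]
        assert all(b >= a - 1e-12 for a, b in zip(values, values[1:]))

    def test_g_larger_than_sample_raises(self):
        with pytest.raises(ValueError, match="locusX"):
            allelic_richness([2, 2], g=5, locus="locusX")


class TestFis:
    def test_hwe_exact_counts_match_brute_force(self):
        """1 AA : 2 Aa : 1 aa gives the brute-force variance-component value
        f = b/(b+c) = 1/7 (slightly positive: the sample is heterozygote-
        deficient relative to the sampling-corrected expectation)."""
        t = make_table({"s": [(10, 10), (10, 12), (10, 12), (12, 12)]})
        per, multi = f_is(t, "s")
        n, p, h = 4, 0.5, 0.5
        b = 2 * (n / (n - 1)) * (p * (1 - p) - (2 * n - 1) / (4 * n) * h)
        c = h
        assert per["L0"] == pytest.approx(1 - c / (b + c))
        assert multi == pytest.approx(1.0 / 7.0)

    def test_all_homozygous_polymorphic_is_one(self):
        t = make_table({"s": [(10, 10), (12, 12), (10, 10)]})
        assert f_is(t, "s")[1] == pytest.approx(1.0)

    def test_monomorphic_locus_excluded(self):
        t = make_table({"s": [[(7, 7), (10, 12)], [(7, 7), (10, 10)]]}, n_loci=2)
        per, multi = f_is(t, "s")
        assert np.isnan(per["L0"]) and np.isfinite(multi)


class TestFst:
    def test_fixed_differences_give_theta_one(self):
        t = make_table({"A": [(10, 10)] * 4, "B": [(12, 12)] * 4})
        theta, _ = f_st(t, "A", "B", n_perm=19, seed=0)
        assert theta == pytest.approx(1.0)

    def test_matches_independent_brute_force(self):
        rng = np.random.default_rng(0)
        genosA = [tuple(sorted(rng.integers(10, 14, size=2))) for _ in range(6)]
        genosB = [tuple(sorted(rng.integers(10, 14, size=2))) for _ in range(5)]
        t = make_table(
            {"A": [[g1, g2] for g1, g2 in zip(genosA, genosA[::-1])],
             "B": [[g1, g2] for g1, g2 in zip(genosB, genosB[::-1])]},
            n_loci=2,
        )
        theta, _ = f_st(t, "A", "B", n_perm=19, seed=0)

        # brute-force oracle: plain loops, ratio of summed components
        A = D = 0.0
        for j in range(2):
            grpA = [row[j] for row, (_, lab) in zip(t.calls, t.individuals) if lab == "A"]
            grpB = [row[j] for row, (_, lab) in zip(t.calls, t.individuals) if lab == "B"]
            alleles = sorted({al for g in grpA + grpB for al in g})
            if len(alleles) < 2:
                continue
            n1, n2, r = len(grpA), len(grpB), 2
            nbar = (n1 + n2) / 2
            nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
            for al in alleles:
                p1 = sum((g[0] == al) + (g[1] == al) for g in grpA) / (2 * n1)
                p2 = sum((g[0] == al) + (g[1] == al) for g in grpB) / (2 * n2)
                h1 = sum(al in g and g[0] != g[1] for g in grpA) / n1
                h2 = sum(al in g and g[0] != g[1] for g in grpB) / n2
                pbar = (n1 * p1 + n2 * p2) / (r * nbar)
                s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
                hbar = (n1 * h1 + n2 * h2) / (r * nbar)
                a = nbar / nc * (
                    s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1))
                b = nbar / (nbar - 1) * (
                    pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar)
                c = hbar / 2
                A += a
                D += a + b + c
        assert theta == pytest.approx(A / D, abs=1e-12)

    def test_no_structure_gives_small_theta_large_p(self, synthetic_table):
        """A panmictic sample split in half shows theta near 0, p not small."""
        table, _ = synthetic_table
        modern = table.subset("crossriver_modern")
        half = ["h1"] * 35 + ["h2"] * 36
        relabeled = GenotypeTable(
            locus_names=modern.locus_names,
            individuals=[(i, lab) for (i, _), lab in zip(modern.individuals, half)],
            calls=modern.calls,
        )
        theta, p = f_st(relabeled, "h1", "h2", n_perm=99, seed=1)
        assert abs(theta) < 0.05
        assert p > 0.05

    def test_small_sample_rejected(self):
        t = make_table({"A": [(1, 2)], "B": [(1, 2), (2, 2)]})
        with pytest.raises(ValueError):
            f_st(t, "A", "B", n_perm=9, seed=0)

    def test_permutation_p_superuniform_under_null(self):
        """Over null datasets the permutation p-value is (super-)uniform."""
        rng = np.random.default_rng(7)
        pvals = []
        for _ in range(300):
            genos = [tuple(sorted(rng.integers(1, 5, size=2))) for _ in range(16)]
            rows = [[g, tuple(sorted(rng.integers(1, 5, size=2)))] for g in genos]
            t = make_table({"A": rows[:8], "B": rows[8:]}, n_loci=2)
            _, p = f_st(t, "A", "B", n_perm=39, seed=int(rng.integers(2**31)))
            pvals.append(p)
        # anti-conservative p-values would push the ECDF above the diagonal
        res = stats.kstest(pvals, "uniform", alternative="greater")
        assert res.pvalue > 0.01


class TestHeResampling:
    def test_exhaustive_enumeration_oracle(self):
        """With all C(n, k) subsets enumerable the Monte-Carlo fraction
        converges to the exact enumeration value."""
        rng = np.random.default_rng(5)
        modern_genos = [
            [tuple(sorted(rng.integers(1, 6, size=2))) for _ in range(2)] for _ in range(7)
        ]
        modern = make_table({"m": modern_genos}, n_loci=2)
        hist = make_table(
            {"h": [[tuple(sorted(rng.integers(1, 6, size=2))) for _ in range(2)]
                   for _ in range(3)]},
            n_loci=2,
        )
        _, he_hist = unbiased_expected_heterozygosity(hist, "h")

        def mean_he(idx):
            vals = []
            for j in range(2):
                counts = {}
                n = 0
                for i in idx:
                    g = modern.calls[i][j]
                    for al in g:
                        counts[al] = counts.get(al, 0) + 1
                    n += 2
                ps = np.array(list(counts.values())) / n
                vals.append(n / (n - 1) * (1 - np.sum(ps**2)))
            return np.mean(vals)

        exact = np.mean(
            [mean_he(idx) >= he_hist for idx in itertools.combinations(range(7), 3)]
        )
        frac = he_resampling_test(modern, hist, "m", "h", reps=20_000, seed=11)
        assert frac == pytest.approx(exact, abs=0.02)

    def test_deterministic_given_seed(self, synthetic_table):
        table, _ = synthetic_table
        args = (table, table, "crossriver_modern", "crossriver_historical")
        assert he_resampling_test(*args, reps=200, seed=9) == he_resampling_test(
            *args, reps=200, seed=9
        )

    def test_null_fraction_calibration(self, synthetic_table):
        """When the 'historical' sample is itself a random modern subset, the
        fraction is approximately uniform over subsets (null calibration)."""
        table, _ = synthetic_table
        modern = table.subset("crossriver_modern")
        rng = np.random.default_rng(3)
        fracs = []
        for _ in range(200):
            idx = rng.choice(71, size=14, replace=False)
            pseudo = GenotypeTable(
                locus_names=modern.locus_names,
                individuals=[(f"p{k}", "pseudo") for k in range(14)],
                calls=[list(modern.calls[i]) for i in idx],
            )
            fracs.append(
                he_resampling_test(modern, pseudo, "crossriver_modern", "pseudo",
                                   reps=150, seed=int(rng.integers(2**31)))
            )
        assert 0.35 < np.mean(fracs) < 0.65
        assert stats.kstest(fracs, "uniform").pvalue > 1e-3

    def test_bad_sizes_rejected(self, synthetic_table):
        table, _ = synthetic_table
        with pytest.raises(ValueError):
            he_resampling_test(table, table, "crossriver_historical",
                               "crossriver_modern", reps=10, seed=0)
        with pytest.raises(ValueError):
            he_resampling_test(table, table, "crossriver_modern",
                               "crossriver_historical", reps=0, seed=0)


def test_diversity_report_end_to_end(synthetic_table):
    table, _ = synthetic_table
    rep = diversity_report(table, "crossriver_historical",
                           other_sample="crossriver_modern", n_perm=49, seed=0)
    assert 0 <= rep.h_obs_mean <= 1 and 0 <= rep.h_exp_mean <= 1
    assert all(v >= 1 - 1e-9 for v in rep.allelic_richness.values())
    assert -1 <= rep.f_is_multilocus <= 1
    assert -1 <= rep.f_st <= 1 and 0 < rep.f_st_pvalue <= 1
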