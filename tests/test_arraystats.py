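import numpy as np
import pytest

from poolsweep.arraystats import (
    ArrayQcConfig,
    GenotypeMatrix,
    apply_array_qc,
    genotype_pca,
    het_and_f,
    hwe_exact_test,
    ibs_identity_matrix,
    pool_frequency_pca,
)
from poolsweep.simdata import SimParams, simulate_genotypes, simulate_pools

from conftest import make_counts
from oracles import brute_hwe_p


def make_genotypes(calls, pops=None):
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    return GenotypeMatrix(
        calls=calls,
        individual_ids=[f"i{k}" for k in range(n)],
        snp_ids=[f"s{j}" for j in range(m)],
        chrom=np.full(m, "1", dtype=object),
        pos=np.arange(1, m + 1) * 1000,
        populations=pops or ["pop1"] * n,
    )


class TestHweExact:
    def test_worked_two_heterozygotes(self):
        # (0,2,0): weights het=0 -> 2, het=2 -> 4; both probs <= 2/3 -> p = 1
        assert hwe_exact_test(0, 2, 0) == pytest.approx(1.0)

    def test_monomorphic(self):
        assert hwe_exact_test(10, 0, 0) == 1.0

    def test_matches_enumeration_small_tables(self):
        for n_AA in range(0, 12):
            for n_Aa in range(0, 12):
                for n_aa in range(0, 12):
                    if n_AA + n_Aa + n_aa == 0:
                        continue
                    assert hwe_exact_test(n_AA, n_Aa, n_aa) == pytest.approx(
                        brute_hwe_p(n_AA, n_Aa, n_aa), abs=1e-12
                    )

    def test_extreme_het_deficit_is_significant(self):
        assert hwe_exact_test(50, 0, 50) < 1e-6


class TestArrayQc:
    def test_low_call_rate_individual_dropped(self):
        rng = np.random.default_rng(0)
        calls = rng.integers(0, 3, size=(6, 40)).astype(np.int8)
        calls[0, :20] = -1  # 50% call rate
        g = make_genotypes(calls)
        out, report = apply_array_qc(g, ArrayQcConfig(min_maf=0.0, hwe_alpha=0.0))
        assert report["removed_call_rate"] == 1
        assert "i0" not in out.individual_ids

    def test_duplicate_dropped_once(self):
        rng = np.random.default_rng(1)
        calls = rng.integers(0, 3, size=(5, 60)).astype(np.int8)
        calls[3] = calls[1]  # exact duplicate pair (i1, i3)
        g = make_genotypes(calls)
        out, report = apply_array_qc(g, ArrayQcConfig(min_maf=0.0, hwe_alpha=0.0))
        assert report["removed_ibs"] == 1
        assert "i1" in out.individual_ids and "i3" not in out.individual_ids

    def test_snp_failing_maf_in_one_population_removed(self):
        rng = np.random.default_rng(2)
        calls = rng.integers(0, 2, size=(30, 10)).astype(np.int8)
        calls[:, 3] = np.where(np.arange(30) < 15, calls[:, 3], 0)
        calls[:15, 3] = rng.integers(0, 3, 15)  # polymorphic in popA only
        calls[15:, 3] = 0  # monomorphic (MAF 0) in popB
        pops = ["A"] * 15 + ["B"] * 15
        g = make_genotypes(calls, pops)
        out, _ = apply_array_qc(g, ArrayQcConfig(hwe_alpha=0.0))
        assert "s3" not in out.snp_ids

    def test_idempotent_and_reconciles(self):
        gm = simulate_genotypes(40, 300, missing_rate=0.02, seed=5)
        out, report = apply_array_qc(gm)
        again, report2 = apply_array_qc(out)
        assert again.n_snps == out.n_snps and again.n_individuals == out.n_individuals
        assert report["individuals_in"] - report["removed_call_rate"] - report[
            "removed_ibs"
        ] == report["individuals_out"]
        assert report["snps_in"] - report["removed_maf"] - report[
            "removed_missingness"
        ] - report["removed_hwe"] == report["snps_out"]

    def test_all_missing_rejected(self):
        g = make_genotypes(np.full((4, 5), -1, dtype=np.int8))
        with pytest.raises(ValueError):
            apply_array_qc(g)

    def test_ibs_of_duplicates_is_one(self):
        calls = np.array([[0, 1, 2, 1], [0, 1, 2, 1], [2, 1, 0, 1]], dtype=np.int8)
        ibs = ibs_identity_matrix(calls)
        assert ibs[0, 1] == pytest.approx(1.0)
        assert ibs[0, 2] == pytest.approx(np.mean([0.0, 1.0, 0.0, 1.0]))


class TestHetAndF:
    def test_fully_heterozygous_individual(self):
        calls = np.array(
            [[1, 1, 1, 1], [0, 2, 0, 2], [2, 0, 1, 0], [0, 1, 2, 1]], dtype=np.int8
        )
        per_ind, _ = het_and_f(make_genotypes(calls))
        row = per_ind.set_index("individual").loc["i0"]
        assert row["obs_hom"] == 0
        assert row["F"] < 0

    def test_zero_inbreeding_recovered(self):
        gm = simulate_genotypes(300, 2000, inbreeding_f=0.0, seed=6)
        _, summary = het_and_f(gm)
        assert abs(summary["F_mean"]) < 0.02

    def test_invariant_to_order(self):
        gm = simulate_genotypes(30, 200, inbreeding_f=0.05, seed=7)
        _, s1 = het_and_f(gm)
        rng = np.random.default_rng(8)
        perm_snp = rng.permutation(gm.n_snps)
        perm_ind = rng.permutation(gm.n_individuals)
        shuffled = GenotypeMatrix(
            calls=gm.calls[np.ix_(perm_ind, perm_snp)],
            individual_ids=[gm.individual_ids[i] for i in perm_ind],
            snp_ids=[gm.snp_ids[j] for j in perm_snp],
            chrom=gm.chrom[perm_snp],
            pos=np.arange(1, gm.n_snps + 1) * 1000,
            populations=[gm.populations[i] for i in perm_ind],
        )
        _, s2 = het_and_f(shuffled)
        assert s1["F_mean"] == pytest.approx(s2["F_mean"], abs=1e-12)
        assert s1["obs_het"] == pytest.approx(s2["obs_het"], abs=1e-12)


class TestPca:
    def test_variance_fractions_properties(self):
        gm = simulate_genotypes(50, 400, seed=9)
        _, frac = genotype_pca(gm, 10)
        assert (np.diff(frac) <= 1e-12).all()
        assert frac.sum() <= 1.0 + 1e-9

    def test_pc1_separates_populations(self):
        rng = np.random.default_rng(10)
        freq_a = np.clip(rng.beta(0.8, 0.8, 500), 0.05, 0.95)
        # Balding-Nichols draw at c = 0.2 around shared ancestral frequencies
        c = 0.2
        fa = rng.beta(freq_a * (1 - c) / c, (1 - freq_a) * (1 - c) / c)
        fb = rng.beta(freq_a * (1 - c) / c, (1 - freq_a) * (1 - c) / c)
        calls_a = rng.binomial(2, fa, size=(25, 500)).astype(np.int8)
        calls_b = rng.binomial(2, fb, size=(25, 500)).astype(np.int8)
        g = make_genotypes(np.vstack([calls_a, calls_b]), ["A"] * 25 + ["B"] * 25)
        coords, _ = genotype_pca(g, 2)
        pc1 = coords[:, 0]
        assert max(pc1[:25].min(), pc1[25:].min()) > min(pc1[:25].max(), pc1[25:].max()) \
            or (pc1[:25].max() < pc1[25:].min()) or (pc1[25:].max() < pc1[:25].min())

    def test_duplicated_individuals_equal_coordinates(self):
        gm = simulate_genotypes(20, 300, seed=11)
        doubled = make_genotypes(np.vstack([gm.calls, gm.calls]))
        coords, _ = genotype_pca(doubled, 3)
        assert coords[:20] == pytest.approx(coords[20:], abs=1e-8)


class TestPoolFrequencyPca:
    def test_maf_filter_toy(self):
        from poolsweep.arraystats import pooled_maf_mask

        # pooled frequencies {0.5, 0.45, 0.1}: 2 SNPs pass MAF > 0.4
        ref = np.array([[50, 50, 50], [55, 55, 55], [90, 90, 90]])
        alt = np.array([[50, 50, 50], [45, 45, 45], [10, 10, 10]])
        counts = make_counts(ref, alt)
        assert pooled_maf_mask(counts, 0.40).sum() == 2
        coords, frac = pool_frequency_pca(counts, maf_min=0.40)
        # identical pools: essentially no variance on any axis
        assert np.allclose(frac, 0) or np.allclose(coords, 0, atol=1e-9)

    def test_requires_three_pools(self, tiny_counts):
        with pytest.raises(ValueError):
            pool_frequency_pca(tiny_counts)

    def test_divergent_clusters_split_on_pc1(self):
        params = SimParams(n_pools=6, n_snps=3000, mean_depth=80, fst_target=0.3, seed=12)
        counts, truth = simulate_pools(params)
        # two clusters: pools 0-2 copy pool 0's frequencies, 3-5 copy pool 3's
        rng = np.random.default_rng(13)
        freqs = truth.pool_freqs.copy()
        for j in (1, 2):
            freqs[:, j] = freqs[:, 0]
        for j in (4, 5):
            freqs[:, j] = freqs[:, 3]
        depth = rng.poisson(80, size=freqs.shape)
        alt = rng.binomial(depth, freqs)
        counts = make_counts(depth - alt, alt, sizes=[100] * 6)
        coords, _ = pool_frequency_pca(counts, maf_min=0.2)
        pc1 = coords[:, 0]
        assert (pc1[:3].max() < pc1[3:].min()) or (pc1[3:].max() < pc1[:3].min())
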