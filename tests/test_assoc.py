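import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fearscan import assoc, relatedness, simdata
from fearscan.assoc import (
    genomic_inflation, lmm_assoc, manhattan_qq_data, significance_thresholds,
)
from fearscan.genio import fill_sporadic_missing


@pytest.fixture(scope="module")
def gwas_cohort():
    cfg = simdata.SimConfig(n_breeds=3, n_per_breed=80, n_snps=600,
                            missing_rate=0, seed=17)
    geno, variants, samples, truth = simdata.simulate_genotypes(cfg)
    K = relatedness.compute_grm(geno, "centered")
    return geno, variants, samples, K


class TestThresholds:
    def test_direct_formula(self):
        t = significance_thresholds(100, alpha=0.05)
        assert t.bonferroni_p == 5e-4
        assert t.suggestive_p == 1e-2

    def test_study_marker_count(self):
        t = significance_thresholds(293_519)
        assert np.isclose(t.suggestive_p, 3.4069e-6, rtol=1e-3)

    @pytest.mark.parametrize("n", [1, 10, 1000, 293_519])
    def test_bonferroni_below_suggestive(self, n):
        t = significance_thresholds(n, alpha=0.05)
        assert t.bonferroni_p < t.suggestive_p

    def test_zero_variants_errors(self):
        with pytest.raises(ValueError):
            significance_thresholds(0)


class TestGenomicInflation:
    def test_all_half_is_exactly_one(self):
        assert genomic_inflation(np.full(101, 0.5)) == pytest.approx(1.0)

    def test_uniform_null_near_one(self, rng):
        p = rng.uniform(size=100_000)
        assert 0.97 < genomic_inflation(p) < 1.03

    def test_halving_pvalues_inflates(self, rng):
        p = rng.uniform(size=5_000)
        assert genomic_inflation(p / 2) > genomic_inflation(p)

    def test_empty_or_invalid_errors(self):
        with pytest.raises(ValueError):
            genomic_inflation(np.array([]))
        with pytest.raises(ValueError):
            genomic_inflation(np.array([0.0, 0.5]))


class TestLmmAssoc:
    def test_permuted_phenotype_null_is_calibrated(self, gwas_cohort, rng):
        geno, variants, samples, K = gwas_cohort
        y = rng.permutation(rng.normal(size=geno.n_samples))
        rec = lmm_assoc(y, geno, K, mode="fast")
        p = rec["wald_p"].dropna()
        assert 0.8 < genomic_inflation(p.to_numpy()) < 1.2
        assert 0.02 < (p < 0.05).mean() < 0.08

    def test_injected_causal_snp_is_top_hit(self, gwas_cohort, rng):
        geno, variants, samples, K = gwas_cohort
        j = 123
        x = geno.dosage[:, j].astype(float)
        y = x * 1.0 + rng.normal(size=geno.n_samples) * np.sqrt(
            9 * x.var()
        )  # SNP explains ~10% of variance
        rec = lmm_assoc(y, geno, K, mode="exact")
        assert rec.loc[rec["wald_p"].idxmin(), "id"] == geno.variant_ids[j]

    def test_identity_kinship_matches_ols(self, gwas_cohort, rng):
        geno, *_ = gwas_cohort
        n = geno.n_samples
        y = rng.normal(size=n)
        rec = lmm_assoc(y, geno.subset_variants(range(20)), 2.0 * np.eye(n))
        for j in range(20):
            x = geno.dosage[:, j].astype(float)
            slope, *_ = stats.linregress(x, y)
            assert np.isclose(rec.set_index("id").loc[geno.variant_ids[j], "beta"],
                              slope, atol=1e-6)

    def test_wald_matches_dense_gls_oracle(self, gwas_cohort, rng):
        """Rotated-space GLS equals dense whole-covariance GLS at the same
        fitted variance ratio, to 1e-6."""
        geno, variants, samples, K = gwas_cohort
        n = 150
        sub = geno.subset_samples(range(n)).subset_variants(range(60))
        Km = K.matrix[:n, :n]
        y = rng.normal(size=n)
        rec = lmm_assoc(y, sub, Km, mode="exact").set_index("id")
        for vid in sub.variant_ids[:25]:
            j = sub.variant_ids.index(vid)
            x = sub.dosage[:, j].astype(float)
            if x.std() == 0:
                continue
            delta = rec.loc[vid, "delta"]
            V = Km + delta * np.eye(n)
            Vi = np.linalg.inv(V)
            X = np.column_stack([np.ones(n), x])
            C = np.linalg.inv(X.T @ Vi @ X)
            b = C @ X.T @ Vi @ y
            r = y - X @ b
            s2 = (r @ Vi @ r) / (n - 2)
            se = np.sqrt(s2 * C[1, 1])
            wald_dense = (b[1] / se) ** 2
            assert np.isclose(rec.loc[vid, "wald"], wald_dense, atol=1e-6)

    def test_monomorphic_variant_gets_nan_record(self, rng):
        from fearscan.genio import GenotypeMatrix
        d = rng.integers(0, 3, size=(50, 5)).astype(np.int8)
        d[:, 2] = 1
        geno = GenotypeMatrix(d, [f"s{i}" for i in range(50)],
                              [f"v{j}" for j in range(5)])
        K = relatedness.compute_grm(geno, "centered")
        rec = lmm_assoc(rng.normal(size=50), geno, K)
        assert np.isnan(rec.set_index("id").loc["v2", "wald_p"])
        assert rec["wald_p"].notna().sum() == 4

    def test_sample_misalignment_errors(self, gwas_cohort):
        geno, _, _, K = gwas_cohort
        with pytest.raises(ValueError, match="sample"):
            lmm_assoc(np.zeros(10), geno, K)


class TestPlotData:
    def _records(self):
        return pd.DataFrame({
            "id": ["a", "b", "c", "d"],
            "chrom": ["1", "1", "2", "3"],
            "pos": [100, 400, 250, 50],
            "wald_p": [0.5, 0.01, 0.2, 0.9],
        })

    def test_cumulative_positions_increasing(self):
        man, qq, lines = manhattan_qq_data(self._records())
        assert (np.diff(man["cum_pos"]) > 0).all()

    def test_three_chromosome_offsets_hand_computed(self):
        man, *_ = manhattan_qq_data(self._records())
        man = man.set_index("id")
        # chrom 1 spans to 400; chrom 2 offset 400; chrom 3 offset 650
        assert man.loc["a", "cum_pos"] == 100
        assert man.loc["b", "cum_pos"] == 400
        assert man.loc["c", "cum_pos"] == 650
        assert man.loc["d", "cum_pos"] == 700

    def test_qq_expected_quantiles_definition(self):
        _, qq, _ = manhattan_qq_data(self._records())
        m = len(qq)
        expected = -np.log10((np.arange(1, m + 1) - 0.5) / m)
        assert np.allclose(qq["expected_neglog10"], expected)

    def test_threshold_lines_echoed(self):
        t = significance_thresholds(1000)
        *_, lines = manhattan_qq_data(self._records(), t)
        assert np.isclose(lines["suggestive_neglog10"], 3.0)
        assert "lambda_gc" in lines

    def test_empty_records_error(self):
        with pytest.raises(ValueError):
            manhattan_qq_data(pd.DataFrame())
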