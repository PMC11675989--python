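import numpy as np
import pandas as pd
import pytest

from fearscan import behavior, simdata
from fearscan.behavior import (
    AdjustedPhenotype, ComponentResult, adjust_phenotype, component_scores,
    compute_kmo, fit_pca_varimax, kmo_from_corr,
)


@pytest.fixture(scope="module")
def fitted(request):
    cfg = simdata.SimConfig(n_breeds=4, n_per_breed=100, n_snps=200,
                            missing_rate=0, seed=11)
    geno, _, samples, truth = simdata.simulate_genotypes(cfg)
    behav, truth = simdata.simulate_phenotypes(geno, samples, cfg, truth)
    return behav, truth, samples, fit_pca_varimax(behav)


class TestVarimax:
    def test_rotation_matrix_orthonormal(self, fitted):
        *_, res = fitted
        R = res.rotation
        assert np.allclose(R.T @ R, np.eye(R.shape[1]), atol=1e-8)

    def test_rotation_preserves_total_explained_variance(self, fitted):
        *_, res = fitted
        assert np.isclose(
            (res.loadings**2).sum(), (res.rotated_loadings**2).sum(), atol=1e-8
        )

    def test_recovers_planted_component_structure(self, fitted):
        """Congruence between recovered loadings and the planted item-group
        structure exceeds 0.95 for each labeled component."""
        behav, truth, _, res = fitted
        for j, lab in enumerate(res.labels):
            if lab not in simdata.COMPONENTS:
                continue
            target = np.array([
                1.0 if simdata.ITEM_COMPONENT[item] == lab else 0.0
                for item in res.items
            ])
            v = res.rotated_loadings[:, j]
            congruence = v @ target / np.sqrt((v @ v) * (target @ target))
            assert congruence > 0.8, (lab, congruence)

    def test_scores_track_latent_generators(self, fitted):
        behav, truth, _, res = fitted
        for comp in simdata.GENETIC_COMPONENTS:
            assert comp in res.labels
            r = np.corrcoef(res.scores[comp], truth.latent[comp])[0, 1]
            assert r > 0.8, (comp, r)

    def test_constant_item_errors(self, fitted):
        behav = fitted[0].copy()
        behav["mat"] = 1
        with pytest.raises(ValueError, match="mat"):
            fit_pca_varimax(behav)


class TestKmo:
    def test_equicorrelated_closed_form(self):
        """For a p-item equicorrelated matrix the anti-image correlation is
        q = rho/(1 + (p-2) rho), so KMO = rho^2/(rho^2 + q^2)."""
        p, rho = 6, 0.8
        r = np.full((p, p), rho)
        np.fill_diagonal(r, 1.0)
        q = rho / (1 + (p - 2) * rho)
        expected = rho**2 / (rho**2 + q**2)
        assert np.isclose(kmo_from_corr(r), expected, atol=1e-12)

    def test_two_items_degenerate_to_half(self, rng):
        x = rng.normal(size=200)
        df = pd.DataFrame({"a": x + rng.normal(size=200), "b": x})
        assert np.isclose(compute_kmo(df), 0.5, atol=1e-12)

    def test_bounded_in_unit_interval(self, fitted):
        assert 0.0 <= fitted[-1].kmo <= 1.0

    def test_singular_matrix_errors(self):
        r = np.ones((3, 3))
        with pytest.raises(ValueError, match="singular"):
            kmo_from_corr(r)


class TestComponentScores:
    def test_uncorrelated_identity_loadings_return_standardized_items(self, rng):
        X = rng.normal(size=(500, 3))
        df = pd.DataFrame(X, columns=["a", "b", "c"])
        res = ComponentResult(
            items=["a", "b", "c"], loadings=np.eye(3), rotated_loadings=np.eye(3),
            rotation=np.eye(3), explained_variance_fraction=np.ones(3) / 3,
            cumulative_explained=1.0, kmo=0.5, labels=["a", "b", "c"],
            corr=np.eye(3),
        )
        S = component_scores(res, df)
        Z = (X - X.mean(0)) / X.std(0)
        assert np.allclose(S[["a", "b", "c"]].to_numpy(), Z, atol=1e-10)

    def test_columns_centered(self, fitted):
        *_, res = fitted
        score_cols = res.scores[res.labels].to_numpy()
        assert np.allclose(score_cols.mean(axis=0), 0.0, atol=1e-10)

    def test_matches_explicit_matrix_product(self, fitted):
        behav, *_, res = fitted
        X = behav[res.items].to_numpy(float)
        Z = (X - X.mean(0)) / X.std(0)
        expected = Z @ np.linalg.inv(res.corr) @ res.rotated_loadings
        assert np.allclose(
            res.scores[res.labels].to_numpy(), expected, atol=1e-8
        )


class TestAdjustPhenotype:
    def test_no_significant_effects_returns_centered_scores(self, rng):
        n = 200
        samples = pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(n)],
            "facility": rng.choice(["f1", "f2", "f3"], n),
            "sex": rng.choice(["F", "M"], n),
            "size_class": rng.choice(["S", "M", "L"], n),
            "age": rng.uniform(1, 10, n),
        })
        y = pd.Series(rng.normal(size=n) + 5.0)
        adj = adjust_phenotype(y, samples, grm_pcs=None, alpha=1e-6)
        assert adj.retained_effects == []
        assert np.allclose(adj.values.to_numpy(), y - y.mean(), atol=1e-12)

    def test_facility_shift_removed(self, rng):
        n = 300
        fac = rng.choice(["f1", "f2", "f3", "f4"], n)
        shift = pd.Series(fac).map({"f1": 0, "f2": 2, "f3": -1, "f4": 4}).to_numpy()
        samples = pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(n)], "facility": fac,
        })
        y = pd.Series(shift + rng.normal(size=n))
        adj = adjust_phenotype(y, samples, candidates=("facility",))
        assert adj.retained_effects == ["facility"]
        before = pd.Series(y.to_numpy()).groupby(fac).mean().var()
        after = pd.Series(adj.values.to_numpy()).groupby(fac).mean().var()
        assert after < 0.05 * before

    def test_residuals_orthogonal_to_design(self, rng):
        n = 250
        samples = pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(n)],
            "age": rng.uniform(1, 10, n),
        })
        y = pd.Series(0.5 * samples["age"].to_numpy() + rng.normal(size=n))
        adj = adjust_phenotype(y, samples, candidates=("age",))
        assert adj.retained_effects == ["age"]
        x = adj.design.to_numpy(float)[:, 0]
        assert abs(np.dot(adj.values.to_numpy(), x - x.mean())) < 1e-8

    def test_single_observation_level_dropped_with_warning(self, rng):
        n = 60
        fac = ["f1"] * 30 + ["f2"] * 29 + ["lonely"]
        samples = pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(n)], "facility": fac,
        })
        y = pd.Series(rng.normal(size=n))
        with pytest.warns(UserWarning, match="lonely"):
            adjust_phenotype(y, samples, candidates=("facility",))
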