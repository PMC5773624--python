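"""PCA fitting, projection, applicability domain and initial filtration."""

import numpy as np
import pytest
from scipy import stats

from ahrscreen.chemspace import (
    FiltrationResult,
    applicability_domain,
    fit_pca,
    initial_filtration,
    project,
)
from ahrscreen.descriptors import DescriptorMatrix


def dm(values, prefix="x"):
    values = np.asarray(values, dtype=float)
    ids = [f"c{i}" for i in range(values.shape[0])]
    names = [f"{prefix}{j}" for j in range(values.shape[1])]
    return DescriptorMatrix(ids, names, values)


class TestFitPCA:
    def test_rank_one_data_explains_everything(self, rng):
        t = rng.normal(size=40)
        x = np.column_stack([t, 2 * t])
        model = fit_pca(dm(x))
        assert model.r2x[0] == pytest.approx(1.0, abs=1e-10)

    def test_matches_eigendecomposition_oracle(self, rng):
        x = rng.normal(size=(50, 10))
        model = fit_pca(dm(x))
        # independent oracle: eigendecomposition of the scaled covariance
        z = (x - x.mean(0)) / x.std(0, ddof=1)
        evals, evecs = np.linalg.eigh(np.cov(z, rowvar=False))
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        np.testing.assert_allclose(model.eigenvalues, evals[: len(model.eigenvalues)],
                                   atol=1e-8)
        for a in range(model.loadings.shape[1]):
            dot = abs(model.loadings[:, a] @ evecs[:, a])
            assert dot == pytest.approx(1.0, abs=1e-8)  # up to sign

    def test_full_reconstruction_recovers_scaled_matrix(self, rng):
        x = rng.normal(size=(30, 6))
        model = fit_pca(dm(x))
        z = (x - model.column_means) / model.column_scales
        recon = (z @ model.loadings) @ model.loadings.T
        np.testing.assert_allclose(recon, z, atol=1e-8)

    def test_eigenvalue_rule_counts_significant_pcs(self, rng):
        # two strong directions shared by many columns, rest noise
        t1, t2 = rng.normal(size=(2, 200))
        x = np.column_stack([t1 + 0.05 * rng.normal(size=200) for _ in range(5)]
                            + [t2 + 0.05 * rng.normal(size=200) for _ in range(5)])
        model = fit_pca(dm(x))
        assert model.n_significant == 2
        assert np.all(model.eigenvalues[: 2] >= 2.0)

    def test_constant_columns_dropped_with_warning(self, rng):
        x = rng.normal(size=(20, 3))
        x[:, 1] = 4.2
        with pytest.warns(UserWarning, match="constant"):
            model = fit_pca(dm(x))
        assert model.names == ["x0", "x2"]

    def test_too_few_compounds_rejected(self):
        with pytest.raises(ValueError):
            fit_pca(dm(np.zeros((2, 4))))

    def test_serialization_round_trip(self, tmp_path, rng):
        model = fit_pca(dm(rng.normal(size=(20, 5))))
        model.save(tmp_path / "pca.json")
        from ahrscreen.chemspace import PCAModel
        back = PCAModel.load(tmp_path / "pca.json")
        np.testing.assert_allclose(back.loadings, model.loadings)
        assert back.n_significant == model.n_significant
        assert back.t2_limit_95 == pytest.approx(model.t2_limit_95)


class TestProject:
    def test_training_compound_scores_match(self, rng):
        x = rng.normal(size=(25, 6))
        m = dm(x)
        model = fit_pca(m)
        scores = project(model, m)
        dup = DescriptorMatrix(["new"], m.names, x[3][None, :])
        np.testing.assert_allclose(project(model, dup).scores[0], scores.scores[3])

    def test_mean_profile_projects_to_origin(self, rng):
        x = rng.normal(size=(25, 6))
        model = fit_pca(dm(x))
        mean_row = DescriptorMatrix(["mean"], [f"x{j}" for j in range(6)],
                                    x.mean(0)[None, :])
        np.testing.assert_allclose(project(model, mean_row).scores, 0.0, atol=1e-10)

    def test_external_compound_matches_hand_computation(self, rng):
        x = rng.normal(size=(25, 6))
        model = fit_pca(dm(x))
        new = rng.normal(size=6)
        expected = ((new - model.column_means) / model.column_scales) \
            @ model.loadings[:, : model.n_significant]
        got = project(model, DescriptorMatrix(["n"], [f"x{j}" for j in range(6)],
                                              new[None, :]))
        np.testing.assert_allclose(got.scores[0], expected, atol=1e-10)

    def test_unknown_columns_rejected(self, rng):
        model = fit_pca(dm(rng.normal(size=(20, 4))))
        other = dm(rng.normal(size=(3, 4)), prefix="y")
        with pytest.raises(ValueError, match="missing"):
            project(model, other)


class TestApplicabilityDomain:
    def test_centroid_compound_is_inside_with_zero_t2(self, rng):
        x = rng.normal(size=(40, 5))
        model = fit_pca(dm(x))
        centroid = DescriptorMatrix(["c"], [f"x{j}" for j in range(5)],
                                    x.mean(0)[None, :])
        ad = applicability_domain(model, centroid)
        assert ad.t2[0] == pytest.approx(0.0, abs=1e-10)
        assert bool(ad.inside[0])

    def test_far_outlier_is_outside(self, rng):
        x = rng.normal(size=(40, 5))
        m = dm(x)
        model = fit_pca(m)
        outlier = DescriptorMatrix(["o"], m.names, (x.max(0) * 100)[None, :])
        assert not bool(applicability_domain(model, outlier).inside[0])

    def test_partition_matches_first_principles_oracle(self, rng):
        x = rng.normal(size=(60, 8))
        m = dm(x)
        model = fit_pca(m)
        y = rng.normal(size=(30, 8)) * 1.5
        my = dm(y)
        ad = applicability_domain(model, my)

        # explicit recomputation of T2, DModX and both 95% limits
        n, p = x.shape
        z_train = (x - x.mean(0)) / x.std(0, ddof=1)
        u, s, vt = np.linalg.svd(z_train, full_matrices=False)
        lam = s ** 2 / (n - 1)
        a = max(int(np.sum(lam >= 2.0)), 1)
        load = vt[:a].T
        resid_train = z_train - (z_train @ load) @ load.T
        s0 = np.sqrt((resid_train ** 2).sum() / ((n - a - 1) * (p - a)))
        t2_lim = a * (n - 1) / (n - a) * stats.f.ppf(0.95, a, n - a)
        d_crit = np.sqrt(stats.f.ppf(0.95, p - a, (n - a - 1) * (p - a)))

        z = (y - x.mean(0)) / x.std(0, ddof=1)
        t = z @ load
        t2 = (t ** 2 / lam[:a]).sum(1)
        resid = z - t @ load.T
        dmodx = np.sqrt((resid ** 2).sum(1) / (p - a)) / s0
        inside = (t2 <= t2_lim) & (dmodx <= d_crit)

        # loadings sign flips cancel in both statistics
        np.testing.assert_allclose(ad.t2, t2, atol=1e-8)
        np.testing.assert_allclose(ad.dmodx, dmodx, atol=1e-8)
        np.testing.assert_array_equal(ad.inside, inside)

    def test_t2_invariant_under_rotation_of_pc_basis(self, rng):
        # rotating the retained score axes leaves the Mahalanobis form unchanged
        x = rng.normal(size=(50, 6))
        model = fit_pca(dm(x))
        a = model.n_significant
        scores = project(model, dm(x)).scores
        t2 = (scores ** 2 / model.eigenvalues[:a]).sum(1)
        # rotation in the metric induced by the eigenvalues
        w = scores / np.sqrt(model.eigenvalues[:a])
        q, _ = np.linalg.qr(rng.normal(size=(a, a)))
        np.testing.assert_allclose(((w @ q) ** 2).sum(1), t2, atol=1e-8)

    def test_training_set_mostly_inside_own_domain(self, rng):
        x = rng.normal(size=(120, 8))
        m = dm(x)
        ad = applicability_domain(fit_pca(m), m)
        assert ad.inside.mean() >= 0.85


class TestInitialFiltration:
    def test_union_of_disjoint_branches_adds_up(self):
        typical = {f"t{i}" for i in range(330)}
        atypical = {f"a{i}" for i in range(99)}
        res = FiltrationResult(typical, atypical)
        assert len(res.union) == 429
        assert len(res.overlap) == 0

    def test_overlap_counted_once(self):
        res = FiltrationResult({"a", "b"}, {"b", "c"})
        assert res.union == {"a", "b", "c"}
        assert res.overlap == {"b"}

    def test_identical_candidate_lands_in_typical_branch(self, rng):
        x = rng.normal(size=(30, 6)) + 5
        binders = dm(x)
        atypical = dm(rng.normal(size=(4, 6)) + 5)
        clone = DescriptorMatrix(["clone"], binders.names, x[0][None, :])
        res = initial_filtration(binders, atypical, clone)
        assert "clone" in res.typical_hits

    def test_monotone_in_atypical_ed_cutoff(self, rng):
        binders = dm(rng.normal(size=(25, 6)) + 10)
        atypical = dm(rng.normal(size=(5, 6)) + 10)
        cands = dm(rng.normal(size=(40, 6)) * 2 + 10)
        loose = initial_filtration(binders, atypical, cands, ed_cutoff_atypical=3.0)
        tight = initial_filtration(binders, atypical, cands, ed_cutoff_atypical=1.5)
        assert tight.atypical_hits <= loose.atypical_hits
        assert len(loose.union) <= 40

    def test_empty_reference_sets_rejected(self, rng):
        cands = dm(rng.normal(size=(5, 4)))
        empty = DescriptorMatrix([], cands.names, np.zeros((0, 4)))
        with pytest.raises(ValueError):
            initial_filtration(empty, cands, cands)
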