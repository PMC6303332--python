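"""REML likelihood, AI-REML fitting, surfaces and confidence regions."""

import numpy as np
import pytest
from scipy import linalg, stats

from heritvc.vc import (VarianceComponentsModel, aireml_fit,
                        confidence_region)


def naive_reml_loglik(y, X, V):
    """Independent dense-algebra oracle for the restricted log-likelihood.

    Uses an explicit orthonormal basis of the complement of col(X) (the
    'error contrast' formulation) instead of the projection-matrix identity
    used by the implementation.
    """
    n, p = X.shape
    Q, _ = np.linalg.qr(X, mode="complete")
    A = Q[:, p:]                        # n x (n-p), A'X = 0
    W = A.T @ V @ A
    z = A.T @ y
    sign, logdet = np.linalg.slogdet(W)
    return -0.5 * (logdet + z @ np.linalg.solve(W, z)) \
        - 0.5 * np.linalg.slogdet(X.T @ X)[1] * 0


def _family_components(n_fam=30, fam_size=2):
    """Block-family K with its (collinear) equicorrelation companion.

    Suitable for single-component tests; for joint K + D tests use
    :func:`_pedigree_components`, because with constant within-family
    correlations D is a linear combination of K and I and the pair is not
    jointly identifiable.
    """
    n = n_fam * fam_size
    K = np.kron(np.eye(n_fam), np.full((fam_size, fam_size), 0.5))
    np.fill_diagonal(K, 1.0)
    D = np.kron(np.eye(n_fam), np.full((fam_size, fam_size), 0.25))
    np.fill_diagonal(D, 1.0)
    return K, D


def _pedigree_components(seed=0, n_founders=80, gens=4, target=240):
    """K and D from the last two generations of a generated pedigree.

    Mixing parent-offspring pairs (K = 1/2, D = 0) with full sibs
    (K = 1/2, D = 1/4) and cousins makes the two components jointly
    well identified.
    """
    from heritvc.synth import generate_isolate_pedigree
    from heritvc.pedkin import pedigree_kd_matrices
    ped = generate_isolate_pedigree(n_founders, gens, mean_sibship=3.0,
                                    target_genotyped=target, seed=seed)
    members = np.flatnonzero(ped.generation >= gens - 2)[:target]
    return pedigree_kd_matrices(ped, members)


def _simulate(K_list, weights, sigma_e2, seed, X=None):
    n = K_list[0].shape[0]
    rng = np.random.default_rng(seed)
    V = sigma_e2 * np.eye(n)
    for w, K in zip(weights, K_list):
        V += w * K
    L = np.linalg.cholesky(V + 1e-10 * np.eye(n))
    y = L @ rng.standard_normal(n)
    if X is not None:
        y = y + X @ np.arange(1, X.shape[1] + 1)
    return y


class TestRemlLoglik:
    def test_iid_ridge(self):
        # with C = I the likelihood depends on tau + sigma_e2 only
        rng = np.random.default_rng(0)
        y = rng.standard_normal(40)
        m = VarianceComponentsModel(y, {"K": np.eye(40)})
        assert m.reml_loglik([0.3], 0.7) == pytest.approx(
            m.reml_loglik([0.6], 0.4), abs=1e-9)
        # and is maximized on the ridge at the residual variance
        vhat = y.var(ddof=1)
        best = m.reml_loglik([vhat / 2], vhat / 2)
        assert best > m.reml_loglik([vhat], vhat) - 1e-9
        assert best > m.reml_loglik([vhat / 4], vhat / 4) - 1e-9

    def test_invariant_to_fixed_effect_shift(self):
        rng = np.random.default_rng(1)
        K, D = _family_components()
        n = K.shape[0]
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = _simulate([K], [0.5], 0.5, seed=2)
        a = VarianceComponentsModel(y, {"K": K}, X).reml_loglik([0.4], 0.6)
        b = VarianceComponentsModel(y + X @ np.array([3.0, -2.0]),
                                    {"K": K}, X).reml_loglik([0.4], 0.6)
        assert a == pytest.approx(b, abs=1e-8)

    def test_agrees_with_error_contrast_oracle(self):
        rng = np.random.default_rng(3)
        n = 50
        K = rng.standard_normal((n, n))
        K = K @ K.T / n
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = rng.standard_normal(n)
        m = VarianceComponentsModel(y, {"K": K}, X)
        V = 0.7 * K + 0.5 * np.eye(n)
        got = m.reml_loglik([0.7], 0.5)
        want = naive_reml_loglik(y, X, V)
        # the two formulations differ by a y-independent constant
        got2 = m.reml_loglik([0.2], 1.1)
        want2 = naive_reml_loglik(y, X, 0.2 * K + 1.1 * np.eye(n))
        assert got - got2 == pytest.approx(want - want2, abs=1e-8)

    def test_singular_V_raises(self):
        y = np.arange(5.0)
        m = VarianceComponentsModel(y, {"K": np.ones((5, 5))})
        with pytest.raises(FloatingPointError):
            m.reml_loglik([1.0], 0.0)


class TestAIREML:
    def test_matches_grid_search(self):
        # N=60, 30 duplicate pairs: compare to nested 2-D grid refinement
        n = 60
        K = np.kron(np.eye(30), np.ones((2, 2)))
        y = _simulate([K], [0.6], 0.4, seed=4)
        m = VarianceComponentsModel(y, {"K": K})
        fit = m.fit()
        lo = np.array([1e-4, 1e-4])
        hi = np.array([2.0, 2.0])
        for _ in range(8):
            ts = np.linspace(lo[0], hi[0], 12)
            ss = np.linspace(lo[1], hi[1], 12)
            lls = [(m.reml_loglik([t], s), t, s) for t in ts for s in ss]
            _, t0, s0 = max(lls)
            span_t, span_s = (hi - lo) / 11
            lo = np.array([max(t0 - span_t, 1e-6), max(s0 - span_s, 1e-6)])
            hi = np.array([t0 + span_t, s0 + span_s])
        assert fit.tau[0] == pytest.approx(t0, abs=1e-4)
        assert fit.sigma_e2 == pytest.approx(s0, abs=1e-4)
        assert fit.converged

    def test_null_trait_pins_at_zero_boundary(self):
        rng = np.random.default_rng(5)
        n = 300
        G = rng.binomial(2, 0.3, (n, 500))
        from heritvc.grm import additive_grm
        K = additive_grm(G)
        h2 = []
        for rep in range(60):
            y = rng.standard_normal(n)
            fit = VarianceComponentsModel(y, {"K": K}).fit()
            h2.append(fit.h2["K"])
        h2 = np.asarray(h2)
        assert np.all(h2 >= 0.0)
        assert h2.mean() < 0.08

    def test_recovers_two_components(self):
        K, D = _pedigree_components(seed=6, n_founders=120, target=450)
        y = _simulate([K, D], [0.45, 0.3], 0.25, seed=6)
        fit = aireml_fit(y, {"K": K, "D": D})
        assert fit.converged
        assert fit.tau[0] == pytest.approx(0.45, abs=0.25)
        assert fit.h2["K"] + fit.h2["D"] + \
            fit.sigma_e2 / fit.total_variance == pytest.approx(1.0)

    def test_nonconvergence_reported_not_raised(self):
        K, _ = _family_components()
        y = _simulate([K], [0.5], 0.5, seed=7)
        fit = VarianceComponentsModel(y, {"K": K}).fit(max_iter=1)
        assert fit.converged in (True, False)   # no exception either way

    def test_summary_mentions_model_and_estimates(self):
        K, D = _family_components()
        y = _simulate([K, D], [0.4, 0.2], 0.4, seed=8)
        fit = aireml_fit(y, {"K": K, "D": D})
        text = fit.summary()
        assert "model KD" in text
        assert "H2" in text

    def test_from_dataframe(self):
        import pandas as pd
        K, _ = _family_components()
        y = _simulate([K], [0.5], 0.5, seed=9)
        df = pd.DataFrame({"trait": y, "age": np.linspace(20, 70, y.size)})
        m = VarianceComponentsModel.from_dataframe(df, "trait", {"K": K},
                                                   covariates=["age"])
        assert m.p == 2
        assert m.fit().converged


class TestLikelihoodSurface:
    def _model(self, h2a, h2d, seed, **kw):
        K, D = _pedigree_components(seed=1, **kw)
        y = _simulate([K, D], [h2a, h2d], 1 - h2a - h2d, seed=seed)
        return VarianceComponentsModel(y, {"K": K, "D": D})

    def test_argmax_matches_aireml(self):
        m = self._model(0.4, 0.3, seed=10)
        fit = m.fit()
        surf = m.likelihood_surface(grid_step=0.02)
        a, d = surf.argmax
        assert abs(a - fit.h2["K"]) <= 0.02 + 1e-9
        assert abs(d - fit.h2["D"]) <= 0.02 + 1e-9
        # surface maximum cannot exceed the free optimum (same constant)
        assert surf.max_loglik <= fit.loglik + 1e-4

    def test_boundary_truth(self):
        m = self._model(0.45, 0.0, seed=11)
        surf = m.likelihood_surface(grid_step=0.05)
        _, d = surf.argmax
        assert d <= 0.1

    def test_requires_two_components(self):
        K, _ = _family_components()
        y = _simulate([K], [0.5], 0.5, seed=12)
        m = VarianceComponentsModel(y, {"K": K})
        with pytest.raises(ValueError):
            m.likelihood_surface()

    def test_bad_grid_step(self):
        m = self._model(0.3, 0.3, seed=13)
        with pytest.raises(ValueError):
            m.likelihood_surface(grid_step=0.0)


class TestConfidenceRegion:
    def test_contains_argmax_and_limits(self):
        K, D = _pedigree_components(seed=2, n_founders=60, target=180)
        y = _simulate([K, D], [0.4, 0.2], 0.4, seed=14)
        surf = VarianceComponentsModel(y, {"K": K, "D": D}) \
            .likelihood_surface(grid_step=0.05)
        mask = surf.confidence_region(0.95)
        k = np.argmax(surf.loglik)
        assert mask[k]
        # level -> 1 limit: once the chi-square threshold exceeds the
        # observed likelihood range, every evaluable node is covered
        # (corners where the covariance degenerates have -inf loglik)
        from scipy import stats as sps
        finite = np.isfinite(surf.loglik)
        span = 2 * (surf.max_loglik - surf.loglik[finite].min())
        high = sps.chi2.cdf(span + 1.0, df=2)
        assert confidence_region(surf, high)[finite].all()
        # and the region grows with the level
        assert confidence_region(surf, 0.99).sum() >= mask.sum()
        with pytest.raises(ValueError):
            confidence_region(surf, 1.5)

    def test_nominal_coverage(self):
        # strong pedigree structure, truth on a grid node
        K, D = _pedigree_components(seed=3, n_founders=100, target=300)
        truth = (0.40, 0.30)
        hits = 0
        n_rep = 150
        rng_seed = 100
        for r in range(n_rep):
            y = _simulate([K, D], list(truth), 1 - sum(truth),
                          seed=rng_seed + r)
            surf = VarianceComponentsModel(y, {"K": K, "D": D}) \
                .likelihood_surface(grid_step=0.05)
            mask = surf.confidence_region(0.95)
            node = (np.isclose(surf.h2a, truth[0]) &
                    np.isclose(surf.h2d, truth[1]))
            hits += bool(mask[node][0])
        cover = hits / n_rep
        se = np.sqrt(0.95 * 0.05 / n_rep)
        assert abs(cover - 0.95) < 4 * se
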