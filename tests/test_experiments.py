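"""Experiment batteries, MLE clouds and minimal ellipses."""

import numpy as np
import pandas as pd
import pytest

from heritvc.experiments import (Ellipse, ExperimentConfig, PanelRecipe,
                                 PopulationRecipe, build_population,
                                 log_m_grid, minimal_ellipse_95, mle_cloud,
                                 relatedness_matrices, run_battery,
                                 summarize_battery)


TINY_PANEL = PanelRecipe(n_haplotypes=80, n_sites=1500, n_chromosomes=2)
TINY_ISOLATE = PopulationRecipe(kind="isolate", n_genotyped=60, n_founders=60,
                                n_generations=5, pool_subset_size=40)


class TestConfig:
    def test_invalid_model_name_rejected(self):
        with pytest.raises(ValueError):
            ExperimentConfig(models=("KDX",))

    def test_duplicate_component_rejected(self):
        with pytest.raises(ValueError):
            ExperimentConfig(models=("KK",))

    def test_log_m_grid_spans_range(self):
        g = log_m_grid(12)
        assert g[0] == 1 and g[-1] == 1_000_000
        assert len(g) <= 12


class TestPopulations:
    def test_outbred_label_and_size(self):
        pop = build_population(PopulationRecipe(kind="outbred",
                                                n_genotyped=25),
                               TINY_PANEL, seed=1)
        assert pop.cohort.label == "Outbred(25)"
        assert pop.pedigree is None

    def test_isolate_with_replication_and_nosibs(self):
        rec = PopulationRecipe(kind="isolate", n_genotyped=30, n_founders=40,
                               n_generations=4, k=2, nosibs=True,
                               pool_subset_size=40)
        pop = build_population(rec, TINY_PANEL, seed=2)
        assert pop.pedigree is not None
        assert pop.cohort.n < 60          # sibs removed
        S, labels = pop.sibship()
        assert np.array_equal(S, np.eye(pop.cohort.n))  # no sib left

    def test_matrix_methods_share_interface(self):
        pop = build_population(TINY_ISOLATE, TINY_PANEL, seed=3)
        for method in ("grm", "pedigree", "true_ibd"):
            mats = relatedness_matrices(pop, method, maf_threshold=0.01)
            assert mats.K.shape == (pop.cohort.n,) * 2
            assert np.allclose(mats.K, mats.K.T)
            assert np.allclose(mats.D, mats.D.T)

    def test_eigenvalue_variance_isolate_exceeds_outbred(self):
        from heritvc.grm import eigenvalue_variance
        iso = build_population(TINY_ISOLATE, TINY_PANEL, seed=4)
        out = build_population(PopulationRecipe(kind="outbred",
                                                n_genotyped=60),
                               TINY_PANEL, seed=4)
        Ki = relatedness_matrices(iso, "grm", maf_threshold=0.01).K
        Ko = relatedness_matrices(out, "grm", maf_threshold=0.01).K
        assert eigenvalue_variance(Ki) > eigenvalue_variance(Ko)


class TestBattery:
    CFG = ExperimentConfig(population=TINY_ISOLATE, panel=TINY_PANEL,
                           M_grid=(30,), models=("K", "KD"), replicates=3,
                           seed=5, maf_threshold=0.01)

    def test_rows_and_determinism(self):
        a = run_battery(self.CFG)
        b = run_battery(self.CFG)
        assert len(a) == 3 * 2
        assert (a["error"] == "").all()
        pd.testing.assert_frame_equal(a, b)
        assert {"h2A_hat", "h2D_hat", "loglik", "converged"} <= set(a.columns)

    def test_summary_aggregation(self):
        df = run_battery(self.CFG)
        summ = summarize_battery(df)
        assert {"h2A_hat_mean", "h2A_hat_se", "n_ok"} <= set(summ.columns)
        assert (summ["n_ok"] == 3).all()

    def test_precision_improves_with_isolate_replication(self):
        # stacking independent gene-drop copies (k = 1 -> 3) shrinks the
        # spread of the per-replicate dominance estimates
        spreads = {}
        for k in (1, 3):
            pop_recipe = PopulationRecipe(kind="isolate", n_genotyped=120,
                                          n_founders=120, n_generations=5,
                                          k=k, pool_subset_size=60)
            cfg = ExperimentConfig(population=pop_recipe, panel=TINY_PANEL,
                                   M_grid=(60,), models=("KD",),
                                   replicates=12, seed=21,
                                   maf_threshold=0.02)
            df = run_battery(cfg)
            ok = df[df["error"] == ""]
            spreads[k] = ok["h2D_hat"].std(ddof=1)
        assert spreads[3] < spreads[1]

    def test_mle_cloud(self):
        cfg = ExperimentConfig(population=TINY_ISOLATE, panel=TINY_PANEL,
                               M_grid=(30,), models=("KD",), replicates=6,
                               seed=6, maf_threshold=0.01)
        df = run_battery(cfg)
        cloud = mle_cloud(df)
        assert len(cloud.points) == 6
        assert cloud.ellipse is not None
        inside = cloud.ellipse.contains(
            cloud.points[["h2A_hat", "h2D_hat"]].to_numpy())
        assert inside.mean() >= 0.95


class TestConfoundingStudy:
    def test_grid_and_models_present(self):
        from heritvc.experiments import confounding_study
        cfg = ExperimentConfig(population=TINY_ISOLATE, panel=TINY_PANEL,
                               M_grid=(30,), replicates=2, seed=7,
                               maf_threshold=0.01)
        df = confounding_study(cfg, h2S_values=(0.0, 0.2),
                               matrix_methods=("grm",))
        assert set(df["model"]) == {"KD", "KDS"}
        assert set(df["h2S_sim"]) == {0.0, 0.2}
        assert (df["error"] == "").all()


def mvee_sqp_oracle(points):
    """Independent minimum-area enclosing ellipse via constrained
    optimisation on the convex hull (SLSQP on the Cholesky factor)."""
    from scipy.optimize import minimize
    from scipy.spatial import ConvexHull
    hull = points[ConvexHull(points).vertices]

    def unpack(x):
        c = x[:2]
        L = np.array([[x[2], 0.0], [x[3], x[4]]])
        return c, L @ L.T

    def neg_logdet(x):
        _, A = unpack(x)
        sign, ld = np.linalg.slogdet(A)
        return -ld if sign > 0 else 1e6

    def constraints(x):
        c, A = unpack(x)
        q = np.einsum("ni,ij,nj->n", hull - c, A, hull - c)
        return 1.0 - q

    c0 = hull.mean(axis=0)
    C0 = np.linalg.inv(np.cov(hull.T) * 4)
    L0 = np.linalg.cholesky(C0)
    x0 = np.array([c0[0], c0[1], L0[0, 0], L0[1, 0], L0[1, 1]])
    res = minimize(neg_logdet, x0, constraints={"type": "ineq",
                                                "fun": constraints},
                   method="SLSQP", options={"maxiter": 500, "ftol": 1e-12})
    _, A = unpack(res.x)
    ev = np.linalg.eigvalsh(A)
    return float(np.pi / np.sqrt(ev[0] * ev[1]))


class TestMinimalEllipse:
    def test_identical_points_zero_area(self):
        pts = np.tile([0.3, 0.4], (20, 1))
        ell = minimal_ellipse_95(pts)
        assert ell.degenerate
        assert ell.area == 0.0

    def test_collinear_degenerates_to_segment(self):
        t = np.linspace(0, 1, 40)
        pts = np.column_stack([t, 2 * t + 1])
        ell = minimal_ellipse_95(pts)
        assert ell.degenerate
        assert ell.half_length > 0

    def test_gaussian_cloud_contains_95_percent(self):
        rng = np.random.default_rng(7)
        pts = rng.standard_normal((1000, 2))
        ell = minimal_ellipse_95(pts)
        assert not ell.degenerate
        assert ell.contains(pts).sum() >= 950

    def test_area_matches_independent_oracle(self):
        rng = np.random.default_rng(8)
        pts = rng.standard_normal((400, 2)) @ np.array([[1.0, 0.4],
                                                        [0.0, 0.7]])
        ell = minimal_ellipse_95(pts)
        # rebuild the survivor set exactly as the implementation defines it
        center = pts.mean(axis=0)
        Ci = np.linalg.inv(np.cov(pts.T))
        d2 = np.einsum("ni,ij,nj->n", pts - center, Ci, pts - center)
        survivors = pts[np.argsort(d2)[: 400 - 20]]
        oracle_area = mvee_sqp_oracle(survivors)
        assert ell.area == pytest.approx(oracle_area, rel=0.10)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            minimal_ellipse_95(np.zeros((3, 2)))
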