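"""Replicated simulation-estimation experiments.

This module wires the generators and the variance-components model into the
replicated experiment batteries of the study design: simulate a population
(isolate by pedigree gene-dropping, or outbred by independent mosaic
copying), build K/D relatedness matrices by one of three routes (GRM,
pedigree expectation, true IBD), simulate phenotype replicates over a grid
of causal-variant counts M, fit the requested LMMs, and aggregate the
maximum-likelihood estimates into clouds with empirical means, standard
errors and minimal 95% ellipses on the (h2_A, h2_D) simplex.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import genedrop, grm as grm_mod, mosaic, pedkin, phenosim, synth
from .vc import VarianceComponentsModel

__all__ = [
    "PanelRecipe",
    "PopulationRecipe",
    "ExperimentConfig",
    "StudyPopulation",
    "RelatednessSet",
    "make_panel",
    "build_population",
    "relatedness_matrices",
    "run_battery",
    "summarize_battery",
    "confounding_study",
    "log_m_grid",
    "minimal_ellipse_95",
    "Ellipse",
    "MLECloud",
    "mle_cloud",
]


# ---------------------------------------------------------------------------
# Recipes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PanelRecipe:
    """Reference panel dimensions (split evenly across chromosomes)."""

    n_haplotypes: int = 600
    n_sites: int = 20_000
    n_chromosomes: int = 2
    sfs_shape: float | None = None   # None = calibrated per pool size
    chrom_length_bp: int = 100_000_000
    rate_cm_per_mb: float = 1.0


@dataclass(frozen=True)
class PopulationRecipe:
    """How to construct the analysed cohort."""

    kind: str = "isolate"            # "isolate" | "outbred"
    n_genotyped: int = 1000          # per gene-drop copy / outbred total
    k: int = 1                       # stacked independent copies
    nosibs: bool = False             # discard one member of each sib pair
    n_founders: int = 1000
    n_generations: int = 8
    mean_sibship: float = 3.0
    pool_subset_size: int = 200
    switch_intensity: float = mosaic.DEFAULT_SWITCH_INTENSITY


@dataclass(frozen=True)
class ExperimentConfig:
    """One replicated battery: population x matrices x phenotypes x models."""

    population: PopulationRecipe = PopulationRecipe()
    panel: PanelRecipe = PanelRecipe()
    matrix_method: str = "grm"       # "grm" | "pedigree" | "true_ibd"
    M_grid: tuple = (1000,)
    scenario: str = "A"
    h2A: float = 0.4
    h2D: float = 0.4
    h2S: float = 0.0
    models: tuple = ("KD",)
    replicates: int = 100
    seed: int = 0
    maf_threshold: float = 0.05
    hwe_threshold: float = 1e-5

    def __post_init__(self):
        for m in self.models:
            if not m or any(ch not in "KDS" for ch in m) or \
                    len(set(m)) != len(m):
                raise ValueError(f"invalid model name {m!r}: use subsets "
                                 "of the letters K, D, S")
        if any(M < 1 for M in self.M_grid):
            raise ValueError("M grid entries must be positive")


def log_m_grid(n_values: int = 12, lo: int = 1, hi: int = 1_000_000) -> tuple:
    """Log-uniform grid of causal-variant counts between lo and hi."""
    g = np.unique(np.round(np.geomspace(lo, hi, n_values)).astype(int))
    return tuple(int(v) for v in g)


# ---------------------------------------------------------------------------
# Population construction
# ---------------------------------------------------------------------------

@dataclass
class StudyPopulation:
    """A constructed cohort plus the structures needed to analyse it."""

    cohort: mosaic.Cohort
    pools: list
    pedigree: synth.Pedigree | None = None

    @property
    def label(self) -> str:
        return self.cohort.label

    def sibship(self) -> tuple[np.ndarray, np.ndarray]:
        """(S matrix, integer sibship labels) for the cohort members."""
        n = self.cohort.n
        if self.pedigree is None:
            return np.eye(n), np.arange(n)
        rows, tags = genedrop.cohort_pedigree_rows(self.cohort, self.pedigree)
        labels = np.empty(n, dtype=np.int64)
        keys: dict = {}
        for k, (r, t) in enumerate(zip(rows.tolist(), tags.tolist())):
            f, m = int(self.pedigree.father[r]), int(self.pedigree.mother[r])
            key = (t, f, m) if f >= 0 else ("solo", t, k)
            labels[k] = keys.setdefault(key, len(keys))
        S = (labels[:, None] == labels[None, :]).astype(float)
        return S, labels


def make_panel(recipe: PanelRecipe, seed) -> list:
    """Generate one reference pool per chromosome."""
    rng = np.random.default_rng(seed)
    per = np.full(recipe.n_chromosomes,
                  recipe.n_sites // recipe.n_chromosomes)
    per[: recipe.n_sites % recipe.n_chromosomes] += 1
    return [synth.generate_reference_pool(
        recipe.n_haplotypes, int(m), recipe.sfs_shape, seed=rng,
        chrom_length_bp=recipe.chrom_length_bp,
        rate_cm_per_mb=recipe.rate_cm_per_mb) for m in per]


def build_population(pop: PopulationRecipe, panel: PanelRecipe | list,
                     seed) -> StudyPopulation:
    """Construct the cohort named by a population recipe."""
    rng = np.random.default_rng(seed)
    pools = panel if isinstance(panel, list) else make_panel(panel, rng)
    if pop.kind == "outbred":
        cohort = mosaic.simulate_outbred_cohort(
            pools, pop.n_genotyped * pop.k, pop.switch_intensity, seed=rng)
        return StudyPopulation(cohort, pools)
    if pop.kind != "isolate":
        raise ValueError(f"unknown population kind {pop.kind!r}")
    pedigree = synth.generate_isolate_pedigree(
        pop.n_founders, pop.n_generations, pop.mean_sibship,
        pop.n_genotyped, seed=rng)
    recipe = genedrop.IsolateRecipe(pedigree, pools, pop.pool_subset_size,
                                    pop.switch_intensity)
    cohort = genedrop.replicate_isolates(recipe, pop.k, seed=rng)
    if pop.nosibs:
        cohort = genedrop.drop_one_sib_per_pair(cohort, pedigree, seed=rng)
    return StudyPopulation(cohort, pools, pedigree)


# ---------------------------------------------------------------------------
# Relatedness matrices
# ---------------------------------------------------------------------------

@dataclass
class RelatednessSet:
    """K, D (and optionally S) under one interface whatever the estimator."""

    K: np.ndarray
    D: np.ndarray
    S: np.ndarray | None = None
    method: str = ""
    m_variants: int | None = None

    def components_for(self, model_name: str) -> dict:
        out = {}
        for ch in model_name:
            mat = getattr(self, ch)
            if mat is None:
                raise ValueError(f"component {ch} unavailable")
            out[ch] = mat
        return out


def relatedness_matrices(population: StudyPopulation, method: str = "grm",
                         maf_threshold: float = 0.05,
                         hwe_threshold: float = 1e-5) -> RelatednessSet:
    """Estimate K and D for a study population by the requested route.

    "grm": method-of-moments matrices from QC-passing common variants;
    "pedigree": expected values from the genealogy; "true_ibd": exact
    realised IBD sharing from the recorded origin labels.
    """
    cohort = population.cohort
    S, _ = population.sibship()
    if method == "grm":
        qc = grm_mod.variant_qc(cohort.genotypes, maf_threshold, hwe_threshold)
        K = grm_mod.additive_grm(cohort.genotypes, qc)
        D = grm_mod.dominance_grm(cohort.genotypes, qc)
        return RelatednessSet(K, D, S, "grm", qc.m_kept)
    if method == "pedigree":
        if population.pedigree is None:
            raise ValueError("pedigree matrices need a pedigree")
        rows, tags = genedrop.cohort_pedigree_rows(cohort, population.pedigree)
        Kp, Dp = pedkin.pedigree_kd_matrices(population.pedigree, rows)
        # members of different replicate copies are unrelated by construction
        same = tags[:, None] == tags[None, :]
        K = np.where(same, Kp, 0.0)
        D = np.where(same, Dp, 0.0)
        np.fill_diagonal(K, np.diag(Kp))
        np.fill_diagonal(D, 1.0)
        return RelatednessSet(K, D, S, "pedigree")
    if method == "true_ibd":
        ibd = genedrop.true_ibd_matrices(cohort)
        return RelatednessSet(ibd.K_true, ibd.D_true, S, "true_ibd")
    raise ValueError(f"unknown matrix method {method!r}")


# ---------------------------------------------------------------------------
# Batteries
# ---------------------------------------------------------------------------

def run_battery(config: ExperimentConfig,
                population: StudyPopulation | None = None,
                matrices: RelatednessSet | None = None) -> pd.DataFrame:
    """Run one replicated battery; one row per M x replicate x model.

    Deterministic given ``config.seed``.  Any per-replicate failure is
    recorded in the row's ``error`` column and the battery continues.  A
    prebuilt population / relatedness set may be passed to share them
    between batteries.
    """
    root = np.random.SeedSequence(config.seed)
    pop_seed, mat_seed, pheno_root = root.spawn(3)
    if population is None:
        population = build_population(config.population, config.panel, pop_seed)
    if matrices is None:
        matrices = relatedness_matrices(population, config.matrix_method,
                                        config.maf_threshold,
                                        config.hwe_threshold)
    _, sib_labels = population.sibship()

    rows = []
    pheno_seeds = pheno_root.spawn(len(config.M_grid) * config.replicates)
    k = 0
    for M in config.M_grid:
        spec = phenosim.PhenotypeSpec(M=M, scenario=config.scenario,
                                      h2A=config.h2A, h2D=config.h2D,
                                      h2S=config.h2S)
        for rep in range(config.replicates):
            seed = pheno_seeds[k]
            k += 1
            base = dict(population=population.label, M=M,
                        scenario=config.scenario,
                        matrix_method=matrices.method, replicate=rep)
            try:
                ph = phenosim.simulate_phenotype(
                    population.cohort, spec, sibship_labels=sib_labels,
                    seed=seed)
            except Exception as err:   # pragma: no cover - defensive
                for model_name in config.models:
                    rows.append({**base, "model": model_name,
                                 "error": str(err)})
                continue
            for model_name in config.models:
                row = {**base, "model": model_name, "error": ""}
                try:
                    fit = VarianceComponentsModel(
                        ph.Y, matrices.components_for(model_name)).fit()
                    h2 = fit.h2
                    row.update(h2A_hat=h2.get("K", 0.0),
                               h2D_hat=h2.get("D", 0.0),
                               h2S_hat=h2.get("S", 0.0),
                               H2_hat=h2.get("K", 0.0) + h2.get("D", 0.0),
                               sigma_e2=fit.sigma_e2, loglik=fit.loglik,
                               converged=fit.converged, n_iter=fit.n_iter)
                except Exception as err:
                    row["error"] = str(err)
                rows.append(row)
    return pd.DataFrame(rows)


def summarize_battery(df: pd.DataFrame,
                      by=("population", "matrix_method", "model", "M")
                      ) -> pd.DataFrame:
    """Mean and empirical SE of the estimates per battery cell."""
    ok = df[df["error"] == ""].copy()
    cols = [c for c in ("h2A_hat", "h2D_hat", "h2S_hat", "H2_hat") if c in ok]
    g = ok.groupby(list(by))[cols]
    mean = g.mean().add_suffix("_mean")
    se = (g.std(ddof=1) / np.sqrt(g.count())).add_suffix("_se")
    out = mean.join(se)
    out["n_ok"] = g.size()
    return out.reset_index()


def confounding_study(config: ExperimentConfig,
                      h2S_values=(0.0, 0.02, 0.05, 0.10, 0.20, 0.40),
                      matrix_methods=("grm", "pedigree"),
                      population: StudyPopulation | None = None
                      ) -> pd.DataFrame:
    """Sibling shared-environment confounding: models KD vs KDS.

    For each h2_S, phenotypes are simulated with h2_A = 0.4 and
    h2_D = 0.4 - h2_S plus sibling environmental covariance, then fitted
    with and without the sibship component, for each matrix estimation
    route.  The returned table lets one read off the broad-sense inflation
    of the unadjusted model KD and its correction under model KDS.
    """
    root = np.random.SeedSequence(config.seed)
    pop_seed, *_ = root.spawn(1)
    if population is None:
        population = build_population(config.population, config.panel,
                                      pop_seed)
    mats = {m: relatedness_matrices(population, m, config.maf_threshold,
                                    config.hwe_threshold)
            for m in matrix_methods}
    frames = []
    for i, h2S in enumerate(h2S_values):
        for method in matrix_methods:
            sub = ExperimentConfig(
                population=config.population, panel=config.panel,
                matrix_method=method, M_grid=config.M_grid,
                scenario=config.scenario, h2A=0.4, h2D=0.4 - h2S, h2S=h2S,
                models=("KD", "KDS"), replicates=config.replicates,
                seed=config.seed + 1000 * i + 1)
            out = run_battery(sub, population=population,
                              matrices=mats[method])
            out["h2S_sim"] = h2S
            frames.append(out)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# MLE clouds and minimal ellipses
# ---------------------------------------------------------------------------

@dataclass
class Ellipse:
    """An ellipse {x : (x - center)' A (x - center) <= 1} in the plane."""

    center: np.ndarray
    A: np.ndarray | None
    degenerate: bool = False
    axis_direction: np.ndarray | None = None   # for degenerate segments
    half_length: float = 0.0

    @property
    def radii(self) -> np.ndarray:
        """Semi-axis lengths (descending)."""
        if self.degenerate or self.A is None:
            return np.array([self.half_length, 0.0])
        ev = np.linalg.eigvalsh(self.A)
        return np.sort(1.0 / np.sqrt(ev))[::-1]

    @property
    def area(self) -> float:
        r = self.radii
        return float(np.pi * r[0] * r[1])

    def contains(self, points: np.ndarray, rtol: float = 1e-9) -> np.ndarray:
        pts = np.atleast_2d(points) - self.center
        if self.degenerate or self.A is None:
            d = self.axis_direction
            along = pts @ d
            across = pts - np.outer(along, d)
            return (np.abs(along) <= self.half_length * (1 + rtol)) & \
                (np.linalg.norm(across, axis=1) <= 1e-9 + rtol)
        q = np.einsum("ni,ij,nj->n", pts, self.A, pts)
        return q <= 1.0 + rtol


def _mvee(points: np.ndarray, tol: float = 1e-7,
          max_iter: int = 100_000) -> Ellipse:
    """Minimum-volume enclosing ellipse by Khachiyan's barycentric updates."""
    P = np.asarray(points, dtype=float)
    n, d = P.shape
    Q = np.column_stack([P, np.ones(n)]).T          # (d+1, n)
    u = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        V = Q @ (u[:, None] * Q.T)
        try:
            M = np.einsum("ij,ji->i", Q.T, np.linalg.solve(V, Q))
        except np.linalg.LinAlgError:
            break
        j = int(np.argmax(M))
        mx = M[j]
        step = (mx - d - 1.0) / ((d + 1.0) * (mx - 1.0))
        new_u = (1.0 - step) * u
        new_u[j] += step
        if np.linalg.norm(new_u - u) < tol:
            u = new_u
            break
        u = new_u
    center = P.T @ u
    cov = P.T @ (u[:, None] * P) - np.outer(center, center)
    if np.linalg.matrix_rank(cov, tol=1e-12) < d:
        return _degenerate_segment(P)
    A = np.linalg.inv(cov) / d
    # rescale so every input point is inside despite finite tolerance
    q = np.einsum("ni,ij,nj->n", P - center, A, P - center)
    A = A / max(float(q.max()), 1.0)
    return Ellipse(center, A)


def _degenerate_segment(P: np.ndarray) -> Ellipse:
    center = P.mean(axis=0)
    X = P - center
    if np.allclose(X, 0):
        return Ellipse(center, None, degenerate=True,
                       axis_direction=np.array([1.0, 0.0]), half_length=0.0)
    _, _, vt = np.linalg.svd(X, full_matrices=False)
    d = vt[0]
    along = X @ d
    return Ellipse(center, None, degenerate=True, axis_direction=d,
                   half_length=float(np.abs(along).max()))


def minimal_ellipse_95(points: np.ndarray, tol: float = 1e-7) -> Ellipse:
    """Minimal ellipse containing 95% of a 2-D point cloud.

    The 5% of points with the largest Mahalanobis distance from the sample
    mean are discarded, then the minimum-area enclosing ellipse of the
    survivors is computed (Khachiyan's algorithm, tolerance ``tol``).
    Collinear survivors yield a degenerate segment, flagged on the result.
    """
    P = np.asarray(points, dtype=float)
    if P.ndim != 2 or P.shape[1] != 2:
        raise ValueError("points must be (n, 2)")
    n = P.shape[0]
    if n < 5:
        raise ValueError("need at least 5 points")
    center = P.mean(axis=0)
    cov = np.cov(P.T)
    if np.linalg.matrix_rank(np.atleast_2d(cov), tol=1e-12) < 2:
        return _degenerate_segment(P)
    Ci = np.linalg.inv(cov)
    d2 = np.einsum("ni,ij,nj->n", P - center, Ci, P - center)
    n_drop = int(np.floor(0.05 * n))
    keep = np.argsort(d2)[: n - n_drop]
    return _mvee(P[keep], tol=tol)


@dataclass
class MLECloud:
    """Replicate MLEs with empirical summaries and the 95% ellipse."""

    points: pd.DataFrame
    mean: pd.Series
    se: pd.Series
    ellipse: Ellipse = field(default=None)


def mle_cloud(df: pd.DataFrame,
              params=("h2A_hat", "h2D_hat", "h2S_hat", "H2_hat")) -> MLECloud:
    """Aggregate a battery's rows (single cell) into an MLE cloud."""
    ok = df[df["error"] == ""]
    cols = [p for p in params if p in ok.columns]
    pts = ok[cols]
    mean = pts.mean()
    se = pts.std(ddof=1) / np.sqrt(len(pts))
    ell = None
    if {"h2A_hat", "h2D_hat"} <= set(cols) and len(pts) >= 5:
        ell = minimal_ellipse_95(pts[["h2A_hat", "h2D_hat"]].to_numpy())
    return MLECloud(pts, mean, se, ell)
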