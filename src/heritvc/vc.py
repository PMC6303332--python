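"""Multi-component REML variance decomposition of a quantitative trait.

The model is the standard variance-component linear mixed model

    Y ~ MVN(X b,  sum_c tau_c C_c + sigma_E^2 I_N)

where each C_c is a named N x N covariance structure - an additive
relationship matrix K, a dominance matrix D, a sibship indicator S, or any
other positive semi-definite structure - and the model name is the
concatenation of the component names (model K, KD, KS, KDS, ...).
Heritability fractions follow from the variance estimates:

    h2_c = tau_c / (sum_c tau_c + sigma_E^2),   H2 = (tau_A + tau_D) / (...)

Fitting is by restricted maximum likelihood with average-information
(quasi-Newton) updates, step-halving and an EM fallback, and non-negativity
enforced by projection: a component pinned at zero is reported as exactly
zero.  For the two-component K + D model the full restricted likelihood
surface over the (h2_A, h2_D) simplex is available with the overall variance
scale and fixed effects profiled out analytically, along with
likelihood-ratio confidence regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, stats

__all__ = [
    "VarianceComponentsModel",
    "VarianceComponentsResults",
    "LikelihoodSurface",
    "aireml_fit",
    "confidence_region",
]


class VarianceComponentsModel:
    """Variance-components LMM for one trait.

    Parameters
    ----------
    y : array, shape (N,)
        Phenotype vector.
    components : mapping of str -> array (N, N)
        Named covariance structures (order preserved; the residual identity
        component is implicit and always last).
    X : array (N, p), optional
        Fixed-effect design; defaults to an intercept column.  Must have
        full column rank.
    """

    def __init__(self, y, components, X=None):
        self.y = np.asarray(y, dtype=np.float64).ravel()
        n = self.y.size
        if X is None:
            X = np.ones((n, 1))
        self.X = np.asarray(X, dtype=np.float64)
        if self.X.ndim == 1:
            self.X = self.X[:, None]
        if self.X.shape[0] != n:
            raise ValueError("X and y have incompatible shapes")
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValueError("fixed-effect design X is rank deficient")
        self.names = list(components)
        self.components = []
        for name in self.names:
            C = np.asarray(components[name], dtype=np.float64)
            if C.shape != (n, n):
                raise ValueError(f"component {name!r} is not {n}x{n}")
            if not np.allclose(C, C.T, atol=1e-8):
                raise ValueError(f"component {name!r} is not symmetric")
            self.components.append(C)
        self.n = n
        self.p = self.X.shape[1]

    @classmethod
    def from_dataframe(cls, data, response: str, components,
                       covariates: list[str] | None = None):
        """Build from a DataFrame (adds an intercept plus listed covariates)."""
        y = data[response].to_numpy(dtype=float)
        X = np.ones((len(data), 1))
        if covariates:
            X = np.column_stack([X, data[list(covariates)].to_numpy(dtype=float)])
        return cls(y, components, X)

    @property
    def model_name(self) -> str:
        return "".join(self.names)

    # ------------------------------------------------------------------
    # restricted likelihood machinery
    # ------------------------------------------------------------------

    def _build_V(self, theta: np.ndarray) -> np.ndarray:
        V = np.diag(np.full(self.n, theta[-1]))
        for t, C in zip(theta[:-1], self.components):
            if t != 0.0:
                V += t * C
        return V

    def _reml_parts(self, theta: np.ndarray):
        """Return (loglik, P, Py) for the REML projection at theta."""
        V = self._build_V(theta)
        try:
            cho = linalg.cho_factor(V, lower=True, check_finite=False)
        except linalg.LinAlgError as err:
            raise FloatingPointError(
                "covariance matrix is singular at the requested parameters"
            ) from err
        logdet_V = 2.0 * np.log(np.diag(cho[0])).sum()
        Vi = linalg.cho_solve(cho, np.eye(self.n), check_finite=False)
        ViX = Vi @ self.X
        XtViX = self.X.T @ ViX
        sign, logdet_X = np.linalg.slogdet(XtViX)
        if sign <= 0:
            raise FloatingPointError("X' V^-1 X is not positive definite")
        P = Vi - ViX @ np.linalg.solve(XtViX, ViX.T)
        Py = P @ self.y
        ll = -0.5 * (logdet_V + logdet_X + self.y @ Py)
        return ll, P, Py

    def reml_loglik(self, tau, sigma_e2: float) -> float:
        """Restricted log-likelihood (up to an additive constant).

        Equals -1/2 [log|V| + log|X'V^-1 X| + y'Py] with P the REML
        projection; invariant to translations of y inside the column space
        of X.
        """
        tau = np.atleast_1d(np.asarray(tau, dtype=float))
        if tau.size != len(self.components):
            raise ValueError("tau has wrong length for this model")
        theta = np.append(tau, float(sigma_e2))
        ll, _, _ = self._reml_parts(theta)
        return float(ll)

    # ------------------------------------------------------------------
    # AI-REML
    # ------------------------------------------------------------------

    def fit(self, init=None, max_iter: int = 200, tol: float = 1e-6,
            verbose: bool = False) -> "VarianceComponentsResults":
        """Fit by average-information REML.

        Starts from an equal split of the phenotypic variance unless
        ``init`` (tau_1..tau_c, sigma_E^2) is given.  Each iteration takes
        an AI (quasi-Newton) step, falling back to step-halving and then to
        an EM update whenever the step would decrease the restricted
        likelihood or leave the feasible region; variance components are
        constrained non-negative by projection and a component pinned at the
        zero boundary is reported as exactly 0.  Convergence: successive
        log-likelihood change below ``tol``.  Non-convergence within
        ``max_iter`` is reported via ``converged=False``, not an exception.
        """
        c = len(self.components)
        # phenotypic variance from the OLS residual
        beta0, *_ = np.linalg.lstsq(self.X, self.y, rcond=None)
        resid = self.y - self.X @ beta0
        vp = float(resid @ resid) / max(self.n - self.p, 1)
        if vp <= 0:
            raise ValueError("phenotype has no residual variance")
        floor = 1e-8 * vp
        e_floor = 1e-6 * vp

        theta = np.full(c + 1, vp / (c + 1.0)) if init is None \
            else np.asarray(init, dtype=float).copy()
        if theta.size != c + 1:
            raise ValueError("init has wrong length")
        theta = np.maximum(theta, floor)
        theta[-1] = max(theta[-1], e_floor)

        ll, P, Py = self._reml_parts(theta)
        converged = False
        n_iter = 0
        AI = None
        # active-set handling of the tau >= 0 constraints: a component held
        # at the boundary is excluded from the updates until its gradient
        # points back into the interior
        pinned = np.zeros(c + 1, dtype=bool)
        ai_cap = min(max_iter, 25)
        for n_iter in range(1, ai_cap + 1):
            grad, AI, quad, trPC = self._derivatives(theta, P, Py)
            pinned[:-1] &= grad[:-1] <= 0        # release if pushing inward
            pinned[:-1] |= (theta[:-1] <= floor * 1.01) & (grad[:-1] <= 0)
            free = ~pinned
            new = self._advance(theta, ll, grad, AI, quad, trPC, free,
                                floor, e_floor)
            if new is None:
                converged = True
                break
            delta = new[1] - ll
            theta, ll, P, Py = new
            if verbose:
                print(f"iter {n_iter:3d}  ll={ll:.6f}  theta={theta}")
            if abs(delta) < tol:
                converged = True
                break

        if not converged and max_iter > ai_cap:
            # a nearly flat likelihood valley can reduce the AI updates to
            # a crawl; polish with a bounded quasi-Newton search driven by
            # the exact REML gradient
            theta, ll, ok, n_ev = self._polish(theta, floor, e_floor)
            converged = ok
            n_iter += n_ev
            _, P, Py = self._reml_parts(theta)
            _, AI, _, _ = self._derivatives(theta, P, Py)
            if verbose:
                print(f"polish ({n_ev} evaluations)  ll={ll:.6f}  "
                      f"theta={theta}")

        at_zero = theta[:-1] <= floor * 1.01
        tau = np.where(at_zero, 0.0, theta[:-1])
        return VarianceComponentsResults(
            model=self, tau=tau, sigma_e2=float(theta[-1]), loglik=float(ll),
            converged=converged, n_iter=n_iter, pinned=at_zero,
            ai_matrix=AI)

    def _polish(self, theta, floor, e_floor):
        """Bounded L-BFGS-B refinement with the analytic REML gradient."""
        from scipy import optimize

        def fg(t):
            try:
                ll, P, Py = self._reml_parts(t)
            except FloatingPointError:
                return 1e12, np.zeros_like(t)
            grad, *_ = self._derivatives(t, P, Py)
            return -ll, -grad

        bounds = [(floor, None)] * (theta.size - 1) + [(e_floor, None)]
        res = optimize.minimize(fg, theta, jac=True, method="L-BFGS-B",
                                bounds=bounds,
                                options=dict(maxiter=150, ftol=1e-12,
                                             gtol=1e-6))
        ll0, *_ = self._reml_parts(theta)
        if -res.fun < ll0:            # never accept a worse point
            return theta, float(ll0), False, int(res.nfev)
        return np.asarray(res.x), float(-res.fun), bool(res.success), \
            int(res.nfev)

    def _derivatives(self, theta, P, Py):
        """REML gradient and average-information matrix at theta."""
        c = len(self.components)
        mats = self.components + [None]          # None = identity (residual)
        T = np.empty((self.n, c + 1))
        trPC = np.empty(c + 1)
        quad = np.empty(c + 1)
        for k, C in enumerate(mats):
            if C is None:
                T[:, k] = Py
                trPC[k] = np.trace(P)
            else:
                T[:, k] = C @ Py
                trPC[k] = np.einsum("ij,ij->", P, C)
            quad[k] = Py @ T[:, k]
        grad = -0.5 * (trPC - quad)
        PT = P @ T
        AI = 0.5 * (T.T @ PT)
        return grad, AI, quad, trPC

    def _advance(self, theta, ll, grad, AI, quad, trPC, free, floor, e_floor):
        """One accepted update: AI step, halved AI steps, then EM.

        Proposals are evaluated lazily (each costs a factorization) and the
        first one that does not decrease the restricted likelihood is
        accepted.  Returns None when no proposal moves the likelihood,
        which the caller treats as convergence at the boundary.
        """
        proposals = []
        lows = np.full_like(theta, floor)
        lows[-1] = e_floor
        try:
            fi = np.flatnonzero(free)
            step = np.zeros_like(theta)
            step[fi] = np.linalg.solve(AI[np.ix_(fi, fi)], grad[fi])
            full = theta + step
            proposals.append(full)
            # iterative active set: whenever the quasi-Newton step leaves
            # the feasible region, pin the offending parameters at their
            # boundary and re-solve for the rest, instead of crawling
            # along a clamped direction
            clamped = np.zeros_like(free)
            for _ in range(theta.size):
                newly = free & ~clamped & (theta + step < lows)
                if not newly.any() or (free & ~clamped & ~newly).sum() == 0:
                    break
                clamped |= newly
                fi2 = np.flatnonzero(free & ~clamped)
                step = np.zeros_like(theta)
                step[fi2] = np.linalg.solve(AI[np.ix_(fi2, fi2)],
                                            grad[fi2])
                prop = theta + step
                prop[clamped] = lows[clamped]
                proposals.append(prop)
            for half in (0.5, 0.25, 0.1):
                proposals.append(theta + half * (full - theta))
        except np.linalg.LinAlgError:
            pass
        em = theta.copy()
        em[fi] = theta[fi] + theta[fi] ** 2 * (quad[fi] - trPC[fi]) / self.n
        proposals.append(em)

        best = None
        for cand in proposals:
            cand = np.where(free, np.maximum(cand, floor), theta)
            cand[-1] = max(cand[-1], e_floor)
            try:
                cll, cP, cPy = self._reml_parts(cand)
            except FloatingPointError:
                continue
            if cll >= ll - 1e-10:
                return cand, cll, cP, cPy
            if best is None or cll > best[1]:
                best = (cand, cll, cP, cPy)
        if best is not None and best[1] > ll - 1e-6:
            return best
        return None

    # ------------------------------------------------------------------
    # likelihood surface over the (h2A, h2D) simplex
    # ------------------------------------------------------------------

    def likelihood_surface(self, grid_step: float = 0.02) -> "LikelihoodSurface":
        """Profiled restricted log-likelihood over the heritability simplex.

        Only defined for the two-component model KD.  At each grid node
        (h2A, h2D) with h2A + h2D <= 1 the covariance is
        V proportional to h2A K + h2D D + (1 - h2A - h2D) I and the overall
        scale is profiled out in closed form along with the fixed effects,
        so every node costs a single factorization.
        """
        if len(self.components) != 2:
            raise ValueError("likelihood surface requires exactly two "
                             "components (model KD)")
        if grid_step <= 0:
            raise ValueError("grid_step must be positive")
        K, D = self.components
        ticks = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
        ticks = np.minimum(ticks, 1.0)
        h2a, h2d, ll = [], [], []
        n, p = self.n, self.p
        I = np.eye(n)
        for a in ticks:
            for d in ticks:
                if a + d > 1.0 + 1e-12:
                    continue
                V0 = a * K + d * D + (1.0 - a - d) * I
                val = self._profiled_loglik(V0)
                h2a.append(a)
                h2d.append(d)
                ll.append(val)
        return LikelihoodSurface(np.asarray(h2a), np.asarray(h2d),
                                 np.asarray(ll), grid_step, self)

    def _profiled_loglik(self, V0: np.ndarray) -> float:
        """REML log-likelihood with total variance scale profiled out."""
        n, p = self.n, self.p
        try:
            cho = linalg.cho_factor(V0, lower=True, check_finite=False)
        except linalg.LinAlgError:
            return -np.inf
        logdet = 2.0 * np.log(np.diag(cho[0])).sum()
        ViX = linalg.cho_solve(cho, self.X, check_finite=False)
        Viy = linalg.cho_solve(cho, self.y, check_finite=False)
        XtViX = self.X.T @ ViX
        sign, logdet_X = np.linalg.slogdet(XtViX)
        if sign <= 0:
            return -np.inf
        yPy = self.y @ Viy - (self.X.T @ Viy) @ \
            np.linalg.solve(XtViX, self.X.T @ Viy)
        if yPy <= 0:
            return -np.inf
        s_hat = yPy / (n - p)
        return float(-0.5 * ((n - p) * np.log(s_hat) + logdet + logdet_X
                             + (n - p)))


def aireml_fit(y, components, X=None, **kwargs) -> "VarianceComponentsResults":
    """Convenience wrapper: build the model and fit it in one call."""
    return VarianceComponentsModel(y, components, X).fit(**kwargs)


# ---------------------------------------------------------------------------
# Results
# ---------------------------------------------------------------------------

@dataclass
class VarianceComponentsResults:
    """REML estimates with derived heritabilities and diagnostics.

    ``h2`` maps each component name to its variance fraction
    tau_c / (sum tau + sigma_E^2); ``H2`` sums the genetic fractions (the
    K and D components when present, otherwise all named components).
    Standard errors come from the inverse average-information matrix at the
    optimum (delta method for the fractions) and are approximate near the
    zero boundary.
    """

    model: VarianceComponentsModel
    tau: np.ndarray
    sigma_e2: float
    loglik: float
    converged: bool
    n_iter: int
    pinned: np.ndarray
    ai_matrix: np.ndarray | None = None
    _cov: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        if self.ai_matrix is not None:
            try:
                self._cov = np.linalg.inv(self.ai_matrix)
            except np.linalg.LinAlgError:
                self._cov = None

    # -- parameters ----------------------------------------------------

    @property
    def names(self) -> list[str]:
        return self.model.names

    @property
    def total_variance(self) -> float:
        return float(self.tau.sum() + self.sigma_e2)

    @property
    def h2(self) -> dict:
        tot = self.total_variance
        return {name: float(t / tot) for name, t in zip(self.names, self.tau)}

    @property
    def H2(self) -> float:
        """Broad-sense heritability: the genetic variance fractions summed."""
        h2 = self.h2
        genetic = [n for n in self.names if n in ("K", "D")] or self.names
        return float(sum(h2[n] for n in genetic))

    @property
    def se(self) -> dict:
        """Approximate standard errors of (tau_c..., sigma_E^2)."""
        if self._cov is None:
            return {}
        sd = np.sqrt(np.maximum(np.diag(self._cov), 0.0))
        out = {name: float(s) for name, s in zip(self.names, sd[:-1])}
        out["sigma_E2"] = float(sd[-1])
        return out

    @property
    def h2_se(self) -> dict:
        """Delta-method standard errors of the heritability fractions."""
        if self._cov is None:
            return {}
        theta = np.append(self.tau, self.sigma_e2)
        tot = theta.sum()
        out = {}
        for k, name in enumerate(self.names):
            g = np.full(theta.size, -theta[k] / tot ** 2)
            g[k] += 1.0 / tot
            out[name] = float(np.sqrt(max(g @ self._cov @ g, 0.0)))
        return out

    # -- reporting ------------------------------------------------------

    def summary(self) -> str:
        lines = [
            f"Variance components model {self.model.model_name} "
            f"(N={self.model.n}, p={self.model.p})",
            f"REML log-likelihood {self.loglik:.4f}   "
            f"converged={self.converged} in {self.n_iter} iterations",
            f"{'component':<10}{'tau':>12}{'h2':>10}{'se(h2)':>10}",
        ]
        h2, h2se = self.h2, self.h2_se
        for k, name in enumerate(self.names):
            mark = " (boundary)" if self.pinned[k] else ""
            lines.append(f"{name:<10}{self.tau[k]:>12.5f}{h2[name]:>10.4f}"
                         f"{h2se.get(name, float('nan')):>10.4f}{mark}")
        lines.append(f"{'residual':<10}{self.sigma_e2:>12.5f}"
                     f"{self.sigma_e2 / self.total_variance:>10.4f}")
        lines.append(f"H2 = {self.H2:.4f}")
        return "\n".join(lines)

    def __str__(self):
        return self.summary()


# ---------------------------------------------------------------------------
# Surface & confidence regions
# ---------------------------------------------------------------------------

@dataclass
class LikelihoodSurface:
    """Profiled REML log-likelihood over the (h2A, h2D) simplex grid."""

    h2a: np.ndarray
    h2d: np.ndarray
    loglik: np.ndarray
    grid_step: float
    model: VarianceComponentsModel

    @property
    def argmax(self) -> tuple[float, float]:
        k = int(np.argmax(self.loglik))
        return float(self.h2a[k]), float(self.h2d[k])

    @property
    def max_loglik(self) -> float:
        return float(np.max(self.loglik))

    def confidence_region(self, level: float = 0.95) -> np.ndarray:
        """Boolean mask of grid nodes inside the likelihood-ratio region.

        A node is included when 2 (ll_max - ll) <= chi2 quantile with 2
        degrees of freedom at the requested level (5.991 at 95%).
        """
        return confidence_region(self, level)

    def plot(self, ax=None, level: float = 0.95):
        """Contour plot of the surface with the confidence region shaded."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        mask = self.confidence_region(level)
        if mask.sum() > 3:
            ax.tricontourf(self.h2a[mask], self.h2d[mask], self.loglik[mask],
                           alpha=0.4, cmap="Reds")
        finite = np.isfinite(self.loglik)
        ax.tricontour(self.h2a[finite], self.h2d[finite],
                      self.loglik[finite], levels=12, colors="k",
                      linewidths=0.6)
        a, d = self.argmax
        ax.plot([a], [d], "r^", label="MLE")
        ax.plot([0, 1, 0, 0], [0, 0, 1, 0], "-", color="grey", lw=1)
        ax.set_xlabel("$h^2_A$")
        ax.set_ylabel("$h^2_D$")
        ax.legend()
        return ax


def confidence_region(surface: LikelihoodSurface,
                      level: float = 0.95) -> np.ndarray:
    """Likelihood-ratio confidence region on a computed surface."""
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    thresh = stats.chi2.ppf(level, df=2)
    return 2.0 * (surface.max_loglik - surface.loglik) <= thresh
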