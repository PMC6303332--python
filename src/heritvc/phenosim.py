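"""Phenotype simulation from causal additive and dominance effects.

Traits are sums of genetic and environmental contributions,

    Y = G_A beta_A + G_D beta_D + eps,

where G_A / G_D are the standardized additive and orthogonal-dominance
codings of M randomly selected causal sites each (the two sets are drawn
independently and may overlap), beta are i.i.d. normal effect sizes rescaled
so the realized variances hit their targets exactly
(tau_A = sum beta_A^2 = h2_A, tau_D = sum beta_D^2 = h2_D), and eps has
covariance sigma_E^2 I plus, optionally, a sibling shared-environment term:
sigma_E^2 + sigma_S^2 on the diagonal and sigma_S^2 on every off-diagonal
entry belonging to a sibling pair.  Total phenotypic variance is normalized
to 1, so the h2 parameters are directly the variance fractions.

Causal Variant Scenarios: under A, causal sites are drawn completely at
random among sites polymorphic in the cohort; under B, only sites with
MAF > 0.01 are eligible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PhenotypeSpec",
    "SimulatedPhenotype",
    "select_causal",
    "simulate_phenotype",
]


@dataclass(frozen=True)
class PhenotypeSpec:
    """Target architecture of a simulated trait."""

    M: int
    scenario: str = "A"              # "A": any MAF; "B": MAF > 0.01
    h2A: float = 0.4
    h2D: float = 0.4
    h2S: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.M < 1:
            raise ValueError("M must be >= 1")
        if self.scenario not in ("A", "B"):
            raise ValueError(f"unknown causal-variant scenario {self.scenario!r}")
        for name in ("h2A", "h2D", "h2S"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.h2A + self.h2D + self.h2S > 1 + 1e-12:
            raise ValueError("h2A + h2D + h2S must not exceed 1")


@dataclass
class SimulatedPhenotype:
    """A realized trait with its causal configuration and variance parts."""

    Y: np.ndarray
    causal_A: np.ndarray
    causal_D: np.ndarray
    beta_A: np.ndarray
    beta_D: np.ndarray
    tau_A: float
    tau_D: float
    sigma_S2: float
    sigma_E2: float
    spec: PhenotypeSpec = field(default=None)


def select_causal(freqs: np.ndarray, M: int, scenario: str = "A",
                  seed: int | np.random.Generator = 0):
    """Draw the additive and dominance causal site sets.

    Two independent uniform draws without replacement from the eligible
    sites; the sets may overlap, so at most 2M sites carry an effect.
    ``freqs`` are per-site minor allele frequencies (sites with MAF = 0 are
    never eligible: they carry no variance).
    """
    rng = np.random.default_rng(seed)
    maf = np.minimum(np.asarray(freqs, dtype=float),
                     1 - np.asarray(freqs, dtype=float))
    if scenario == "A":
        eligible = np.flatnonzero(maf > 0)
    elif scenario == "B":
        eligible = np.flatnonzero(maf > 0.01)
    else:
        raise ValueError(f"unknown causal-variant scenario {scenario!r}")
    if eligible.size < M:
        raise ValueError(
            f"M={M} causal variants requested but only {eligible.size} "
            f"eligible sites under scenario {scenario}")
    causal_A = np.sort(rng.choice(eligible, size=M, replace=False))
    causal_D = np.sort(rng.choice(eligible, size=M, replace=False))
    return causal_A, causal_D


def _additive_coding(G: np.ndarray, p: np.ndarray) -> np.ndarray:
    """(g - 2p) / sqrt(2p(1-p)): mean 0, variance 1 under HWE at frequency p."""
    return (G - 2 * p) / np.sqrt(2 * p * (1 - p))


def _dominance_coding(G: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Orthogonal dominance code standardized by its HWE moments.

    d(g) = {0, 2p, 4p-2} has mean 2p^2 and standard deviation 2p(1-p)
    under HWE; the standardized version has zero covariance with the
    additive coding.  Standardizing by these theoretical moments (not the
    realised sample variance) is what keeps the per-site variance
    contribution equal to beta^2 in expectation even at sites so rare that
    an alternate homozygote never appears in the sample.
    """
    d = np.where(G == 1, 2 * p, np.where(G == 2, 4 * p - 2, 0.0))
    return (d - 2 * p ** 2) / (2 * p * (1 - p))


def simulate_phenotype(cohort, spec: PhenotypeSpec,
                       S: np.ndarray | None = None,
                       sibship_labels: np.ndarray | None = None,
                       seed: int | np.random.Generator | None = None
                       ) -> SimulatedPhenotype:
    """Simulate one trait on a cohort at exact target heritabilities.

    ``cohort`` is anything with a ``genotypes`` (N x S) matrix (a
    :class:`~heritvc.mosaic.Cohort`) or a plain genotype matrix.  With
    ``spec.h2S > 0``, the sibling structure must be supplied either as the
    binary sibship matrix ``S`` or as integer ``sibship_labels``; the shared
    component is sampled as one normal deviate per sibship (exactly the
    factorization of the sibling covariance block structure).

    Effect sizes are drawn i.i.d. standard normal and rescaled so that
    sum(beta_A^2) = h2A and sum(beta_D^2) = h2D hold exactly; the codings
    are standardized by their theoretical HWE moments at the cohort allele
    frequency, so each causal column contributes beta^2 variance in
    expectation and the realised total phenotypic variance is 1 on average.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    G = cohort.genotypes if hasattr(cohort, "genotypes") else np.asarray(cohort)
    n = G.shape[0]
    freqs = G.mean(axis=0) / 2.0

    causal_A, causal_D = select_causal(freqs, spec.M, spec.scenario, rng)

    Y = np.zeros(n)
    # additive part (unit HWE variance per column at the cohort frequency)
    Za = _additive_coding(G[:, causal_A].astype(np.float64), freqs[causal_A])
    beta_A = _rescale(rng.standard_normal(spec.M), spec.h2A)
    Y += Za @ beta_A
    # dominance part: HWE-orthogonal coding at the cohort frequency
    Zd = _dominance_coding(G[:, causal_D].astype(np.float64), freqs[causal_D])
    beta_D = _rescale(rng.standard_normal(spec.M), spec.h2D)
    Y += Zd @ beta_D

    sigma_S2 = spec.h2S
    sigma_E2 = 1.0 - spec.h2A - spec.h2D - spec.h2S
    if sigma_E2 < -1e-12:
        raise ValueError("residual variance is negative")
    sigma_E2 = max(sigma_E2, 0.0)
    Y += np.sqrt(sigma_E2) * rng.standard_normal(n)
    if sigma_S2 > 0:
        labels = _resolve_sibships(S, sibship_labels, n)
        shared = rng.standard_normal(labels.max() + 1) * np.sqrt(sigma_S2)
        Y += shared[labels]

    return SimulatedPhenotype(Y, causal_A, causal_D, beta_A, beta_D,
                              tau_A=float(beta_A @ beta_A),
                              tau_D=float(beta_D @ beta_D),
                              sigma_S2=sigma_S2, sigma_E2=sigma_E2, spec=spec)


def _rescale(beta: np.ndarray, target: float) -> np.ndarray:
    ss = float(beta @ beta)
    if target == 0 or ss == 0:
        return np.zeros_like(beta)
    return beta * np.sqrt(target / ss)


def _resolve_sibships(S, labels, n) -> np.ndarray:
    if labels is not None:
        labels = np.asarray(labels)
        if labels.shape != (n,):
            raise ValueError("sibship_labels has wrong length")
        return labels
    if S is None:
        raise ValueError("h2S > 0 requires a sibship matrix or labels")
    S = np.asarray(S)
    if S.shape != (n, n):
        raise ValueError("sibship matrix has wrong shape")
    # sibships are cliques: label by connected components of the indicator
    labels = np.full(n, -1, dtype=np.int64)
    nxt = 0
    for i in range(n):
        if labels[i] < 0:
            members = np.flatnonzero(S[i] > 0)
            labels[members] = nxt
            nxt += 1
    return labels
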