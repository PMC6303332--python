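"""Genotype-based relationship matrices and variant quality control.

The additive and dominance GRMs are the method-of-moments estimators built
from per-site standardized codings.  At a site with alternate-allele
frequency p and genotype g in {0, 1, 2}:

    additive   z_A(g) = (g - 2p) / sqrt(2 p (1 - p))
    dominance  d(g)   = {0, 2p, 4p - 2},  z_D = (d - 2p^2) / (2 p (1 - p))

Under Hardy-Weinberg proportions both codings have mean 0 and variance 1 and
are uncorrelated - the dominance coding is the residual of the heterozygote
indicator after regression on allele count, so the two relationship matrices
decompose genetic covariance into orthogonal additive and dominance parts.
Entries are averages of coding products over the retained sites:
K_ij = (1/m) sum_s z_A(g_is) z_A(g_js), likewise D from z_D.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

__all__ = [
    "VariantQC",
    "variant_qc",
    "hwe_exact_p",
    "additive_grm",
    "dominance_grm",
    "eigenvalue_variance",
]


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

@lru_cache(maxsize=200_000)
def hwe_exact_p(n_het: int, n_hom_minor: int, n_hom_major: int) -> float:
    """Two-sided exact Hardy-Weinberg test p-value (no mid-p correction).

    Sums the probabilities of all heterozygote counts, conditional on the
    observed allele counts, that are no more probable than the observed one
    (the standard SNP-HWE enumeration).
    """
    n_het, n_hom_minor, n_hom_major = int(n_het), int(n_hom_minor), int(n_hom_major)
    if min(n_het, n_hom_minor, n_hom_major) < 0:
        raise ValueError("negative genotype count")
    rare = 2 * n_hom_minor + n_het
    common = 2 * n_hom_major + n_het
    if rare > common:
        rare, common = common, rare
    n = n_het + n_hom_minor + n_hom_major
    if n == 0 or rare == 0:
        return 1.0

    # unnormalized probabilities over all feasible het counts (same parity)
    mid = rare * common // (rare + common)
    if mid % 2 != rare % 2:
        mid += 1
    probs = {mid: 1.0}
    # going down from mid: P(h-2)/P(h) = h (h-1) / ((r-h+2)(c-h+2))
    h, p = mid, 1.0
    while h >= 2:
        p *= h * (h - 1) / ((rare - h + 2.0) * (common - h + 2.0))
        h -= 2
        probs[h] = p
    h, p = mid, 1.0
    while h + 2 <= rare:
        p *= ((rare - h) * (common - h)) / ((h + 2.0) * (h + 1.0))
        h += 2
        probs[h] = p
    total = sum(probs.values())
    p_obs = probs.get(n_het, 0.0)
    return min(1.0, sum(v for v in probs.values() if v <= p_obs * (1 + 1e-12))
               / total)


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

@dataclass
class VariantQC:
    """Per-site filters: keep = (MAF > maf_threshold) & (HWE p > hwe_threshold)."""

    maf: np.ndarray
    hwe_p: np.ndarray
    keep: np.ndarray
    freqs: np.ndarray                 # alternate-allele sample frequency
    maf_threshold: float
    hwe_threshold: float

    @property
    def m_kept(self) -> int:
        return int(self.keep.sum())


def variant_qc(genotypes: np.ndarray, maf_threshold: float = 0.05,
               hwe_threshold: float = 1e-5) -> VariantQC:
    """Compute sample MAF and exact HWE p-value per site and keep flags.

    Defaults reproduce the common GWAS-panel filter: MAF > 0.05 and exact
    Hardy-Weinberg p > 1e-5.
    """
    G = np.asarray(genotypes)
    if G.size == 0:
        raise ValueError("empty genotype matrix")
    if G.ndim != 2:
        raise ValueError("genotypes must be (individuals x sites)")
    n = G.shape[0]
    n_het = (G == 1).sum(axis=0)
    n_alt = (G == 2).sum(axis=0)
    n_ref = n - n_het - n_alt
    freqs = (2 * n_alt + n_het) / (2.0 * n)
    maf = np.minimum(freqs, 1 - freqs)
    hwe = np.empty(G.shape[1])
    for s in range(G.shape[1]):
        lo, hi = (n_alt[s], n_ref[s]) if n_alt[s] <= n_ref[s] \
            else (n_ref[s], n_alt[s])
        hwe[s] = hwe_exact_p(int(n_het[s]), int(lo), int(hi))
    keep = (maf > maf_threshold) & (hwe > hwe_threshold)
    return VariantQC(maf, hwe, keep, freqs, maf_threshold, hwe_threshold)


# ---------------------------------------------------------------------------
# GRMs
# ---------------------------------------------------------------------------

def _kept_freqs(G: np.ndarray, qc: VariantQC | None):
    if qc is None:
        n = G.shape[0]
        freqs = G.mean(axis=0) / 2.0
        keep = (freqs > 0) & (freqs < 1)
    else:
        freqs = qc.freqs
        keep = qc.keep & (freqs > 0) & (freqs < 1)
    if not keep.any():
        raise ValueError("no variants left after filtering")
    return keep, freqs


def additive_grm(genotypes: np.ndarray, qc: VariantQC | None = None) -> np.ndarray:
    """Additive GRM: average outer product of the standardized allele count."""
    G = np.asarray(genotypes, dtype=np.float64)
    keep, freqs = _kept_freqs(G, qc)
    p = freqs[keep]
    Z = (G[:, keep] - 2 * p) / np.sqrt(2 * p * (1 - p))
    return (Z @ Z.T) / keep.sum()


def dominance_grm(genotypes: np.ndarray, qc: VariantQC | None = None) -> np.ndarray:
    """Dominance GRM from the HWE-orthogonal heterozygosity coding."""
    G = np.asarray(genotypes, dtype=np.float64)
    keep, freqs = _kept_freqs(G, qc)
    p = freqs[keep]
    Gk = G[:, keep]
    # d(g) = {0, 2p, 4p-2}; equivalently 2p*het + (4p-2)*homalt
    d = np.where(Gk == 1, 2 * p, np.where(Gk == 2, 4 * p - 2, 0.0))
    Z = (d - 2 * p ** 2) / (2 * p * (1 - p))
    return (Z @ Z.T) / keep.sum()


def dominance_coding(g: np.ndarray, p: float) -> np.ndarray:
    """Standardized dominance code of one site (population-frequency scale)."""
    d = np.where(g == 1, 2 * p, np.where(g == 2, 4 * p - 2, 0.0))
    return (d - 2 * p ** 2) / (2 * p * (1 - p))


def eigenvalue_variance(K: np.ndarray) -> float:
    """Variance of the eigenvalue spectrum of a symmetric matrix.

    Used as a one-number summary of sample structure: cohorts with strong
    relatedness (isolates) concentrate covariance in a few directions and
    have a much larger eigenvalue variance than equally sized outbred
    samples.
    """
    K = np.asarray(K)
    if K.ndim != 2 or K.shape[0] != K.shape[1]:
        raise ValueError("input must be a square matrix")
    ev = np.linalg.eigvalsh((K + K.T) / 2.0)
    return float(ev.var())
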