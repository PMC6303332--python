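import numpy as np
import pytest

from heritvc.synth import Pedigree


@pytest.fixture(scope="session")
def nuclear_pedigree():
    """Two founders and two full-sib children (C0, C1 genotyped)."""
    return Pedigree(
        np.array(["F0", "F1", "C0", "C1"]),
        np.array([-1, -1, 0, 0]),
        np.array([-1, -1, 1, 1]),
        np.array([1, 2, 1, 2]),
        np.array([False, False, True, True]),
    )


@pytest.fixture(scope="session")
def sibmating_pedigree():
    """Full-sib mating: X is the offspring of sibs C0 x C1 (f = 1/4)."""
    return Pedigree(
        np.array(["F0", "F1", "C0", "C1", "X"]),
        np.array([-1, -1, 0, 0, 2]),
        np.array([-1, -1, 1, 1, 3]),
        np.array([1, 2, 1, 2, 1]),
        np.zeros(5, bool),
    )


@pytest.fixture(scope="session")
def small_pool():
    import heritvc.synth as synth
    return synth.generate_reference_pool(60, 1200, seed=7)


def drop_alleles(pedigree, n_loci, rng):
    """Independent single-locus gene-dropping oracle.

    Transmits founder allele labels down the pedigree at ``n_loci``
    unlinked loci (one random parental allele per meiosis), entirely
    independent of the package's recombination machinery.  Returns two
    (n_individuals, n_loci) arrays of founder-allele labels.
    """
    n = pedigree.n
    pat = np.zeros((n, n_loci), dtype=np.int32)
    mat = np.zeros((n, n_loci), dtype=np.int32)
    for i in pedigree.topological_order.tolist():
        f, m = int(pedigree.father[i]), int(pedigree.mother[i])
        if f < 0:
            pat[i] = 2 * i
            mat[i] = 2 * i + 1
        else:
            pick = rng.integers(0, 2, size=n_loci, dtype=np.int8)
            pat[i] = np.where(pick, pat[f], mat[f])
            pick = rng.integers(0, 2, size=n_loci, dtype=np.int8)
            mat[i] = np.where(pick, pat[m], mat[m])
    return pat, mat


def jacquard_state_freqs(pat, mat, i, j):
    """Empirical condensed-identity state frequencies from dropped labels."""
    a, b, c, d = pat[i], mat[i], pat[j], mat[j]
    ab = a == b
    cd = c == d
    ac, ad, bc, bd = a == c, a == d, b == c, b == d
    out = np.zeros(9)
    s1 = ab & cd & ac
    s2 = ab & cd & ~ac
    s3 = ab & ~cd & (ac | ad)
    s4 = ab & ~cd & ~(ac | ad)
    s5 = ~ab & cd & (ac | bc)
    s6 = ~ab & cd & ~(ac | bc)
    s7 = ~ab & ~cd & ((ac & bd) | (ad & bc))
    s8 = ~ab & ~cd & (ac.astype(int) + ad + bc + bd == 1)
    s9 = ~ab & ~cd & ~(ac | ad | bc | bd)
    for k, s in enumerate((s1, s2, s3, s4, s5, s6, s7, s8, s9)):
        out[k] = s.mean()
    return out
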