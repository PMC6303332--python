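"""Pedigree-expectation relatedness coefficients.

Provides the classical recursive kinship matrix, Jacquard's nine condensed
identity coefficients computed through Karigl's generalized-kinship
recursions (exact rational arithmetic, valid under inbreeding), the K/D
covariance matrices they imply, and the sibship indicator matrix used as a
shared-environment variance structure.

Identity notation for a pair (i, j) with i's alleles (a, b) and j's (c, d):
Delta_1..Delta_9 are the probabilities of the nine condensed identity
states.  The kinship coefficient and the probability of sharing two pairs
of alleles IBD follow as

    phi   = Delta1 + (Delta3 + Delta5 + Delta7) / 2 + Delta8 / 4
    D_ij  = Delta1 + Delta7

with K = 2 phi (diagonal 1 + f) and D diagonal 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .synth import Pedigree

__all__ = [
    "kinship_matrix",
    "inbreeding_coefficients",
    "jacquard_coefficients",
    "IdentityCoefficients",
    "pedigree_KD",
    "pedigree_kd_matrices",
    "sibship_matrix",
]


# ---------------------------------------------------------------------------
# Kinship (vectorized tabular method)
# ---------------------------------------------------------------------------

def kinship_matrix(pedigree: Pedigree, members: np.ndarray | None = None,
                   dtype=np.float64) -> np.ndarray:
    """Kinship coefficients phi for all pairs, by the tabular recurrence.

    Individuals are processed in topological order; for a non-founder i and
    any previously processed j != i,

        phi(i, j) = (phi(father_i, j) + phi(mother_i, j)) / 2
        phi(i, i) = (1 + phi(father_i, mother_i)) / 2

    and founders are unrelated non-inbred (phi = 1/2 with themselves).
    Returns the full matrix, or the submatrix for ``members``.
    """
    n = pedigree.n
    order = pedigree.topological_order
    pos = np.empty(n, dtype=np.int64)
    pos[order] = np.arange(n)
    # work in topologically permuted space so parents precede children
    phi = np.zeros((n, n), dtype=dtype)
    pf = pedigree.father[order]
    pm = pedigree.mother[order]
    for k in range(n):
        if pf[k] < 0:
            phi[k, k] = 0.5
        else:
            a, b = pos[pf[k]], pos[pm[k]]
            if k:
                row = 0.5 * (phi[a, :k] + phi[b, :k])
                phi[k, :k] = row
                phi[:k, k] = row
            phi[k, k] = 0.5 * (1.0 + phi[a, b])
    out = np.empty((n, n), dtype=dtype)
    out[np.ix_(pos, pos)] = phi  # undo the permutation
    if members is not None:
        members = np.asarray(members)
        out = out[np.ix_(members, members)]
    return out


def inbreeding_coefficients(pedigree: Pedigree) -> np.ndarray:
    """Inbreeding coefficient per individual: f = 2 phi(i, i) - 1."""
    return 2.0 * np.diag(kinship_matrix(pedigree)) - 1.0


# ---------------------------------------------------------------------------
# Karigl generalized kinship -> condensed identity coefficients
# ---------------------------------------------------------------------------

HALF = Fraction(1, 2)
QUARTER = Fraction(1, 4)


class _Karigl:
    """Memoized generalized kinship coefficients on a pedigree.

    phi2(a,b), phi3(a,b,c), phi4(a,b,c,d) are probabilities that randomly
    sampled alleles (one per listed slot, slots repeat individuals) are all
    IBD; phi22(a,b;c,d) that the first pair and the second pair are each
    IBD.  Recursions expand the individual of highest topological rank
    (never an ancestor of the others), which makes them valid under
    inbreeding.  Exact rationals throughout.
    """

    def __init__(self, pedigree: Pedigree):
        self.ped = pedigree
        self.rank = np.empty(pedigree.n, dtype=np.int64)
        self.rank[pedigree.topological_order] = np.arange(pedigree.n)
        self._p2: dict = {}
        self._p3: dict = {}
        self._p4: dict = {}
        self._p22: dict = {}

    def parents(self, a):
        return int(self.ped.father[a]), int(self.ped.mother[a])

    # -- pairwise ------------------------------------------------------------
    def phi2(self, a, b) -> Fraction:
        if a < b:
            a, b = b, a  # sort descending is irrelevant; canonicalize
        key = (a, b)
        got = self._p2.get(key)
        if got is not None:
            return got
        x = a if self.rank[a] >= self.rank[b] else b
        y = b if x == a else a
        f, m = self.parents(x)
        if x == y:
            val = HALF * (1 + (self.phi2(f, m) if f >= 0 else Fraction(0)))
        elif f < 0:
            val = Fraction(0)
        else:
            val = HALF * (self.phi2(f, y) + self.phi2(m, y))
        self._p2[key] = val
        return val

    # -- triple --------------------------------------------------------------
    def phi3(self, a, b, c) -> Fraction:
        key = tuple(sorted((a, b, c)))
        got = self._p3.get(key)
        if got is not None:
            return got
        trio = sorted(key, key=lambda i: self.rank[i], reverse=True)
        x = trio[0]
        rest = trio[1:]
        f, m = self.parents(x)
        mult = key.count(x)
        if mult == 3:
            val = QUARTER * (1 + 3 * (self.phi2(f, m) if f >= 0 else Fraction(0)))
        elif mult == 2:
            other = rest[1] if rest[0] == x else rest[0]
            val = HALF * self.phi2(x, other)
            if f >= 0:
                val += HALF * self.phi3(f, m, other)
        elif f < 0:
            val = Fraction(0)
        else:
            val = HALF * (self.phi3(f, rest[0], rest[1]) +
                          self.phi3(m, rest[0], rest[1]))
        self._p3[key] = val
        return val

    # -- quadruple -----------------------------------------------------------
    def phi4(self, a, b, c, d) -> Fraction:
        key = tuple(sorted((a, b, c, d)))
        got = self._p4.get(key)
        if got is not None:
            return got
        quad = sorted(key, key=lambda i: self.rank[i], reverse=True)
        x = quad[0]
        rest = quad[1:]  # the other three slots
        f, m = self.parents(x)
        mult = key.count(x)
        fa = self.phi2(f, m) if f >= 0 else Fraction(0)
        if mult == 4:
            val = Fraction(1, 8) * (1 + 7 * fa)
        elif mult == 3:
            other = next(i for i in rest if i != x)
            val = QUARTER * self.phi2(x, other)
            if f >= 0:
                val += Fraction(3, 4) * self.phi3(f, m, other)
        elif mult == 2:
            others = [i for i in rest if i != x]
            val = HALF * self.phi3(x, others[0], others[1])
            if f >= 0:
                val += HALF * self.phi4(f, m, others[0], others[1])
        elif f < 0:
            val = Fraction(0)
        else:
            val = HALF * (self.phi4(f, rest[0], rest[1], rest[2]) +
                          self.phi4(m, rest[0], rest[1], rest[2]))
        self._p4[key] = val
        return val

    # -- pair of pairs ---------------------------------------------------------
    def phi22(self, a, b, c, d) -> Fraction:
        """P(draw from a IBD draw from b, and draw from c IBD draw from d)."""
        p1 = tuple(sorted((a, b)))
        p2 = tuple(sorted((c, d)))
        key = tuple(sorted((p1, p2)))
        got = self._p22.get(key)
        if got is not None:
            return got
        (a, b), (c, d) = key
        every = [a, b, c, d]
        x = max(every, key=lambda i: self.rank[i])
        f, m = self.parents(x)
        in1 = (a == x) + (b == x)
        in2 = (c == x) + (d == x)
        if in2 > in1 or (in2 == in1 and (c == x) + (d == x) and not (a == x or b == x)):
            (a, b), (c, d) = (c, d), (a, b)
            in1, in2 = in2, in1
        if in1 == 2 and in2 == 2:
            # ((x,x);(x,x))
            fa = self.phi2(f, m) if f >= 0 else Fraction(0)
            val = QUARTER + Fraction(3, 4) * fa
        elif in1 == 2 and in2 == 1:
            # ((x,x);(x,y))
            y = d if c == x else c
            val = HALF * self.phi2(x, y)
            if f >= 0:
                val += HALF * self.phi3(f, m, y)
        elif in1 == 2:
            # ((x,x);(c,d))
            val = HALF * self.phi2(c, d)
            if f >= 0:
                val += HALF * self.phi22(f, m, c, d)
        elif in1 == 1 and in2 == 1:
            # ((x,y);(x,z))
            y = b if a == x else a
            z = d if c == x else c
            val = HALF * self.phi3(x, y, z)
            if f >= 0:
                val += QUARTER * (self.phi22(f, y, m, z) +
                                  self.phi22(m, y, f, z))
        else:
            # ((x,y);(c,d)), x only in the first pair
            y = b if a == x else a
            if f < 0:
                val = Fraction(0)
            else:
                val = HALF * (self.phi22(f, y, c, d) + self.phi22(m, y, c, d))
        self._p22[key] = val
        return val


@dataclass(frozen=True)
class IdentityCoefficients:
    """Condensed identity coefficients for one ordered pair of individuals."""

    delta: tuple                     # Delta1..Delta9, exact Fractions
    phi: Fraction                    # kinship coefficient
    f_i: Fraction                    # inbreeding of i
    f_j: Fraction

    @property
    def as_floats(self) -> np.ndarray:
        return np.array([float(d) for d in self.delta])

    @property
    def K(self) -> float:
        return float(2 * self.phi)

    @property
    def D(self) -> float:
        return float(self.delta[0] + self.delta[6])


# 9x9 linear system: rows are expectations of observable generalized-kinship
# quantities in terms of Delta1..Delta9 (columns), derived by conditioning
# sampled-allele configurations on the condensed identity state.
_A9 = [
    [1, 1, 1, 1, 1, 1, 1, 1, 1],                                     # total
    [1, 1, 1, 1, 0, 0, 0, 0, 0],                                     # f_i
    [1, 1, 0, 0, 1, 1, 0, 0, 0],                                     # f_j
    [1, 0, HALF, 0, HALF, 0, HALF, QUARTER, 0],                      # phi_ij
    [1, 0, HALF, 0, QUARTER, 0, QUARTER, Fraction(1, 8), 0],         # phi_iij
    [1, 0, QUARTER, 0, HALF, 0, QUARTER, Fraction(1, 8), 0],         # phi_ijj
    [1, 0, QUARTER, 0, QUARTER, 0, Fraction(1, 8), Fraction(1, 16), 0],  # iijj
    [1, 1, HALF, HALF, HALF, HALF, QUARTER, QUARTER, QUARTER],       # ii,jj
    [1, 0, QUARTER, 0, QUARTER, 0, QUARTER, Fraction(1, 16), 0],     # ij,ij
]


def _solve_fraction(A, b):
    """Gaussian elimination over exact rationals (small systems)."""
    n = len(b)
    M = [[Fraction(A[r][c]) for c in range(n)] + [Fraction(b[r])]
         for r in range(n)]
    for col in range(n):
        piv = next(r for r in range(col, n) if M[r][col] != 0)
        M[col], M[piv] = M[piv], M[col]
        inv = 1 / M[col][col]
        M[col] = [v * inv for v in M[col]]
        for r in range(n):
            if r != col and M[r][col] != 0:
                factor = M[r][col]
                M[r] = [vr - factor * vc for vr, vc in zip(M[r], M[col])]
    return [M[r][n] for r in range(n)]


def jacquard_coefficients(pedigree: Pedigree, i, j,
                          calculator: _Karigl | None = None) -> IdentityCoefficients:
    """Exact condensed identity coefficients Delta1..Delta9 for a pair.

    ``i`` and ``j`` may be ids or row indices.  Generalized kinship
    coefficients (pairwise, triple, quadruple and two-pair forms) are
    computed by Karigl's memoized recursions and the 9x9 linear system is
    solved in exact rational arithmetic, so the result is valid for inbred
    and mutually inbred pairs.
    """
    def row(x):
        if isinstance(x, (int, np.integer)):
            if not 0 <= int(x) < pedigree.n:
                raise KeyError(f"index {x} outside pedigree")
            return int(x)
        return pedigree.index_of(x)

    a, b = row(i), row(j)
    K = calculator or _Karigl(pedigree)
    f_i = 2 * K.phi2(a, a) - 1
    f_j = 2 * K.phi2(b, b) - 1
    rhs = [
        Fraction(1),
        f_i,
        f_j,
        K.phi2(a, b),
        K.phi3(a, a, b),
        K.phi3(a, b, b),
        K.phi4(a, a, b, b),
        K.phi22(a, a, b, b),
        K.phi22(a, b, a, b),
    ]
    delta = tuple(_solve_fraction(_A9, rhs))
    return IdentityCoefficients(delta, K.phi2(a, b), f_i, f_j)


def pedigree_KD(coeffs: dict | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Assemble K and D matrices from per-pair identity coefficients.

    ``coeffs`` maps (row, col) index pairs to :class:`IdentityCoefficients`
    for the upper triangle of some member list; diagonal entries may be
    omitted (filled as K_ii = 1 + f_i from any pair involving i, D_ii = 1).
    """
    idx = sorted({k for pair in coeffs for k in pair})
    remap = {v: r for r, v in enumerate(idx)}
    n = len(idx)
    K = np.zeros((n, n))
    D = np.zeros((n, n))
    fs = np.full(n, np.nan)
    for (i, j), cc in coeffs.items():
        a, b = remap[i], remap[j]
        if a == b:
            fs[a] = float(cc.f_i)
            continue
        K[a, b] = K[b, a] = cc.K
        D[a, b] = D[b, a] = cc.D
        fs[a] = float(cc.f_i)
        fs[b] = float(cc.f_j)
    if np.any(np.isnan(fs)):
        raise ValueError("incomplete coefficient set: missing individuals")
    np.fill_diagonal(K, 1.0 + fs)
    np.fill_diagonal(D, 1.0)
    return K, D


def pedigree_kd_matrices(pedigree: Pedigree, members: np.ndarray | None = None,
                         method: str = "product") -> tuple[np.ndarray, np.ndarray]:
    """Pedigree-expectation K and D for a member list, at scale.

    method="product" computes K = 2 phi from the tabular kinship recurrence
    and the dominance matrix from the classical parental-kinship product

        D_ij = phi(fi, fj) phi(mi, mj) + phi(fi, mj) phi(mi, fj)

    which equals Delta1 + Delta7 exactly for pairs whose parents are not
    themselves inbred-and-cross-related; it is the standard pedigree-BLUP
    dominance relationship and is fast enough for thousands of members.
    method="jacquard" solves every pair exactly via Karigl's recursions
    (small member sets only).
    """
    if members is None:
        members = np.flatnonzero(pedigree.is_genotyped)
    members = np.asarray(members)
    if method == "jacquard":
        calc = _Karigl(pedigree)
        coeffs = {}
        for a in range(members.size):
            for b in range(a, members.size):
                coeffs[(a, b)] = jacquard_coefficients(
                    pedigree, int(members[a]), int(members[b]), calculator=calc)
        return pedigree_KD(coeffs)
    if method != "product":
        raise ValueError(f"unknown method {method!r}")

    phi_full = kinship_matrix(
        pedigree, dtype=np.float32 if pedigree.n > 3000 else np.float64)
    phi = phi_full[np.ix_(members, members)].astype(np.float64)
    K = 2.0 * phi
    np.fill_diagonal(K, 2.0 * np.diag(phi))  # = 1 + f

    fa = pedigree.father[members]
    mo = pedigree.mother[members]
    has = fa >= 0
    D = np.zeros((members.size, members.size))
    if has.any():
        sub = np.flatnonzero(has)
        F, M = fa[sub], mo[sub]
        pff = phi_full[np.ix_(F, F)].astype(np.float64)
        pmm = phi_full[np.ix_(M, M)].astype(np.float64)
        pfm = phi_full[np.ix_(F, M)].astype(np.float64)
        block = pff * pmm + pfm * pfm.T
        D[np.ix_(sub, sub)] = block
    np.fill_diagonal(D, 1.0)
    return K, D


# ---------------------------------------------------------------------------
# Sibship matrix
# ---------------------------------------------------------------------------

def sibship_matrix(pedigree: Pedigree, members: np.ndarray,
                   mode: str = "full") -> np.ndarray:
    """Binary sibling-indicator covariance structure.

    Unit diagonal; off-diagonal 1 for every pair of members who are siblings
    - sharing both parents (``mode="full"``, the default used throughout the
    simulation study) or sharing the same mother (``mode="maternal"``, the
    definition used for real-data analyses where paternity is less certain).
    """
    members = np.asarray(members)
    n = members.size
    S = np.eye(n)
    fa = pedigree.father[members]
    mo = pedigree.mother[members]
    if mode == "full":
        keys = [(int(f), int(m)) if f >= 0 else None
                for f, m in zip(fa, mo)]
    elif mode == "maternal":
        keys = [int(m) if m >= 0 else None for m in mo]
    else:
        raise ValueError(f"unknown sibling mode {mode!r}")
    groups: dict = {}
    for k, key in enumerate(keys):
        if key is not None:
            groups.setdefault(key, []).append(k)
    for sibs in groups.values():
        for a in range(len(sibs)):
            for b in range(a + 1, len(sibs)):
                S[sibs[a], sibs[b]] = S[sibs[b], sibs[a]] = 1.0
    return S
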