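"""Synthetic reference data: haplotype pools, genetic maps, isolate pedigrees.

Everything downstream (mosaic copying, gene-dropping, GRMs, variance
decomposition) is exercised on data produced here, so the generators aim to
reproduce the coarse features of a sequencing reference panel and of a deep
genealogy from a population isolate:

* a phased haplotype pool with a rare-variant-heavy site-frequency spectrum
  (most variants below 1% minor allele frequency) and local linkage
  disequilibrium induced by building the pool itself as recombinant mosaics
  of a small set of seed haplotypes;
* a multi-generation closed pedigree (no migrants after founding) whose
  bottom stratum is flagged as genotyped and contains full-sibling pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GeneticMap",
    "HaplotypePool",
    "Pedigree",
    "uniform_map",
    "generate_reference_pool",
    "generate_isolate_pedigree",
]


# ---------------------------------------------------------------------------
# Genetic map
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneticMap:
    """A genetic map on one chromosome.

    Parameters
    ----------
    positions : ndarray of int
        Physical coordinates (bp, 0-based), strictly increasing.
    cm : ndarray of float
        Cumulative genetic position (centimorgan) at each physical position;
        non-decreasing, starts at 0.
    """

    positions: np.ndarray
    cm: np.ndarray

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=np.int64)
        cm = np.asarray(self.cm, dtype=np.float64)
        if pos.ndim != 1 or cm.shape != pos.shape:
            raise ValueError("positions and cm must be 1-D arrays of equal length")
        if pos.size == 0:
            raise ValueError("empty genetic map")
        if pos.size > 1 and not np.all(np.diff(pos) > 0):
            raise ValueError("positions must be strictly increasing")
        if np.any(np.diff(cm) < 0):
            raise ValueError("cumulative cM must be non-decreasing")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "cm", cm - cm[0])

    @property
    def length_cm(self) -> float:
        return float(self.cm[-1] - self.cm[0])

    @property
    def rate_cm_per_mb(self) -> np.ndarray:
        """Per-interval recombination rate (cM/Mb)."""
        dbp = np.diff(self.positions) / 1e6
        return np.diff(self.cm) / np.where(dbp > 0, dbp, np.nan)

    def cm_at(self, bp) -> np.ndarray:
        """Interpolated genetic position for arbitrary physical coordinates."""
        return np.interp(np.asarray(bp, dtype=float),
                         self.positions.astype(float), self.cm)


def uniform_map(positions, rate_cm_per_mb: float = 1.0) -> GeneticMap:
    """Constant-rate genetic map: cumulative cM = rate x Mb distance.

    A rate of zero gives a zero-length map (no recombination anywhere).
    """
    if rate_cm_per_mb < 0:
        raise ValueError(f"recombination rate must be >= 0, got {rate_cm_per_mb}")
    pos = np.asarray(positions, dtype=np.int64)
    if pos.size and np.any(np.diff(pos) <= 0):
        raise ValueError("positions must be strictly increasing")
    cm = (pos - pos[0]) / 1e6 * rate_cm_per_mb
    return GeneticMap(pos, cm)


# ---------------------------------------------------------------------------
# Haplotype pool
# ---------------------------------------------------------------------------

@dataclass
class HaplotypePool:
    """Phased reference haplotypes on one chromosome.

    Attributes
    ----------
    alleles : ndarray, shape (n_haplotypes, n_sites), values in {0, 1}
    gmap : GeneticMap
        Genetic map evaluated at the site positions.
    """

    alleles: np.ndarray
    gmap: GeneticMap

    def __post_init__(self):
        a = np.ascontiguousarray(self.alleles, dtype=np.uint8)
        if a.ndim != 2:
            raise ValueError("alleles must be 2-D (haplotype x site)")
        if a.size and a.max() > 1:
            raise ValueError("alleles must be binary")
        if a.shape[1] != self.gmap.positions.size:
            raise ValueError("site count does not match genetic map")
        self.alleles = a

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    @property
    def positions(self) -> np.ndarray:
        return self.gmap.positions

    @property
    def freqs(self) -> np.ndarray:
        """Alternate-allele frequency per site (column mean of alleles)."""
        return self.alleles.mean(axis=0)

    @property
    def maf(self) -> np.ndarray:
        f = self.freqs
        return np.minimum(f, 1.0 - f)


#: fraction of sites rarer than 1% MAF the auto-calibrated spectrum targets
RARE_FRACTION_TARGET = 0.55


def calibrate_sfs_shape(n_haplotypes: int,
                        rare_fraction: float = RARE_FRACTION_TARGET) -> float:
    """Power-law exponent giving the target share of sub-1%-MAF variants.

    A real sequencing panel has just over half of its variants below 1%
    minor allele frequency.  How steep a truncated power-law spectrum must
    be to reproduce that depends on the pool size (at 200 haplotypes only
    singletons are below 1%; at 7,500 the first ~75 count classes are), so
    the exponent is solved by bisection per pool size rather than fixed.
    """
    counts = np.arange(1, n_haplotypes)
    maf = np.minimum(counts, n_haplotypes - counts) / n_haplotypes
    rare = maf < 0.01
    if not rare.any():
        return 2.0      # pool too small for sub-1% variants to exist

    def frac(alpha):
        w = counts.astype(float) ** (-alpha)
        return w[rare].sum() / w.sum()

    lo, hi = 0.1, 6.0
    if frac(hi) < rare_fraction:
        return hi
    for _ in range(60):
        mid = (lo + hi) / 2
        if frac(mid) < rare_fraction:
            lo = mid
        else:
            hi = mid
    return hi


def generate_reference_pool(
    n_haplotypes: int,
    n_sites: int,
    sfs_shape: float | None = None,
    seed: int | np.random.Generator = 0,
    *,
    n_seed_haplotypes: int = 60,
    chrom_length_bp: int = 100_000_000,
    rate_cm_per_mb: float = 1.0,
    switch_intensity: float = 2.0,
) -> HaplotypePool:
    """Generate a phased reference pool with a rare-heavy frequency spectrum.

    Per-site alternate-allele counts are drawn from a truncated power-law
    spectrum P(c) proportional to c**(-sfs_shape) on 1 <= c <= n_haplotypes-1,
    so no site is monomorphic.  By default the shape is calibrated per pool
    size (:func:`calibrate_sfs_shape`) so that just over half of the sites
    fall below 1% minor allele frequency, reproducing the headline property
    of a sequencing imputation panel while keeping a realistic common-variant
    mass.

    Local LD is induced by first tiling every pool haplotype with a mosaic of
    ``n_seed_haplotypes`` ancestral labels (switches follow a Poisson process
    of ``switch_intensity`` per cM on the map; the default gives ancestry
    blocks of ~0.5 cM, the scale over which panel LD decays) and then placing
    the carriers of each variant preferentially on haplotypes that share the
    local ancestral label; nearby sites therefore tend to select nested
    carrier sets, while sites further apart than an ancestry block are
    essentially independent.

    Returns a :class:`HaplotypePool` on a uniform genetic map.
    """
    rng = np.random.default_rng(seed)
    if n_haplotypes < 4 or n_haplotypes % 2:
        raise ValueError("n_haplotypes must be even and >= 4")
    if n_sites < 1:
        raise ValueError("n_sites must be positive")
    if n_seed_haplotypes < 2:
        raise ValueError("need at least 2 seed haplotypes")
    if sfs_shape is None:
        sfs_shape = calibrate_sfs_shape(n_haplotypes)

    positions = np.sort(rng.choice(np.int64(chrom_length_bp), size=n_sites,
                                   replace=False))
    gmap = uniform_map(positions, rate_cm_per_mb)
    site_cm = gmap.cm

    # ancestral-label mosaic per pool haplotype
    labels = np.empty((n_haplotypes, n_sites), dtype=np.int16)
    for h in range(n_haplotypes):
        labels[h] = _label_path(rng, site_cm, n_seed_haplotypes,
                                switch_intensity)

    # per-site focal ancestry: itself a piecewise-constant process along the map
    focal = _label_path(rng, site_cm, n_seed_haplotypes, switch_intensity)

    # alternate-allele counts from the truncated power-law spectrum
    counts = np.arange(1, n_haplotypes)
    pmf = counts.astype(float) ** (-float(sfs_shape))
    pmf /= pmf.sum()
    alt_count = rng.choice(counts, size=n_sites, p=pmf)

    perm = rng.permutation(n_haplotypes)  # fixed tie-break order -> nested carriers
    alleles = np.zeros((n_haplotypes, n_sites), dtype=np.uint8)
    for s in range(n_sites):
        on_focal = labels[perm, s] == focal[s]
        carriers = np.concatenate((perm[on_focal], perm[~on_focal]))[: alt_count[s]]
        alleles[carriers, s] = 1

    return HaplotypePool(alleles, gmap)


def _label_path(rng: np.random.Generator, site_cm: np.ndarray, n_labels: int,
                intensity_per_cm: float) -> np.ndarray:
    """Piecewise-constant label process along a map (Poisson switch points)."""
    length = float(site_cm[-1]) if site_cm.size else 0.0
    n_switch = rng.poisson(intensity_per_cm * length)
    cuts = np.sort(rng.uniform(0.0, length, size=n_switch)) if n_switch else \
        np.empty(0)
    labels = rng.integers(0, n_labels, size=n_switch + 1)
    idx = np.searchsorted(cuts, site_cm, side="right")
    return labels[idx].astype(np.int16)


# ---------------------------------------------------------------------------
# Pedigree
# ---------------------------------------------------------------------------

@dataclass
class Pedigree:
    """A pedigree as parallel arrays with parent links by index.

    ``father`` / ``mother`` hold the row index of each parent or -1 for a
    founder.  Founders have both parents absent; non-founders have both
    present.  The graph must be acyclic (checked on construction).
    """

    ids: np.ndarray                  # unique identifiers (str)
    father: np.ndarray               # int index into ids, -1 = absent
    mother: np.ndarray
    sex: np.ndarray                  # 1 = male, 2 = female
    is_genotyped: np.ndarray         # bool
    generation: np.ndarray | None = None
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self.ids = np.asarray(self.ids)
        self.father = np.asarray(self.father, dtype=np.int64)
        self.mother = np.asarray(self.mother, dtype=np.int64)
        self.sex = np.asarray(self.sex, dtype=np.int8)
        self.is_genotyped = np.asarray(self.is_genotyped, dtype=bool)
        n = self.ids.size
        if len(set(self.ids.tolist())) != n:
            raise ValueError("duplicate individual ids")
        for arr, name in ((self.father, "father"), (self.mother, "mother")):
            if arr.shape != (n,):
                raise ValueError(f"{name} has wrong shape")
            if np.any(arr >= n) or np.any(arr < -1):
                raise ValueError(f"{name} contains out-of-range indices")
        half = (self.father < 0) != (self.mother < 0)
        if np.any(half):
            raise ValueError("individuals must have both parents or neither")
        self._index = {i: k for k, i in enumerate(self.ids.tolist())}
        self._toposort()  # raises on cycles

    # -- basic structure ----------------------------------------------------

    @property
    def n(self) -> int:
        return self.ids.size

    @property
    def is_founder(self) -> np.ndarray:
        return self.father < 0

    @property
    def founders(self) -> np.ndarray:
        return np.flatnonzero(self.is_founder)

    def index_of(self, ident) -> int:
        try:
            return self._index[ident]
        except KeyError:
            raise KeyError(f"unknown individual id: {ident!r}") from None

    def _toposort(self) -> np.ndarray:
        """Topological order (parents before children); raises on cycles."""
        if getattr(self, "_topo", None) is not None:
            return self._topo
        n = self.n
        depth = np.full(n, -1, dtype=np.int64)

        def visit(i, stack):
            if depth[i] >= 0:
                return depth[i]
            if i in stack:
                raise ValueError("pedigree contains a cycle")
            stack.add(i)
            d = 0
            if self.father[i] >= 0:
                d = 1 + max(visit(self.father[i], stack), visit(self.mother[i], stack))
            stack.discard(i)
            depth[i] = d
            return d

        import sys
        old = sys.getrecursionlimit()
        sys.setrecursionlimit(max(old, 10 * n + 100))
        try:
            for i in range(n):
                visit(i, set())
        finally:
            sys.setrecursionlimit(old)
        self._depth = depth
        self._topo = np.argsort(depth, kind="stable")
        return self._topo

    @property
    def topological_order(self) -> np.ndarray:
        return self._toposort()

    # -- sibships -----------------------------------------------------------

    def full_sib_pairs(self, members: np.ndarray | None = None) -> list[tuple[int, int]]:
        """All pairs (i, j), i < j, sharing both parents (non-founders only)."""
        idx = np.arange(self.n) if members is None else np.asarray(members)
        idx = idx[self.father[idx] >= 0]
        groups: dict[tuple[int, int], list[int]] = {}
        for i in idx.tolist():
            groups.setdefault((int(self.father[i]), int(self.mother[i])), []).append(i)
        pairs = []
        for sibs in groups.values():
            sibs.sort()
            for a in range(len(sibs)):
                for b in range(a + 1, len(sibs)):
                    pairs.append((sibs[a], sibs[b]))
        return pairs

    def sibship_labels(self, members: np.ndarray) -> np.ndarray:
        """Integer sibship label per member; singletons get unique labels."""
        members = np.asarray(members)
        keys = {}
        out = np.empty(members.size, dtype=np.int64)
        for k, i in enumerate(members.tolist()):
            if self.father[i] >= 0:
                key = (int(self.father[i]), int(self.mother[i]))
            else:
                key = ("founder", i)
            out[k] = keys.setdefault(key, len(keys))
        return out

    # -- IO -----------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        def name(arr):
            return np.where(arr >= 0, self.ids[np.maximum(arr, 0)], "0")
        return pd.DataFrame({
            "id": self.ids,
            "father": name(self.father),
            "mother": name(self.mother),
            "sex": self.sex,
            "genotyped": self.is_genotyped.astype(int),
        })

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Pedigree":
        ids = df["id"].astype(str).to_numpy()
        lookup = {i: k for k, i in enumerate(ids.tolist())}
        missing = {"0", "", "nan", "NA"}

        def link(col):
            return np.array([lookup[v] if v not in missing else -1
                             for v in df[col].astype(str)], dtype=np.int64)

        sex = df["sex"].to_numpy() if "sex" in df else np.zeros(len(df), np.int8)
        gt = df["genotyped"].to_numpy().astype(bool) if "genotyped" in df \
            else np.ones(len(df), bool)
        return cls(ids, link("father"), link("mother"), sex, gt)


def generate_isolate_pedigree(
    n_founders: int,
    n_generations: int,
    mean_sibship: float = 3.0,
    target_genotyped: int | None = None,
    seed: int | np.random.Generator = 0,
    *,
    bottleneck: int = 6,
) -> Pedigree:
    """Grow a closed multi-generation pedigree from a founding cohort.

    Founders form generation 0; every later individual has both parents
    inside the population (isolate closure - no migrants after founding).
    Couples are monogamous, formed at random within a generation while
    avoiding first-degree matings (sibs, parent-child cannot occur across
    generations by construction), and receive children multinomially so that
    sibship sizes average ``mean_sibship``.  Generation sizes follow a
    contraction / re-expansion trajectory (down to roughly 1/``bottleneck``
    of the founding size at mid-history) - the village-scale demography that
    gives a real isolate its genetic drift, cryptic relatedness and
    consanguinity.  The final generation is the genotyped stratum: exactly
    ``target_genotyped`` of its members are flagged (default: all of them),
    guaranteeing full-sibling pairs among the genotyped at realistic sibship
    sizes.
    """
    rng = np.random.default_rng(seed)
    if n_founders < 2:
        raise ValueError("need at least 2 founders")
    if n_generations < 2:
        raise ValueError("need at least 2 generations")
    if mean_sibship <= 0:
        raise ValueError("mean_sibship must be positive")

    ids: list[str] = []
    father: list[int] = []
    mother: list[int] = []
    sex: list[int] = []
    generation: list[int] = []

    gen_count: dict[int, int] = {}

    def add(gen, f, m, s):
        k = len(ids)
        c = gen_count.get(gen, 0)
        gen_count[gen] = c + 1
        ids.append(f"G{gen}-{c}")
        father.append(f)
        mother.append(m)
        sex.append(s)
        generation.append(gen)
        return k

    # generation 0: founders, balanced sexes
    for k in range(n_founders):
        add(0, -1, -1, 1 + k % 2)

    if target_genotyped is None:
        target_genotyped = n_founders
    # demographic feasibility: couples cannot exceed half the population and
    # each produces mean_sibship children on average
    attainable = (n_founders / 2.0) * mean_sibship ** (n_generations - 1)
    if target_genotyped > attainable:
        raise ValueError(
            f"target_genotyped={target_genotyped} is unreachable from "
            f"{n_founders} founders in {n_generations} generations at mean "
            f"sibship {mean_sibship}")
    # size schedule: founding cohort, contraction to village scale, then
    # re-expansion to a last generation comfortably above the genotyped
    # target -- the demographic history that gives an isolate its drift,
    # cryptic relatedness and consanguinity
    final_size = max(int(np.ceil(target_genotyped * 1.12)), 4)
    if n_generations < 4 or bottleneck <= 1:
        sizes = np.linspace(n_founders, final_size, n_generations)
    else:
        mid_size = max(min(n_founders, final_size) // bottleneck, 4)
        half = n_generations // 2
        sizes = np.concatenate([
            np.linspace(n_founders, mid_size, half, endpoint=False),
            np.linspace(mid_size, final_size, n_generations - half),
        ])
    sizes = np.maximum(sizes.round().astype(int), 4)

    prev = list(range(n_founders))
    for gen in range(1, n_generations):
        males = [i for i in prev if sex[i] == 1]
        females = [i for i in prev if sex[i] == 2]
        rng.shuffle(males)
        rng.shuffle(females)
        couples = []
        used_f: set[int] = set()
        for mle in males:
            for fem in females:
                if fem in used_f:
                    continue
                same_parents = father[mle] >= 0 and \
                    (father[mle], mother[mle]) == (father[fem], mother[fem])
                if same_parents:
                    continue
                couples.append((mle, fem))
                used_f.add(fem)
                break
        if not couples and males and females:
            # tiny generation of a single sibship: permit a sib mating
            # rather than letting the population die out
            couples.append((males[0], females[0]))
        if not couples:
            raise ValueError("pedigree growth stalled: no valid couples")
        n_children = int(sizes[gen])
        n_used = max(1, min(len(couples), int(round(n_children / mean_sibship))))
        chosen = [couples[i] for i in rng.choice(len(couples), size=n_used,
                                                 replace=False)]
        assignment = rng.integers(0, n_used, size=n_children)
        new = []
        for c in range(n_children):
            f, m = chosen[assignment[c]]
            # alternate sexes so small generations stay pairable
            new.append(add(gen, f, m, 1 + c % 2))
        prev = new

    n_total = len(ids)
    last = [i for i in range(n_total) if generation[i] == n_generations - 1]
    n_descendants = n_total - n_founders
    if target_genotyped > n_descendants:
        raise ValueError(
            f"target_genotyped={target_genotyped} exceeds the "
            f"{n_descendants} descendants")
    genotyped = np.zeros(n_total, dtype=bool)
    if target_genotyped > len(last):
        # top up from the penultimate generation if the last one is short
        pool = last + [i for i in range(n_total)
                       if generation[i] == n_generations - 2 and father[i] >= 0]
    else:
        pool = last
    pick = rng.choice(len(pool), size=target_genotyped, replace=False)
    genotyped[np.asarray(pool)[pick]] = True

    return Pedigree(np.array(ids), np.array(father), np.array(mother),
                    np.array(sex), genotyped,
                    generation=np.array(generation))
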