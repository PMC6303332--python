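"""Recombinant mosaic haplotypes copied from a reference pool.

New haplotypes are simulated with the stochastic recombination model used to
generate control individuals in imputation software: a copying path starts
on a uniformly chosen reference haplotype and switches to a new uniformly
chosen one at the points of a Poisson process on the genetic map.  Between
switches, alleles are copied verbatim (no mutation or copy error), and the
origin of every copied segment is recorded so that identity-by-descent can
later be established exactly.

Outbred cohorts are built from two independent mosaics per individual per
chromosome; founder haplotypes for gene-dropping are built the same way but
with the copyable pool restricted to a random subset (long shared haplotypes
among founders are what make the simulated population an isolate).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .synth import GeneticMap, HaplotypePool

__all__ = [
    "MosaicHaplotype",
    "Cohort",
    "sample_mosaic",
    "simulate_outbred_cohort",
    "sample_founder_haplotypes",
    "FounderHaplotypes",
    "DEFAULT_SWITCH_INTENSITY",
]

#: default copying switch intensity, per cM (expected segment length 25 cM)
DEFAULT_SWITCH_INTENSITY = 0.04


def poisson_breaks(rng: np.random.Generator, site_cm: np.ndarray,
                   rate_per_cm: float) -> np.ndarray:
    """Interior site boundaries of a Poisson process on the genetic map.

    Events are drawn on [0, L] cM and mapped to the index of the first site
    at or beyond the event; boundaries at 0 or past the last site are
    dropped, duplicates collapsed.  Returned sorted, each in (0, n_sites).
    """
    length = float(site_cm[-1]) if site_cm.size else 0.0
    if length <= 0 or rate_per_cm <= 0:
        return np.empty(0, dtype=np.int64)
    k = rng.poisson(rate_per_cm * length)
    if k == 0:
        return np.empty(0, dtype=np.int64)
    cuts_cm = np.sort(rng.uniform(0.0, length, size=k))
    bounds = np.searchsorted(site_cm, cuts_cm, side="left").astype(np.int64)
    bounds = np.unique(bounds)
    return bounds[(bounds > 0) & (bounds < site_cm.size)]


@dataclass
class MosaicHaplotype:
    """One haplotype with its copying record.

    ``starts``/``sources`` encode half-open segments: segment ``k`` covers
    sites ``[starts[k], starts[k+1])`` (the last runs to ``n_sites``) and was
    copied from reference haplotype ``sources[k]``.
    """

    alleles: np.ndarray
    starts: np.ndarray
    sources: np.ndarray

    @property
    def n_sites(self) -> int:
        return self.alleles.size

    @property
    def segments(self) -> list[tuple[int, int, int]]:
        ends = np.append(self.starts[1:], self.n_sites)
        return [(int(s), int(e), int(c))
                for s, e, c in zip(self.starts, ends, self.sources)]


def sample_mosaic(
    pool: HaplotypePool,
    gmap: GeneticMap | None = None,
    switch_intensity: float = DEFAULT_SWITCH_INTENSITY,
    seed: int | np.random.Generator = 0,
    *,
    subset: np.ndarray | None = None,
) -> MosaicHaplotype:
    """Draw one mosaic haplotype from a reference pool.

    The initial source is uniform over the pool (or over ``subset``); at each
    switch point of a Poisson(``switch_intensity`` per cM) process the source
    is redrawn uniformly.  Segment sources are recorded even when a redraw
    lands on the current source, so the number of segments minus one equals
    the number of realised switch points.
    """
    rng = np.random.default_rng(seed)
    if pool.n_haplotypes == 0:
        raise ValueError("empty reference pool")
    gmap = gmap or pool.gmap
    choices = np.arange(pool.n_haplotypes) if subset is None \
        else np.asarray(subset, dtype=np.int64)
    if choices.size == 0:
        raise ValueError("empty copyable subset")

    breaks = poisson_breaks(rng, gmap.cm, switch_intensity)
    starts = np.concatenate(([0], breaks)).astype(np.int64)
    sources = choices[rng.integers(0, choices.size, size=starts.size)]
    alleles = _materialize(pool.alleles, starts, sources)
    return MosaicHaplotype(alleles, starts, sources)


def _materialize(ref_alleles: np.ndarray, starts: np.ndarray,
                 sources: np.ndarray) -> np.ndarray:
    n_sites = ref_alleles.shape[1]
    out = np.empty(n_sites, dtype=np.uint8)
    ends = np.append(starts[1:], n_sites)
    for s, e, src in zip(starts, ends, sources):
        out[s:e] = ref_alleles[src, s:e]
    return out


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

@dataclass
class Cohort:
    """Phased diploid individuals across one or more chromosomes.

    ``hap0``/``hap1`` are (individual x site) binary matrices over the
    concatenated site axis; ``genotypes`` is their sum.  ``origins`` records,
    per chromosome and individual, the two segment lists
    ``(starts, sources)`` from which every stretch of each haplotype was
    copied; the meaning of the source label depends on the stage (pool
    haplotype for mosaic cohorts, founder gamete for gene-dropped cohorts).
    """

    hap0: np.ndarray
    hap1: np.ndarray
    positions: np.ndarray            # concatenated physical positions
    site_chrom: np.ndarray           # chromosome index per site
    chrom_offsets: np.ndarray        # start index of each chromosome block
    origins: list                    # [chrom][individual] -> (seg0, seg1)
    label: str = ""
    ids: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.ids is None:
            self.ids = np.array([f"I{k}" for k in range(self.hap0.shape[0])])
        self.ids = np.asarray(self.ids)

    @property
    def genotypes(self) -> np.ndarray:
        return (self.hap0.astype(np.int16) + self.hap1).astype(np.uint8)

    @property
    def n(self) -> int:
        return self.hap0.shape[0]

    @property
    def n_sites(self) -> int:
        return self.hap0.shape[1]

    @property
    def freqs(self) -> np.ndarray:
        return (self.hap0.mean(axis=0) + self.hap1.mean(axis=0)) / 2.0

    @property
    def maf(self) -> np.ndarray:
        f = self.freqs
        return np.minimum(f, 1 - f)

    def subset(self, rows: np.ndarray, label: str | None = None) -> "Cohort":
        rows = np.asarray(rows)
        origins = [[per_chrom[i] for i in rows.tolist()]
                   for per_chrom in self.origins]
        return Cohort(self.hap0[rows], self.hap1[rows], self.positions,
                      self.site_chrom, self.chrom_offsets, origins,
                      label or self.label, self.ids[rows])


def simulate_outbred_cohort(
    pools: HaplotypePool | list[HaplotypePool],
    n_individuals: int,
    switch_intensity: float = DEFAULT_SWITCH_INTENSITY,
    seed: int | np.random.Generator = 0,
    label: str | None = None,
) -> Cohort:
    """Simulate unrelated individuals as independent pairs of mosaics.

    Each individual receives two independent mosaic haplotypes per
    chromosome, copied from the full reference pool; origin (pool-haplotype)
    labels are retained per segment.
    """
    rng = np.random.default_rng(seed)
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    pools = pools if isinstance(pools, list) else [pools]
    h0_blocks, h1_blocks, origins = [], [], []
    for pool in pools:
        h0 = np.empty((n_individuals, pool.n_sites), dtype=np.uint8)
        h1 = np.empty_like(h0)
        per_chrom = []
        for i in range(n_individuals):
            a = sample_mosaic(pool, switch_intensity=switch_intensity, seed=rng)
            b = sample_mosaic(pool, switch_intensity=switch_intensity, seed=rng)
            h0[i], h1[i] = a.alleles, b.alleles
            per_chrom.append(((a.starts, a.sources), (b.starts, b.sources)))
        h0_blocks.append(h0)
        h1_blocks.append(h1)
        origins.append(per_chrom)

    positions = np.concatenate([p.positions for p in pools])
    site_chrom = np.concatenate([np.full(p.n_sites, c, dtype=np.int32)
                                 for c, p in enumerate(pools)])
    offsets = np.cumsum([0] + [p.n_sites for p in pools])[:-1]
    return Cohort(np.hstack(h0_blocks), np.hstack(h1_blocks), positions,
                  site_chrom, offsets, origins,
                  label or f"Outbred({n_individuals})")


# ---------------------------------------------------------------------------
# Founder haplotypes for gene-dropping
# ---------------------------------------------------------------------------

@dataclass
class FounderHaplotypes:
    """Founder gametes for gene-dropping, one allele matrix per chromosome.

    Founder ``k`` (in ``founder_index`` order) owns gametes ``2k`` and
    ``2k + 1``; ``alleles[c]`` has shape (2 x n_founders, n_sites_c).
    ``pool_origins`` keeps the mosaic copying record of every gamete.
    """

    alleles: list[np.ndarray]
    founder_index: np.ndarray
    pool_origins: list            # [chrom][gamete] -> (starts, sources)

    @property
    def n_founders(self) -> int:
        return self.founder_index.size

    @property
    def n_gametes(self) -> int:
        return 2 * self.n_founders


def sample_founder_haplotypes(
    pools: HaplotypePool | list[HaplotypePool],
    pedigree,
    pool_subset_size: int = 200,
    switch_intensity: float = DEFAULT_SWITCH_INTENSITY,
    seed: int | np.random.Generator = 0,
) -> FounderHaplotypes:
    """Draw 2 x n_founders mosaic gametes from a restricted reference subset.

    Per chromosome, a random subset of ``pool_subset_size`` reference
    haplotypes is selected and all founder gametes for that chromosome are
    copied from it, concentrating the founding diversity the way a real
    isolate's founding event does.
    """
    rng = np.random.default_rng(seed)
    pools = pools if isinstance(pools, list) else [pools]
    founders = pedigree.founders
    alleles, origins = [], []
    for pool in pools:
        if pool_subset_size > pool.n_haplotypes:
            raise ValueError(
                f"pool_subset_size={pool_subset_size} exceeds pool size "
                f"{pool.n_haplotypes}")
        subset = rng.choice(pool.n_haplotypes, size=pool_subset_size,
                            replace=False)
        gametes = np.empty((2 * founders.size, pool.n_sites), dtype=np.uint8)
        per_chrom = []
        for g in range(2 * founders.size):
            m = sample_mosaic(pool, switch_intensity=switch_intensity,
                              seed=rng, subset=subset)
            gametes[g] = m.alleles
            per_chrom.append((m.starts, m.sources))
        alleles.append(gametes)
        origins.append(per_chrom)
    return FounderHaplotypes(alleles, founders, origins)
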