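"""Gene-dropping through a pedigree with exact identity-by-descent tracking.

Founder gametes (mosaic haplotypes drawn from a restricted reference subset)
are transmitted down the pedigree: every meiosis passes a recombinant of the
parent's two haplotypes, with crossover points forming a Poisson process on
the genetic map (1 expected crossover per 100 cM, no interference).  Origin
labels compose transitively, so each segment of every descendant haplotype
is annotated with the founder gamete it descends from.  These labels give
*true* genome-wide IBD sharing for every pair - the quantity that pedigree
expectations and genotype-based relationship matrices both try to estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mosaic import Cohort, FounderHaplotypes, poisson_breaks, \
    sample_founder_haplotypes, DEFAULT_SWITCH_INTENSITY
from .synth import GeneticMap, HaplotypePool, Pedigree

__all__ = [
    "gene_drop",
    "true_ibd_matrices",
    "replicate_isolates",
    "drop_one_sib_per_pair",
    "IsolateRecipe",
    "TrueIBDSummary",
]

#: crossovers per cM (definition of the centimorgan)
CROSSOVER_RATE_PER_CM = 0.01


def _segments_at(starts: np.ndarray, sources: np.ndarray,
                 query: np.ndarray) -> np.ndarray:
    """Source label of each query site boundary (query within [0, n_sites))."""
    return sources[np.searchsorted(starts, query, side="right") - 1]


def _meiosis(rng: np.random.Generator, hap_a, hap_b, site_cm: np.ndarray):
    """Recombine a parent's two segment tracks into one transmitted gamete."""
    n_sites = site_cm.size
    breaks = poisson_breaks(rng, site_cm, CROSSOVER_RATE_PER_CM)
    current = int(rng.integers(0, 2))
    bounds = np.concatenate(([0], breaks, [n_sites]))
    out_starts, out_sources = [], []
    tracks = (hap_a, hap_b)
    for k in range(bounds.size - 1):
        s, e = int(bounds[k]), int(bounds[k + 1])
        if s == e:
            current ^= 1
            continue
        starts, sources = tracks[current]
        j0 = int(np.searchsorted(starts, s, side="right")) - 1
        j1 = int(np.searchsorted(starts, e, side="left"))
        sub = starts[j0:j1].copy()
        sub[0] = s
        out_starts.append(sub)
        out_sources.append(sources[j0:j1])
        current ^= 1
    return np.concatenate(out_starts), np.concatenate(out_sources)


def gene_drop(
    pedigree: Pedigree,
    founder_haps: FounderHaplotypes,
    maps: list[GeneticMap],
    seed: int | np.random.Generator = 0,
    members: np.ndarray | None = None,
    label: str | None = None,
) -> Cohort:
    """Drop founder gametes through the pedigree and return phased genomes.

    Returns a :class:`~heritvc.mosaic.Cohort` for the genotyped members
    (or an explicit ``members`` index list) whose ``origins`` are founder
    gamete labels: founders carry a single segment per haplotype labelled
    with their own gametes, and every descendant segment's label is one of
    the founder gametes.  Genotypes are materialised by copying alleles from
    the founder gamete matrices.
    """
    rng = np.random.default_rng(seed)
    if founder_haps.n_founders != pedigree.founders.size:
        raise ValueError("founder haplotypes do not cover this pedigree's "
                         "founders (need 2 gametes per founder)")
    if len(founder_haps.alleles) != len(maps):
        raise ValueError("one genetic map per chromosome is required")
    founder_slot = {int(f): k for k, f in enumerate(founder_haps.founder_index)}
    if members is None:
        members = np.flatnonzero(pedigree.is_genotyped)
    members = np.asarray(members)

    all_h0, all_h1, origins = [], [], []
    for c, gmap in enumerate(maps):
        site_cm = gmap.cm
        n_sites = site_cm.size
        segs: list = [None] * pedigree.n
        for i in pedigree.topological_order.tolist():
            f, m = int(pedigree.father[i]), int(pedigree.mother[i])
            if f < 0:
                g = founder_slot[i]
                one = np.zeros(1, dtype=np.int64)
                segs[i] = ((one, np.array([2 * g], dtype=np.int64)),
                           (one.copy(), np.array([2 * g + 1], dtype=np.int64)))
            else:
                pat = _meiosis(rng, *segs[f], site_cm=site_cm)
                mat = _meiosis(rng, *segs[m], site_cm=site_cm)
                segs[i] = (pat, mat)

        gametes = founder_haps.alleles[c]
        h0 = np.empty((members.size, n_sites), dtype=np.uint8)
        h1 = np.empty_like(h0)
        per_chrom = []
        for row, i in enumerate(members.tolist()):
            for hap, out in zip(segs[i], (h0, h1)):
                starts, sources = hap
                ends = np.append(starts[1:], n_sites)
                for s, e, src in zip(starts, ends, sources):
                    out[row, s:e] = gametes[src, s:e]
            per_chrom.append(segs[i])
        all_h0.append(h0)
        all_h1.append(h1)
        origins.append(per_chrom)

    positions = np.concatenate([g.positions for g in maps])
    site_chrom = np.concatenate([np.full(g.positions.size, c, dtype=np.int32)
                                 for c, g in enumerate(maps)])
    offsets = np.cumsum([0] + [g.positions.size for g in maps])[:-1]
    return Cohort(np.hstack(all_h0), np.hstack(all_h1), positions, site_chrom,
                  offsets, origins, label or f"Isolated({members.size})",
                  ids=pedigree.ids[members])


# ---------------------------------------------------------------------------
# True IBD
# ---------------------------------------------------------------------------

@dataclass
class TrueIBDSummary:
    """Pairwise genome fractions of IBD sharing derived from origin labels.

    ``K_true = ibd2 + ibd1 / 2`` (twice the realised kinship) and ``D_true``
    is the genome fraction where both alleles are shared IBD.  Diagonals:
    ``K_true[i, i] = 1 + f_i`` with ``f_i`` the realised autozygous fraction,
    ``D_true[i, i] = 1``.
    """

    ibd1_share: np.ndarray
    ibd2_share: np.ndarray
    K_true: np.ndarray
    D_true: np.ndarray


def _site_weights(cohort: Cohort, weight: str) -> np.ndarray:
    """Cumulative weight per site boundary, per chromosome concatenation."""
    cum = []
    for c in range(len(cohort.origins)):
        mask = cohort.site_chrom == c
        pos = cohort.positions[mask].astype(float)
        if weight == "sites" or pos.size < 2:
            w = np.ones(pos.size)
        elif weight == "physical":
            d = np.diff(pos)
            w = np.append(d, d.mean())
        else:
            raise ValueError(f"unknown weight scheme {weight!r}")
        cum.append(np.concatenate(([0.0], np.cumsum(w))))
    return cum


def true_ibd_matrices(cohort: Cohort, weight: str = "physical") -> TrueIBDSummary:
    """Exact pairwise IBD-sharing fractions from recorded origin labels.

    For every pair, the four haplotype origin tracks are intersected on a
    merged breakpoint grid; each interval contributes its (physical, by
    default) length to IBD=1 or IBD=2 according to how many disjoint
    founder-gamete matches exist between the two individuals' haplotypes.
    """
    n = cohort.n
    ibd1 = np.zeros((n, n))
    ibd2 = np.zeros((n, n))
    selff = np.zeros(n)
    cum_weights = _site_weights(cohort, weight)
    total = sum(float(cw[-1]) for cw in cum_weights)

    for c, per_chrom in enumerate(cohort.origins):
        cw = cum_weights[c]
        tracks = per_chrom
        for i in range(n):
            (sa0, ca0), (sa1, ca1) = tracks[i]
            # autozygosity
            u = np.unique(np.concatenate((sa0, sa1)))
            w = cw[np.append(u[1:], cw.size - 1)] - cw[u]
            same = _segments_at(sa0, ca0, u) == _segments_at(sa1, ca1, u)
            selff[i] += float(w[same].sum())
            for j in range(i + 1, n):
                (sb0, cb0), (sb1, cb1) = tracks[j]
                u = np.unique(np.concatenate((sa0, sa1, sb0, sb1)))
                w = cw[np.append(u[1:], cw.size - 1)] - cw[u]
                a0 = _segments_at(sa0, ca0, u)
                a1 = _segments_at(sa1, ca1, u)
                b0 = _segments_at(sb0, cb0, u)
                b1 = _segments_at(sb1, cb1, u)
                two = ((a0 == b0) & (a1 == b1)) | ((a0 == b1) & (a1 == b0))
                one = (~two) & ((a0 == b0) | (a0 == b1) |
                                (a1 == b0) | (a1 == b1))
                ibd2[i, j] += float(w[two].sum())
                ibd1[i, j] += float(w[one].sum())

    ibd1 = (ibd1 + ibd1.T) / total
    ibd2 = (ibd2 + ibd2.T) / total
    selff /= total
    np.fill_diagonal(ibd2, 1.0)
    np.fill_diagonal(ibd1, 0.0)
    K = ibd2 + ibd1 / 2.0
    np.fill_diagonal(K, 1.0 + selff)
    D = ibd2.copy()
    np.fill_diagonal(D, 1.0)
    return TrueIBDSummary(ibd1, ibd2, K, D)


# ---------------------------------------------------------------------------
# Population variants used in the study
# ---------------------------------------------------------------------------

@dataclass
class IsolateRecipe:
    """Everything needed to gene-drop one isolate cohort."""

    pedigree: Pedigree
    pools: list[HaplotypePool]
    pool_subset_size: int = 200
    switch_intensity: float = DEFAULT_SWITCH_INTENSITY

    def simulate(self, seed) -> Cohort:
        rng = np.random.default_rng(seed)
        fh = sample_founder_haplotypes(
            self.pools, self.pedigree, self.pool_subset_size,
            self.switch_intensity, seed=rng)
        return gene_drop(self.pedigree, fh,
                         [p.gmap for p in self.pools], seed=rng)


def replicate_isolates(base: IsolateRecipe, k: int,
                       seed: int | np.random.Generator = 0) -> Cohort:
    """Stack ``k`` independent gene-dropped copies of the same pedigree.

    Each copy uses a fresh draw of founding haplotypes, so between-copy true
    relatedness is only whatever the shared reference pool induces; founder
    gamete labels are offset per copy, making cross-copy origin labels
    disjoint by construction.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(seed)
    cohorts = [base.simulate(rng) for _ in range(k)]
    if k == 1:
        return cohorts[0]
    gametes_per_copy = 2 * base.pedigree.founders.size
    h0 = np.vstack([c.hap0 for c in cohorts])
    h1 = np.vstack([c.hap1 for c in cohorts])
    origins = []
    for c in range(len(cohorts[0].origins)):
        per_chrom = []
        for r, coh in enumerate(cohorts):
            off = r * gametes_per_copy
            for (s0, c0), (s1, c1) in coh.origins[c]:
                per_chrom.append(((s0, c0 + off), (s1, c1 + off)))
        origins.append(per_chrom)
    ids = np.concatenate([np.char.add(f"R{r}:", c.ids.astype(str))
                          for r, c in enumerate(cohorts)])
    first = cohorts[0]
    return Cohort(h0, h1, first.positions, first.site_chrom,
                  first.chrom_offsets, origins,
                  f"Isolated({h0.shape[0]})", ids=ids)


def cohort_pedigree_rows(cohort: Cohort, pedigree: Pedigree):
    """Map cohort members to pedigree rows and replicate tags."""
    rows, tags = [], []
    for ident in cohort.ids.tolist():
        tag, _, name = str(ident).rpartition(":")
        rows.append(pedigree.index_of(name if name else ident))
        tags.append(tag)
    return np.asarray(rows), np.asarray(tags)


def drop_one_sib_per_pair(cohort: Cohort, pedigree: Pedigree,
                          seed: int | np.random.Generator = 0) -> Cohort:
    """Remove one random member of every full-sib pair until none remain.

    Siblings are pairs sharing both parents (within the same replicate copy
    for stacked cohorts).  A sibship of size s keeps exactly one survivor.
    """
    rng = np.random.default_rng(seed)
    rows, tags = cohort_pedigree_rows(cohort, pedigree)
    groups: dict = {}
    for k, (row, tag) in enumerate(zip(rows.tolist(), tags.tolist())):
        f, m = int(pedigree.father[row]), int(pedigree.mother[row])
        key = (tag, f, m) if f >= 0 else ("founder", tag, k)
        groups.setdefault(key, []).append(k)
    keep = []
    for members in groups.values():
        if len(members) == 1:
            keep.append(members[0])
        else:
            keep.append(members[int(rng.integers(0, len(members)))])
    keep = np.sort(np.asarray(keep))
    out = cohort.subset(keep)
    out.label = f"{cohort.label.split('(')[0]}({keep.size})_nosibs"
    return out
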