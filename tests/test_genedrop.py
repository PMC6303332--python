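"""Gene-dropping, true IBD sharing and population variants."""

import numpy as np
import pytest

from heritvc.synth import HaplotypePool, Pedigree, uniform_map
from heritvc.mosaic import sample_founder_haplotypes
from heritvc.genedrop import (IsolateRecipe, drop_one_sib_per_pair, gene_drop,
                              replicate_isolates, true_ibd_matrices)


def _one_site_pool(seed=0):
    """A single unlinked site: gene-dropping reduces to allele transmission."""
    alleles = np.array([[0], [1], [1], [0], [1], [0]], dtype=np.uint8)
    return HaplotypePool(alleles, uniform_map(np.array([100]), 0.0))


def _flat_pool(n_hap=8, n_sites=40, seed=1):
    rng = np.random.default_rng(seed)
    alleles = rng.integers(0, 2, (n_hap, n_sites)).astype(np.uint8)
    gmap = uniform_map(np.arange(n_sites) * 1_000_000, 0.0)  # zero length
    return HaplotypePool(alleles, gmap)


class TestGeneDrop:
    def test_zero_map_transmits_intact_founder_gametes(self, nuclear_pedigree):
        pool = _flat_pool()
        fh = sample_founder_haplotypes(pool, nuclear_pedigree,
                                       pool_subset_size=8, seed=2)
        cohort = gene_drop(nuclear_pedigree, fh, [pool.gmap], seed=3)
        # no recombination: every haplotype equals one intact founder gamete
        for row, ((s0, c0), (s1, c1)) in enumerate(cohort.origins[0]):
            assert s0.size == 1 and s1.size == 1
            np.testing.assert_array_equal(cohort.hap0[row],
                                          fh.alleles[0][c0[0]])
            np.testing.assert_array_equal(cohort.hap1[row],
                                          fh.alleles[0][c1[0]])

    def test_origin_labels_are_founder_gametes(self, nuclear_pedigree):
        pool = _flat_pool()
        fh = sample_founder_haplotypes(pool, nuclear_pedigree,
                                       pool_subset_size=8, seed=4)
        cohort = gene_drop(nuclear_pedigree, fh, [pool.gmap], seed=5)
        for (_, c0), (_, c1) in cohort.origins[0]:
            assert set(c0.tolist()) | set(c1.tolist()) <= set(range(4))

    def test_parent_offspring_kinship_monte_carlo(self, nuclear_pedigree):
        # a parent and its child share exactly one allele IBD at every
        # locus, so every replicate drop realises kinship exactly 1/4
        pool = _one_site_pool()
        rng = np.random.default_rng(6)
        members = np.array([0, 2])  # founder F0 and child C0
        for _ in range(50):
            fh = sample_founder_haplotypes(pool, nuclear_pedigree,
                                           pool_subset_size=6, seed=rng)
            coh = gene_drop(nuclear_pedigree, fh, [pool.gmap], seed=rng,
                            members=members)
            ibd = true_ibd_matrices(coh)
            assert ibd.ibd1_share[0, 1] == 1.0
            assert ibd.K_true[0, 1] == 0.5

    def test_missing_founder_haplotypes_rejected(self, nuclear_pedigree,
                                                 sibmating_pedigree):
        pool = _flat_pool()
        fh = sample_founder_haplotypes(pool, nuclear_pedigree,
                                       pool_subset_size=8, seed=0)
        fh_bad = type(fh)(fh.alleles, fh.founder_index[:1], fh.pool_origins)
        with pytest.raises(ValueError):
            gene_drop(nuclear_pedigree, fh_bad, [pool.gmap], seed=0)


class TestTrueIBD:
    def test_identical_twins_share_everything(self, nuclear_pedigree):
        # simulate 'twins' by giving both children the same gametes
        pool = _flat_pool()
        fh = sample_founder_haplotypes(pool, nuclear_pedigree,
                                       pool_subset_size=8, seed=7)
        cohort = gene_drop(nuclear_pedigree, fh, [pool.gmap], seed=8)
        twin = cohort.subset(np.array([0, 0]))
        ibd = true_ibd_matrices(twin)
        assert ibd.ibd2_share[0, 1] == 1.0
        assert ibd.D_true[0, 1] == 1.0
        assert ibd.K_true[0, 1] >= 1.0

    def test_founders_share_nothing(self, nuclear_pedigree):
        pool = _flat_pool()
        fh = sample_founder_haplotypes(pool, nuclear_pedigree,
                                       pool_subset_size=8, seed=9)
        cohort = gene_drop(nuclear_pedigree, fh, [pool.gmap], seed=10,
                           members=np.array([0, 1]))
        ibd = true_ibd_matrices(cohort)
        assert ibd.K_true[0, 1] == 0.0
        assert ibd.D_true[0, 1] == 0.0

    def test_sib_ibd2_monte_carlo(self, nuclear_pedigree):
        # at a single unlinked locus sibs share two alleles IBD w.p. 1/4
        pool = _one_site_pool()
        rng = np.random.default_rng(11)
        vals = []
        for _ in range(4000):
            fh = sample_founder_haplotypes(pool, nuclear_pedigree,
                                           pool_subset_size=6, seed=rng)
            coh = gene_drop(nuclear_pedigree, fh, [pool.gmap], seed=rng)
            vals.append(true_ibd_matrices(coh).D_true[0, 1])
        se = np.std(vals) / np.sqrt(len(vals))
        assert abs(np.mean(vals) - 0.25) < 3 * se

    def test_bounds_and_symmetry(self, small_pool, nuclear_pedigree):
        fh = sample_founder_haplotypes(small_pool, nuclear_pedigree,
                                       pool_subset_size=20, seed=12)
        cohort = gene_drop(nuclear_pedigree, fh, [small_pool.gmap], seed=13)
        ibd = true_ibd_matrices(cohort)
        assert np.all(ibd.ibd1_share + ibd.ibd2_share <= 1 + 1e-12)
        assert np.all(ibd.ibd2_share >= 0)
        np.testing.assert_allclose(ibd.K_true, ibd.K_true.T)


class TestReplication:
    def test_k1_is_identity(self, small_pool, nuclear_pedigree):
        recipe = IsolateRecipe(nuclear_pedigree, [small_pool],
                               pool_subset_size=20)
        a = replicate_isolates(recipe, 1, seed=20)
        b = recipe.simulate(np.random.default_rng(20))
        np.testing.assert_array_equal(a.genotypes, b.genotypes)

    def test_cross_copy_origins_disjoint(self, small_pool, nuclear_pedigree):
        recipe = IsolateRecipe(nuclear_pedigree, [small_pool],
                               pool_subset_size=20)
        stacked = replicate_isolates(recipe, 3, seed=21)
        assert stacked.n == 6
        assert stacked.label == "Isolated(6)"
        ibd = true_ibd_matrices(stacked)
        across = ibd.D_true[:2, 2:]
        assert np.all(across == 0.0)


class TestDropSibs:
    def _cohort(self, pedigree, pool, seed=30):
        fh = sample_founder_haplotypes(pool, pedigree, pool_subset_size=20,
                                       seed=seed)
        return gene_drop(pedigree, fh, [pool.gmap], seed=seed + 1)

    def test_no_sibs_is_fixed_point(self, small_pool):
        ped = Pedigree(np.array(["A", "B", "C"]), np.array([-1, -1, 0]),
                       np.array([-1, -1, 1]), np.array([1, 2, 1]),
                       np.array([True, True, True]))
        cohort = self._cohort(ped, small_pool)
        out = drop_one_sib_per_pair(cohort, ped, seed=0)
        assert out.n == cohort.n

    def test_sibship_of_three_keeps_one(self, small_pool):
        ped = Pedigree(np.array(["A", "B", "C0", "C1", "C2"]),
                       np.array([-1, -1, 0, 0, 0]),
                       np.array([-1, -1, 1, 1, 1]),
                       np.array([1, 2, 1, 1, 2]),
                       np.array([False, False, True, True, True]))
        cohort = self._cohort(ped, small_pool)
        out = drop_one_sib_per_pair(cohort, ped, seed=1)
        assert out.n == 1

    def test_output_has_no_sib_pairs_bruteforce(self, small_pool):
        from heritvc.synth import generate_isolate_pedigree
        ped = generate_isolate_pedigree(30, 4, target_genotyped=30, seed=31)
        cohort = self._cohort(ped, small_pool)
        out = drop_one_sib_per_pair(cohort, ped, seed=2)
        rows = [ped.index_of(i) for i in out.ids]
        for a in range(len(rows)):
            for b in range(a + 1, len(rows)):
                ra, rb = rows[a], rows[b]
                assert not (ped.father[ra] >= 0 and
                            (ped.father[ra], ped.mother[ra]) ==
                            (ped.father[rb], ped.mother[rb]))
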