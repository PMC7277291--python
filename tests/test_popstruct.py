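"""Haplotype EM, Hudson Fst and neighbour-joining trees."""

import numpy as np
import pytest
import skbio

import mhpanel as mh
from mhpanel.panel_model import DistanceMatrix
from mhpanel.popstruct import em_haplotype_freqs
from mhpanel.simulate import haplotype_alphabet


class TestEm:
    def test_phase_unambiguous_data_equals_direct_counting(self):
        # every sample has at most one heterozygous site: no ambiguity
        genotypes = (
            [((("A", "A")), (("C", "C")))] * 30      # hap AC only
            + [((("A", "G")), (("C", "C")))] * 20    # AC / GC
            + [((("G", "G")), (("C", "C")))] * 10    # GC only
        )
        est = em_haplotype_freqs(genotypes)
        freqs = dict(zip(est.haplotypes, est.frequencies))
        assert freqs[("A", "C")] == pytest.approx(80 / 120, abs=1e-9)
        assert freqs[("G", "C")] == pytest.approx(40 / 120, abs=1e-9)

    def test_two_haplotype_toy_is_forced(self):
        genotypes = [((("A", "A")), (("C", "C")))] * 50 + [((("T", "T")), (("G", "G")))] * 50
        est = em_haplotype_freqs(genotypes)
        freqs = dict(zip(est.haplotypes, est.frequencies))
        assert freqs[("A", "C")] == pytest.approx(0.5, abs=1e-12)
        assert freqs[("T", "G")] == pytest.approx(0.5, abs=1e-12)

    def test_recovers_known_spectrum_from_stripped_phase(self):
        truth = mh.AlleleFrequencySet(
            "mh01sim001", haplotype_alphabet(4), np.array([0.4, 0.3, 0.2, 0.1])
        )
        n = 500
        col = mh.hwe_genotypes(truth, n, seed=41)
        est = em_haplotype_freqs(mh.unphased_from_haplotypes(col), locus_id=truth.locus_id)
        estimated = est.frequency_set().as_dict()
        for allele, p in truth.as_dict().items():
            se = np.sqrt(p * (1 - p) / (2 * n))
            assert abs(estimated.get(allele, 0.0) - p) < 3 * se

    def test_loglik_trace_nondecreasing_and_frequencies_normalized(self):
        truth = mh.sample_allele_freqs(4, 1.0, seed=42)
        col = mh.hwe_genotypes(truth, 120, seed=43)
        est = em_haplotype_freqs(mh.unphased_from_haplotypes(col))
        trace = est.loglik_trace
        assert all(b >= a - 1e-9 for a, b in zip(trace, trace[1:]))
        assert est.frequencies.sum() == pytest.approx(1.0, abs=1e-9)
        assert est.converged

    def test_multi_restart_is_deterministic(self):
        truth = mh.sample_allele_freqs(4, 1.0, seed=44)
        col = mh.hwe_genotypes(truth, 100, seed=45)
        unphased = mh.unphased_from_haplotypes(col)
        a = em_haplotype_freqs(unphased, n_restarts=4, seed=7)
        b = em_haplotype_freqs(unphased, n_restarts=4, seed=7)
        np.testing.assert_array_equal(a.frequencies, b.frequencies)

    def test_site_bound_enforced(self):
        geno = [tuple((("A", "A"),)) * 7]
        with pytest.raises(ValueError, match="at most"):
            em_haplotype_freqs(geno)


class TestFst:
    def test_identical_populations_give_zero(self, synthetic_panel):
        freqs = {f.locus_id: f for f in synthetic_panel[:5]}
        assert mh.hudson_fst(freqs, freqs) == pytest.approx(0.0, abs=1e-12)

    def test_fixed_different_alleles_give_one(self):
        f1 = mh.AlleleFrequencySet("mh01sim001", ("ACG", "ACT"), np.array([1.0, 0.0]))
        f2 = mh.AlleleFrequencySet("mh01sim001", ("ACG", "ACT"), np.array([0.0, 1.0]))
        assert mh.hudson_fst({"mh01sim001": f1}, {"mh01sim001": f2}) == pytest.approx(1.0)

    def test_mean_estimate_matches_generating_theta(self):
        """Balding-Nichols simulation at theta = 0.05: the multi-locus Hudson
        estimate over 200 loci should average the generating theta."""
        estimates = []
        for rep in range(20):
            pf = {"P1": {}, "P2": {}}
            for l in range(200):
                anc = mh.sample_allele_freqs(
                    4, 1.0, seed=100_000 + rep * 200 + l, locus_id=f"mh01sim{l + 1:03d}"
                )
                p1, p2 = mh.bn_population_freqs(anc, 0.05, 2, seed=200_000 + rep * 200 + l)
                pf["P1"][anc.locus_id] = p1
                pf["P2"][anc.locus_id] = p2
            estimates.append(mh.pairwise_fst(pf).get("P1", "P2"))
        assert 0.04 < np.mean(estimates) < 0.06

    def test_matrix_properties_and_truncation(self, synthetic_panel):
        tables = {
            label: mh.hwe_genotype_table(synthetic_panel[:10], 40, seed=s)
            for label, s in [("P1", 51), ("P2", 52), ("P3", 53)]
        }
        dm = mh.fst_from_genotypes(tables)
        assert np.allclose(dm.values, dm.values.T)
        assert np.all(np.diag(dm.values) == 0.0)
        assert np.all(dm.values >= 0.0)
        # identical sampling distributions: raw estimates hover around 0 and
        # may be negative, in which case truncation must have applied
        assert dm.raw is not None
        if (dm.raw < 0).any():
            assert (dm.values[dm.raw < 0] == 0.0).all()

    def test_population_order_invariance(self, synthetic_panel):
        freqs = {f.locus_id: f for f in synthetic_panel[:5]}
        drift = {
            f.locus_id: mh.bn_population_freqs(f, 0.1, 1, seed=60)[0]
            for f in synthetic_panel[:5]
        }
        a = mh.pairwise_fst({"X": freqs, "Y": drift})
        b = mh.pairwise_fst({"Y": drift, "X": freqs})
        assert a.get("X", "Y") == b.get("X", "Y")


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        d = np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0]], dtype=float)
        tree = mh.nj_tree(DistanceMatrix(("A", "B", "C"), d))
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths["A"] == pytest.approx((5 + 9 - 10) / 2)
        assert lengths["B"] == pytest.approx((5 + 10 - 9) / 2)
        assert lengths["C"] == pytest.approx((9 + 10 - 5) / 2)

    def test_additive_four_taxon_matrix_recovered_exactly(self):
        labels = ("A", "B", "C", "D")
        d = np.array(
            [[0, 3, 9, 10], [3, 0, 10, 11], [9, 10, 0, 7], [10, 11, 7, 0]], dtype=float
        )
        tree = mh.nj_tree(DistanceMatrix(labels, d))
        tips = {t.name: t for t in tree.tips()}
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                if i < j:
                    assert tips[a].distance(tips[b]) == pytest.approx(d[i, j], abs=1e-9)
        # independent implementation agrees on the topology
        reference = skbio.tree.nj(skbio.DistanceMatrix(d, ids=labels))
        assert mh.nj_tree(DistanceMatrix(labels, d)).compare_rfd(reference) == 0.0

    def test_equidistant_five_taxa_symmetric(self):
        labels = tuple("ABCDE")
        d = np.full((5, 5), 1.0)
        np.fill_diagonal(d, 0.0)
        tree = mh.nj_tree(DistanceMatrix(labels, d))
        tips = {t.name: t for t in tree.tips()}
        dists = {
            (a, b): tips[a].distance(tips[b])
            for i, a in enumerate(labels)
            for b in labels[i + 1 :]
        }
        assert all(v == pytest.approx(1.0, abs=1e-9) for v in dists.values())

    def test_invalid_matrix_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(("A", "B"), np.array([[0.0, 1.0], [2.0, 0.0]]))
        with pytest.raises(ValueError):
            DistanceMatrix(("A", "B"), np.array([[0.0, -1.0], [-1.0, 0.0]]))


def _tree_bipartitions(tree):
    all_tips = frozenset(t.name for t in tree.tips())
    splits = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        splits.add(frozenset({side, all_tips - side}))
    return splits


class TestClusterSeparation:
    def test_nj_separates_two_drifted_clusters(self):
        """Two Balding-Nichols clusters (within-cluster drift much smaller
        than between-cluster drift) should be split by an NJ bipartition in
        nearly every replicate."""
        n_loci, successes, reps = 50, 0, 20
        cluster_a = frozenset({"A1", "A2", "A3"})
        cluster_b = frozenset({"B1", "B2", "B3"})
        for rep in range(reps):
            pop_freqs = {p: {} for p in sorted(cluster_a | cluster_b)}
            for l in range(n_loci):
                anc = mh.sample_allele_freqs(
                    4, 1.0, seed=400_000 + rep * n_loci + l, locus_id=f"mh01sim{l + 1:03d}"
                )
                roots = mh.bn_population_freqs(anc, 0.3, 2, seed=500_000 + rep * n_loci + l)
                for root, cluster in zip(roots, (sorted(cluster_a), sorted(cluster_b))):
                    leaves = mh.bn_population_freqs(
                        root, 0.01, 3, seed=600_000 + rep * n_loci + l
                    )
                    for pop, fs in zip(cluster, leaves):
                        pop_freqs[pop][anc.locus_id] = fs
            tree = mh.nj_tree(mh.pairwise_fst(pop_freqs))
            if frozenset({cluster_a, cluster_b}) in _tree_bipartitions(tree):
                successes += 1
        assert successes >= 0.95 * reps
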