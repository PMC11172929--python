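import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from sweepscan.io import GenotypeMatrix, MISSING
from sweepscan.simulate import SimParams, simulate_balding_nichols
from sweepscan.structure import (ROHParams, _pairwise_r2_block,
                                 classify_roh_length, detect_roh, ibs_distance_matrix,
                                 ld_decay, ld_prune, ld_r2, nj_tree, pca,
                                 summarize_roh)

from conftest import random_matrix
from oracles import newick_tree_distances, random_additive_tree, tree_distance_matrix


def _single_sample_matrix(pos, geno_row):
    n = len(pos)
    return GenotypeMatrix(
        chrom=np.full(n, "1", dtype=object), pos=np.asarray(pos),
        ref=np.full(n, "A", dtype=object), alt=np.full(n, "T", dtype=object),
        geno=np.asarray(geno_row, dtype=np.int8).reshape(1, n),
        samples=["s1"], pop_of={"s1": "p"})


def _planted_roh_matrix(rng, tracts, L=12_000_000, spacing=2_000):
    pos = np.arange(0, L, spacing)
    geno = rng.integers(0, 3, size=pos.size).astype(np.int8)
    geno[rng.random(pos.size) < 0.5] = 1  # heterozygous background
    for lo, ln in tracts:
        m = (pos >= lo) & (pos < lo + ln)
        geno[m] = rng.choice([0, 2], size=m.sum()).astype(np.int8)
        # sharp truth boundaries: heterozygous SNPs flank every tract
        idx = np.flatnonzero(m)
        geno[max(idx[0] - 1, 0)] = 1
        geno[min(idx[-1] + 1, pos.size - 1)] = 1
    return _single_sample_matrix(pos, geno), pos


class TestROH:
    def test_planted_tract_classes(self, rng):
        tracts = [(500_000, 400_000), (2_000_000, 700_000),
                  (4_000_000, 1_500_000), (7_000_000, 2_500_000)]
        g, pos = _planted_roh_matrix(rng, tracts)
        segs = detect_roh(g, "s1")
        assert [s.size_class for s in segs] == ["0.5-1Mb", "1-2Mb", ">2Mb"]
        gap = 2_000
        for seg, (lo, ln) in zip(segs, tracts[1:]):
            assert abs(seg.start - lo) <= gap
            assert abs(seg.end - (lo + ln)) <= gap

    def test_all_heterozygous_sample_has_no_segments(self):
        pos = np.arange(0, 5_000_000, 2_000)
        g = _single_sample_matrix(pos, np.ones(pos.size))
        assert detect_roh(g, "s1") == []

    def test_short_tract_below_minimum_not_called(self, rng):
        g, _ = _planted_roh_matrix(rng, [(2_000_000, 400_000)])
        assert detect_roh(g, "s1") == []

    def test_size_classification(self):
        assert classify_roh_length(400_000) is None
        assert classify_roh_length(700_000) == "0.5-1Mb"
        assert classify_roh_length(1_500_000) == "1-2Mb"
        assert classify_roh_length(2_500_000) == ">2Mb"

    def test_summary_counts_and_total_length(self, rng):
        g, _ = _planted_roh_matrix(rng, [(2_000_000, 1_200_000)])
        segs = detect_roh(g, "s1")
        assert len(segs) == 1
        df = summarize_roh(segs)
        row = df.iloc[0]
        assert (row["0.5-1Mb"], row["1-2Mb"], row[">2Mb"]) == (0, 1, 0)
        assert row["total_bp"] == pytest.approx(1_200_000, rel=0.01)

    def test_empty_input_gives_empty_summary(self):
        assert summarize_roh([]).empty


class TestLD:
    def test_perfect_and_complement_pairs(self):
        x = [0, 1, 2, 0, 1, 2]
        assert ld_r2(x, x) == pytest.approx(1.0)
        assert ld_r2(x, [2 - v for v in x]) == pytest.approx(1.0)

    def test_hand_computed_pearson_squared(self):
        assert ld_r2([0, 1, 2, 0, 1, 2], [0, 0, 1, 1, 2, 2]) \
            == pytest.approx(0.25, abs=1e-12)

    def test_zero_variance_undefined(self):
        assert np.isnan(ld_r2([1, 1, 1, 1], [0, 1, 2, 0]))

    def test_block_r2_matches_pairwise(self, rng):
        g = random_matrix(rng, n_sites=12, missing_rate=0.15)
        block = _pairwise_r2_block(g.geno)
        for i in range(12):
            for j in range(i + 1, 12):
                expected = ld_r2(g.geno[:, i], g.geno[:, j])
                if np.isnan(expected):
                    assert np.isnan(block[i, j])
                else:
                    assert block[i, j] == pytest.approx(expected, abs=1e-10)

    def test_decay_curve_range_and_shuffle_control(self):
        p = SimParams(n_pops=1, samples_per_pop=20, n_snps=300,
                      fst_target=0.0, chrom_length=200_000, seed=11)
        g, _ = simulate_balding_nichols(p)
        curve = ld_decay(g, "pop0", max_dist=100_000, bin_width=10_000)
        vals = curve.mean_r2[np.isfinite(curve.mean_r2)]
        assert np.all((vals >= 0) & (vals <= 1))
        assert curve.pair_counts.sum() > 0

    def test_prune_drops_duplicate_column(self, rng):
        # enough samples that independent random sites stay below r2 = 0.2
        g = random_matrix(rng, n_samples_per_pop=100, n_pops=2, n_sites=10,
                          length=1_000, missing_rate=0.0)
        g.geno[:, 5] = g.geno[:, 4]  # adjacent perfect LD pair
        kept = ld_prune(g)
        assert 4 in kept and 5 not in kept
        assert len(kept) == 9

    def test_prune_postcondition_random_matrices(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            n_sites = int(rng.integers(60, 120))
            g = random_matrix(rng, n_samples_per_pop=50, n_pops=2,
                              n_sites=n_sites, length=10 * n_sites,
                              missing_rate=0.0)
            kept = ld_prune(g, window_snps=50, step_snps=10, r2_max=0.2)
            geno = g.geno[:, kept]
            for start in range(0, max(1, len(kept) - 49), 10):
                block = _pairwise_r2_block(geno[:, start:start + 50])
                iu = np.triu_indices_from(block, k=1)
                vals = block[iu]
                assert not np.any(vals[np.isfinite(vals)] > 0.2)

    def test_prune_deterministic(self, rng):
        g = random_matrix(rng, n_samples_per_pop=30, n_sites=80,
                          length=2_000, missing_rate=0.0)
        assert np.array_equal(ld_prune(g), ld_prune(g))


class TestPCA:
    def test_variance_percentages_ordered(self, rng):
        g = random_matrix(rng, n_samples_per_pop=15, n_sites=200,
                          length=100_000, missing_rate=0.05)
        res = pca(g)
        assert np.all(np.diff(res.pct_variance) <= 1e-9)
        assert res.pct_variance.sum() <= 100.0 + 1e-9
        assert np.all(res.pct_variance >= 0)

    def test_divergent_populations_separate_on_pc1(self):
        p = SimParams(n_pops=2, samples_per_pop=20, n_snps=5_000,
                      fst_target=0.3, chrom_length=10_000_000, seed=21)
        g, _ = simulate_balding_nichols(p)
        res = pca(g)
        pc1 = res.coords[:, 0]
        a, b = pc1[:20], pc1[20:]
        assert a.max() < b.min() or b.max() < a.min()

    def test_too_few_samples_rejected(self):
        g = _single_sample_matrix([10, 20], [1, 1])
        with pytest.raises(ValueError):
            pca(g)


class TestIBS:
    def test_identical_samples_distance_zero(self, rng):
        g = random_matrix(rng, n_sites=30, missing_rate=0.0)
        g.geno[1] = g.geno[0]
        d = ibs_distance_matrix(g)
        assert d.iloc[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_opposite_homozygotes_distance_one(self):
        g = GenotypeMatrix(
            chrom=np.full(4, "1", dtype=object), pos=np.arange(4) * 10,
            ref=np.full(4, "A", dtype=object),
            alt=np.full(4, "T", dtype=object),
            geno=np.array([[0, 0, 0, 0], [2, 2, 2, 2]], dtype=np.int8),
            samples=["a", "b"], pop_of={"a": "x", "b": "y"})
        d = ibs_distance_matrix(g)
        assert d.iloc[0, 1] == pytest.approx(1.0)

    def test_symmetric_zero_diagonal(self, rng):
        g = random_matrix(rng, n_sites=40, missing_rate=0.1)
        d = ibs_distance_matrix(g).to_numpy()
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0.0)


class TestNeighborJoining:
    def test_four_taxon_additive_example(self):
        # cherries (A:1, B:2) and (C:3, D:4) joined by an internal branch 2
        D = pd.DataFrame(
            [[0, 3, 6, 7], [3, 0, 7, 8], [6, 7, 0, 7], [7, 8, 7, 0]],
            index=list("ABCD"), columns=list("ABCD"), dtype=float)
        tree = nj_tree(D)
        dist = newick_tree_distances(tree)
        for pair, expected in [({"A", "B"}, 3), ({"C", "D"}, 7),
                               ({"A", "C"}, 6), ({"A", "D"}, 7),
                               ({"B", "C"}, 7), ({"B", "D"}, 8)]:
            assert dist[frozenset(pair)] == pytest.approx(expected,
                                                          abs=1e-9)

    def test_three_taxon_closed_form(self):
        D = pd.DataFrame([[0, 2, 4], [2, 0, 4], [4, 4, 0]],
                         index=list("ABC"), columns=list("ABC"),
                         dtype=float)
        tree = nj_tree(D)
        lengths = {ch.label: ln for ch, ln in tree.children}
        assert lengths == pytest.approx({"A": 1.0, "B": 1.0, "C": 3.0})

    def test_label_permutation_same_unrooted_topology(self, rng):
        import random
        r = random.Random(3)
        edges, leaves = random_additive_tree(6, r)
        dist = tree_distance_matrix(edges, leaves)
        D = pd.DataFrame(
            [[dist[(a, b)] for b in leaves] for a in leaves],
            index=leaves, columns=leaves)
        perm = list(leaves)
        r.shuffle(perm)
        t1 = nj_tree(D)
        t2 = nj_tree(D.loc[perm, perm])
        d1 = newick_tree_distances(t1)
        d2 = newick_tree_distances(t2)
        for pair in d1:
            assert d1[pair] == pytest.approx(d2[pair], abs=1e-9)

    def test_additive_matrices_reconstructed_exactly(self):
        import random
        r = random.Random(99)
        for _ in range(25):
            n = r.randint(4, 8)
            edges, leaves = random_additive_tree(n, r)
            dist = tree_distance_matrix(edges, leaves)
            D = pd.DataFrame(
                [[dist[(a, b)] for b in leaves] for a in leaves],
                index=leaves, columns=leaves)
            rec = newick_tree_distances(nj_tree(D))
            for i, a in enumerate(leaves):
                for b in leaves[i + 1:]:
                    assert rec[frozenset((a, b))] == pytest.approx(
                        dist[(a, b)], abs=1e-8)

    def test_matches_reference_implementation(self):
        skbio = pytest.importorskip("skbio")
        from skbio import DistanceMatrix

        rng = np.random.default_rng(5)
        g = random_matrix(rng, n_samples_per_pop=4, n_pops=2, n_sites=50,
                          missing_rate=0.0)
        d = ibs_distance_matrix(g)
        ours = newick_tree_distances(nj_tree(d))
        ref = skbio.tree.nj(DistanceMatrix(d.to_numpy(), ids=list(d.index)))
        for i, a in enumerate(d.index):
            for b in d.index[i + 1:]:
                assert ours[frozenset((a, b))] == pytest.approx(
                    ref.find(a).distance(ref.find(b)), abs=1e-6)

    def test_asymmetric_matrix_rejected(self):
        D = pd.DataFrame([[0, 1, 2], [1.5, 0, 2], [2, 2, 0]],
                         index=list("ABC"), columns=list("ABC"),
                         dtype=float)
        with pytest.raises(ValueError):
            nj_tree(D)


@settings(deadline=None, max_examples=15, derandomize=True)
@given(seed=st.integers(0, 1000))
def test_ld_prune_postcondition_property(seed):
    rng = np.random.default_rng(seed)
    g = random_matrix(rng, n_samples_per_pop=25, n_pops=2,
                      n_sites=int(rng.integers(20, 60)), length=5_000,
                      missing_rate=0.0)
    kept = ld_prune(g, window_snps=10, step_snps=3, r2_max=0.3)
    geno = g.geno[:, kept]
    for start in range(0, max(1, len(kept) - 9), 3):
        block = _pairwise_r2_block(geno[:, start:start + 10])
        iu = np.triu_indices_from(block, k=1)
        vals = block[iu]
        assert not np.any(vals[np.isfinite(vals)] > 0.3)
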