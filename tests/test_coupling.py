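import numpy as np
import pytest

from domevol import (
    Alignment,
    DomevolError,
    SequenceRecord,
    classify_edges,
    column_conservation,
    couple,
    cumulative_mi,
    mi_matrix,
    mi_zscores,
    sequence_weights,
)
from domevol.coupling import BACKGROUND, encode
from domevol.io import AMINO_ACIDS
from domevol.simulate import clock_tree, simulate_msa


def naive_mi(msa, i, j, weights, lam=0.05):
    """Independent loop-based MI oracle for one column pair (1-based)."""
    joint = np.full((20, 20), lam)
    for rec, w in zip(msa.records, weights):
        a = rec.residues[i - 1]
        b = rec.residues[j - 1]
        if a in AMINO_ACIDS and b in AMINO_ACIDS:
            joint[AMINO_ACIDS.index(a), AMINO_ACIDS.index(b)] += w
    p = joint / joint.sum()
    pi = p.sum(axis=1)
    pj = p.sum(axis=0)
    mi = 0.0
    for a in range(20):
        for b in range(20):
            if p[a, b] > 0:
                mi += p[a, b] * np.log(p[a, b] / (pi[a] * pj[b]))
    return mi


class TestSequenceWeights:
    def test_identical_rows_share_one_cluster(self):
        msa = Alignment([SequenceRecord(f"s{i}", "ACDEFGHIKL") for i in range(4)])
        w = sequence_weights(msa)
        assert np.allclose(w, 0.25)

    def test_two_constructed_clusters(self):
        # cluster 1: two identical rows; cluster 2: three rows at 90%
        # identity to each other but <62% to cluster 1
        base1 = "AAAAAAAAAA"
        base2 = "WWWWWWWWWC"
        msa = Alignment(
            [
                SequenceRecord("a1", base1),
                SequenceRecord("a2", base1),
                SequenceRecord("b1", base2),
                SequenceRecord("b2", "WWWWWWWWWD"),
                SequenceRecord("b3", "WWWWWWWWWE"),
            ]
        )
        w = sequence_weights(msa, identity_threshold=0.62)
        assert np.allclose(w, [0.5, 0.5, 1 / 3, 1 / 3, 1 / 3])
        assert w.sum() == pytest.approx(2.0)  # number of clusters

    def test_all_distinct_at_threshold_one(self, rng):
        from conftest import random_alignment

        msa = random_alignment(rng, n_rows=5, n_cols=30, gap_frac=0.0)
        w = sequence_weights(msa, identity_threshold=1.0)
        assert np.allclose(w, 1.0)


class TestMiMatrix:
    def test_copied_column_maximal(self):
        # 20 rows, column 1 runs the alphabet, column 2 copies it, column 3
        # is constant: MI(1,2) near ln 20, far above MI(1,3)
        rows = [
            SequenceRecord(f"s{i}", f"{aa}{aa}A")
            for i, aa in enumerate(AMINO_ACIDS)
        ]
        mi, cols = mi_matrix(Alignment(rows), weights=np.ones(20))
        # ln 20 ~ 3.0 before the heavy pseudocount shrinkage at n = 20
        assert mi[0, 1] > 0.5
        assert abs(mi[0, 2]) < 1e-9
        assert mi[0, 1] > 1000 * abs(mi[0, 2])

    def test_matches_naive_oracle(self, rng):
        from conftest import random_alignment

        msa = random_alignment(rng, n_rows=8, n_cols=6, gap_frac=0.1)
        w = sequence_weights(msa)
        mi, cols = mi_matrix(msa, weights=w)
        for ii in range(len(cols)):
            for jj in range(ii + 1, len(cols)):
                expect = naive_mi(msa, cols[ii], cols[jj], w)
                assert mi[ii, jj] == pytest.approx(expect, abs=1e-10)

    def test_independent_columns_low_mi(self):
        # independent columns carry no true MI: the raw plug-in estimate sits
        # at its finite-sample bias (~(19*19)/(2n) nats), and subtracting a
        # within-column permutation null leaves < 0.05 nats
        letters = np.array(list(AMINO_ACIDS))
        w = np.ones(500)
        diffs = []
        for seed in range(50):
            r = np.random.default_rng(seed)
            rows = [
                SequenceRecord(f"s{k}", "".join(letters[r.integers(0, 20, 2)]))
                for k in range(500)
            ]
            msa = Alignment(rows)
            mi, _ = mi_matrix(msa, weights=w)
            null = []
            for _ in range(5):
                perm_rows = [
                    SequenceRecord(f"p{k}", rows[k].residues[0] + rows[j].residues[1])
                    for k, j in enumerate(r.permutation(500))
                ]
                null.append(mi_matrix(Alignment(perm_rows), weights=w)[0][0, 1])
            diffs.append(mi[0, 1] - np.mean(null))
        diffs = np.asarray(diffs)
        assert abs(diffs.mean()) < 0.01  # no systematic coupling signal
        assert np.abs(diffs).max() < 0.15  # and no single-seed outlier

    def test_symmetric_and_nonnegative(self, rng):
        from conftest import random_alignment

        msa = random_alignment(rng, n_rows=10, n_cols=15, gap_frac=0.1)
        mi, _ = mi_matrix(msa)
        assert np.allclose(mi, mi.T)
        assert mi.min() >= -1e-9

    def test_occupancy_filter(self):
        msa = Alignment(
            [
                SequenceRecord("a", "AC-"),
                SequenceRecord("b", "AD-"),
                SequenceRecord("c", "AE-"),
                SequenceRecord("d", "AFW"),
            ]
        )
        _, cols = mi_matrix(msa, weights=np.ones(4))
        assert list(cols) == [1, 2]  # column 3 is 25% occupied


class TestZScores:
    def test_planted_pair_detected(self):
        tree = clock_tree(40, 1.0, seed=21)
        for seed in range(3):
            sim = simulate_msa(
                tree, 60, rate=1.0, seed=seed, covarying_pairs=[(5, 40)]
            )
            z, mi, cols = mi_zscores(sim.alignment, n_permutations=30, seed=seed)
            cols = list(cols)
            assert z[cols.index(5), cols.index(40)] > 6.5

    def test_deterministic_under_seed(self, rng):
        from conftest import random_alignment

        msa = random_alignment(rng, n_rows=12, n_cols=10, gap_frac=0.05)
        z1, _, _ = mi_zscores(msa, n_permutations=25, seed=9)
        z2, _, _ = mi_zscores(msa, n_permutations=25, seed=9)
        assert np.array_equal(z1, z2)

    def test_constant_alignment_zero_sd_flagged_as_zero(self):
        msa = Alignment([SequenceRecord(f"s{i}", "AAAA") for i in range(6)])
        z, _, _ = mi_zscores(msa, n_permutations=20, seed=1)
        assert np.all(z == 0.0)

    def test_too_few_permutations_rejected(self, toy_msa):
        with pytest.raises(DomevolError, match="at least 20"):
            mi_zscores(toy_msa, n_permutations=5, seed=0)


class TestEdgesAndCmi:
    def test_no_edges_above_threshold(self):
        z = np.zeros((4, 4))
        assert np.all(cumulative_mi(z) == 0.0)
        assert len(classify_edges(z)) == 0

    def test_single_qualifying_pair(self):
        z = np.zeros((5, 5))
        z[1, 3] = z[3, 1] = 8.0
        cmi = cumulative_mi(z)
        assert cmi[1] == cmi[3] == 8.0
        assert np.all(np.delete(cmi, [1, 3]) == 0.0)
        edges = classify_edges(z)
        assert len(edges) == 1
        assert edges.iloc[0]["tier"] == "top5"

    def test_hundred_edges_tier_counts(self):
        # 15 columns -> 105 pairs; plant exactly 100 above threshold
        n = 15
        z = np.zeros((n, n))
        iu = list(zip(*np.triu_indices(n, k=1)))
        for rank, (i, j) in enumerate(iu[:100]):
            z[i, j] = z[j, i] = 106.5 - rank  # distinct, all above threshold
        edges = classify_edges(z, threshold=6.5)
        assert len(edges) == 100
        counts = edges["tier"].value_counts()
        assert counts["top5"] == 5 and counts["mid"] == 25 and counts["rest"] == 70


class TestColumnConservation:
    def test_uniform_column_uniform_background_zero(self):
        msa = Alignment(
            [SequenceRecord(f"s{i}", aa) for i, aa in enumerate(AMINO_ACIDS)]
        )
        uniform = {aa: 0.05 for aa in AMINO_ACIDS}
        kl, _ = column_conservation(
            msa, background=uniform, weights=np.ones(20), pseudocount=0.0
        )
        assert kl[0] == pytest.approx(0.0, abs=1e-12)

    def test_invariant_rare_residue_is_maximal(self):
        # invariant columns of W (rare, q~0.013), L (common) and A: the W
        # column diverges most from background
        rows = [SequenceRecord(f"s{i}", "WLA") for i in range(10)]
        kl, _ = column_conservation(Alignment(rows), weights=np.ones(10))
        assert kl[0] == max(kl)
        # scale check: KL of invariant W ~ -ln q_W plus pseudocount shrinkage
        assert kl[0] == pytest.approx(-np.log(BACKGROUND["W"]), rel=0.25)

    def test_bad_background_rejected(self, toy_msa):
        with pytest.raises(DomevolError, match="sum to 1"):
            column_conservation(toy_msa, background={aa: 1.0 for aa in AMINO_ACIDS})


class TestCouple:
    def test_end_to_end_result_shape(self):
        tree = clock_tree(25, 0.8, seed=4)
        sim = simulate_msa(tree, 40, rate=0.8, seed=2, covarying_pairs=[(3, 30)])
        res = couple(sim.alignment, n_permutations=25, seed=11)
        n = len(res.columns)
        assert res.mi.shape == res.z.shape == (n, n)
        assert res.cmi.shape == res.conservation.shape == (n,)
        assert {"i", "j", "z", "tier"} <= set(res.edges.columns)
        tab = res.per_column_table()
        assert list(tab.columns) == ["column", "conservation", "cmi"]
        # the planted pair must surface as an edge
        pairs = {(int(r.i), int(r.j)) for r in res.edges.itertuples()}
        assert (3, 30) in pairs

    def test_raw_threshold_mode(self):
        rows = [SequenceRecord(f"s{i}", f"{aa}{aa}AC") for i, aa in enumerate(AMINO_ACIDS)]
        res = couple(
            Alignment(rows), n_permutations=20, seed=5, threshold=0.5, threshold_on="raw"
        )
        pairs = {(int(r.i), int(r.j)) for r in res.edges.itertuples()}
        assert (1, 2) in pairs
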