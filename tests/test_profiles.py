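"""Presence/absence profiling, hierarchical clustering vs scipy, bootstrap
supports, composition-vector components vs an exhaustive k-mer oracle, and
distance trees."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import linkage as scipy_linkage
from scipy.spatial.distance import squareform

from rhizocomp.genome_io import HomologyHit, hits_from_rows
from rhizocomp.profiles import (
    PresenceAbsenceMatrix,
    ProfileThresholds,
    bootstrap_support,
    composition_vector,
    composition_vector_distance,
    distance_tree,
    hcluster,
    presence_matrix,
    profile_distance,
)


def hit(q, ev=1e-6, ident=40.0):
    return HomologyHit(q, f"s_{q}", ident, 100, ev, 300.0, 90.0)


class TestPresenceMatrix:
    def test_threshold_semantics(self):
        hits = {
            "G1": [hit("m1", ev=1e-6, ident=40.0)],   # passes both
            "G2": [hit("m1", ev=1e-6, ident=20.0)],   # identity below floor
            "G3": [hit("m1", ev=1e-4, ident=40.0)],   # evalue too large
        }
        pam = presence_matrix(["m1"], hits)
        assert pam.data.loc["m1"].tolist() == [True, False, False]

    def test_evalue_boundary_inclusive(self):
        pam = presence_matrix(["m1"], {"G1": [hit("m1", ev=1e-5)]})
        assert pam.data.loc["m1", "G1"]

    def test_identity_ceiling_variant(self):
        thr = ProfileThresholds(identity_is_floor=False)
        pam = presence_matrix(["m1"], {"G1": [hit("m1", ident=20.0)]}, thr)
        assert pam.data.loc["m1", "G1"]

    def test_reference_genome_all_present(self):
        pam = presence_matrix(["m1", "m2"], {"G1": []}, reference_genome="G0")
        assert pam.data["G0"].all()
        assert not pam.data["G1"].any()

    def test_lossless_simulation_gives_all_ones(self):
        from rhizocomp.simulate import SimConfig, simulate_cohort
        from rhizocomp.orthology import build_groups, sample_marker_genes, single_copy_core
        from tests.conftest import cohort_rbh_pairs

        cfg = SimConfig(n_genomes=4, genes_per_genome=60, island_spec=None,
                        seed=14, with_sequences=False)
        annots, hit_tables, truth = simulate_cohort(cfg)
        scc = single_copy_core(build_groups(cohort_rbh_pairs(hit_tables, truth)), annots)
        markers = sample_marker_genes(scc, 30, seed=1, reference_genome="G0")
        hits_by_genome = {
            f"G{i}": hits_from_rows(hit_tables[("G0", f"G{i}")], truth.gene_lengths)
            for i in range(1, 4)
        }
        pam = presence_matrix(markers, hits_by_genome, reference_genome="G0")
        assert pam.data.to_numpy().all()


class TestProfileDistance:
    def test_identical_and_complementary_columns(self):
        df = pd.DataFrame(
            {"A": [1, 0, 1, 0], "B": [1, 0, 1, 0], "C": [0, 1, 0, 1]}, dtype=bool
        )
        d = profile_distance(PresenceAbsenceMatrix(df))
        assert d.loc["A", "B"] == 0.0
        assert d.loc["A", "C"] == 1.0
        assert np.allclose(d, d.T) and np.allclose(np.diag(d), 0.0)

    def test_matches_double_loop_recomputation(self):
        rng = np.random.default_rng(2)
        for metric in ("hamming", "jaccard"):
            df = pd.DataFrame(
                rng.integers(0, 2, size=(20, 8)).astype(bool),
                columns=[f"g{i}" for i in range(8)],
            )
            d = profile_distance(PresenceAbsenceMatrix(df), metric)
            for a, b in itertools.combinations(df.columns, 2):
                x, y = df[a].to_numpy(), df[b].to_numpy()
                if metric == "hamming":
                    exp = sum(int(u != v) for u, v in zip(x, y)) / len(x)
                else:
                    inter = sum(int(u and v) for u, v in zip(x, y))
                    union = sum(int(u or v) for u, v in zip(x, y))
                    exp = 1 - inter / union if union else 0.0
                assert d.loc[a, b] == pytest.approx(exp)


class TestHcluster:
    def test_two_items_single_merge(self):
        d = pd.DataFrame([[0, 0.4], [0.4, 0]], index=["A", "B"], columns=["A", "B"])
        dend = hcluster(d)
        assert dend.root.height == 0.4
        assert dend.root.leaves == ("A", "B")

    def test_forced_topology(self):
        d = pd.DataFrame(
            [[0, 0.1, 0.8], [0.1, 0, 0.8], [0.8, 0.8, 0]],
            index=list("ABC"), columns=list("ABC"),
        )
        dend = hcluster(d)
        (inner,) = [n for n in dend.internal_nodes() if n is not dend.root]
        assert inner.leaves == ("A", "B")

    def test_average_linkage_matches_scipy_upgma(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            n = 6
            m = rng.uniform(0.1, 1.0, size=(n, n))
            m = (m + m.T) / 2
            np.fill_diagonal(m, 0.0)
            labels = [f"t{i}" for i in range(n)]
            d = pd.DataFrame(m, index=labels, columns=labels)
            dend = hcluster(d, "average")
            z = scipy_linkage(squareform(m, checks=False), method="average")
            # compare clade sets and merge heights
            heights = sorted(nd.height for nd in dend.internal_nodes())
            assert heights == pytest.approx(sorted(z[:, 2]))
            clades = {frozenset(nd.leaves) for nd in dend.internal_nodes()}
            sets = {i: {labels[i]} for i in range(n)}
            for step, (i, j, h, _) in enumerate(z):
                merged = sets[int(i)] | sets[int(j)]
                sets[n + step] = merged
                assert frozenset(merged) in clades

    def test_order_invariance(self):
        rng = np.random.default_rng(9)
        n = 5
        m = rng.uniform(0.1, 1.0, size=(n, n))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0.0)
        labels = [f"t{i}" for i in range(n)]
        d = pd.DataFrame(m, index=labels, columns=labels)
        perm = [3, 1, 4, 0, 2]
        d2 = d.iloc[perm, perm]
        assert hcluster(d).to_newick() == hcluster(d2).to_newick()


class TestBootstrap:
    def _matrix(self):
        rng = np.random.default_rng(12)
        # A/B identical, everything else far away
        base = rng.integers(0, 2, size=(40, 1)).astype(bool)
        df = pd.DataFrame(
            {
                "A": base[:, 0],
                "B": base[:, 0],
                "C": ~base[:, 0],
                "D": rng.integers(0, 2, size=40).astype(bool),
            }
        )
        return PresenceAbsenceMatrix(df)

    def test_identical_profiles_get_full_support(self):
        dend = bootstrap_support(self._matrix(), n_reps=200, seed=3)
        assert dend.clade_support(["A", "B"]) == 100.0

    def test_same_seed_same_supports(self):
        a = bootstrap_support(self._matrix(), n_reps=100, seed=5)
        b = bootstrap_support(self._matrix(), n_reps=100, seed=5)
        assert a.to_newick() == b.to_newick()

    def test_row_order_invariance(self):
        pam = self._matrix()
        shuffled = PresenceAbsenceMatrix(pam.data.iloc[::-1])
        a = bootstrap_support(pam, n_reps=100, seed=7)
        b = bootstrap_support(shuffled, n_reps=100, seed=7)
        assert a.to_newick() == b.to_newick()


def brute_cv_components(seq, k):
    """Dictionary-based tally of the Markov-subtracted k-string components."""
    from itertools import product

    rc = seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]

    def counts(length):
        c = {}
        for s in (seq, rc):
            for i in range(len(s) - length + 1):
                c[s[i : i + length]] = c.get(s[i : i + length], 0) + 1
        tot = sum(c.values())
        return c, tot

    ck, nk = counts(k)
    c1, n1 = counts(k - 1)
    c2, n2 = counts(k - 2)
    comp = {}
    for mer in ("".join(p) for p in product("ACGT", repeat=k)):
        f = ck.get(mer, 0) / nk
        fpre = c1.get(mer[:-1], 0) / n1
        fsuf = c1.get(mer[1:], 0) / n1
        fmid = c2.get(mer[1:-1], 0) / n2
        f0 = fpre * fsuf / fmid if fmid > 0 else 0.0
        comp[mer] = (f - f0) / f0 if f0 > 0 else 0.0
    return comp


class TestCompositionVector:
    TOY = "ATGATGATGCCCATGATGATGCCC"

    def test_identical_sequences_distance_zero(self):
        assert composition_vector_distance(self.TOY, self.TOY, k=3) == 0.0

    def test_symmetry(self):
        rng = np.random.default_rng(4)
        a = "".join(rng.choice(list("ACGT"), 300))
        b = "".join(rng.choice(list("ACGT"), 300))
        assert composition_vector_distance(a, b) == composition_vector_distance(b, a)

    def test_toy_components_match_exhaustive_oracle(self):
        got = composition_vector(self.TOY, k=3)
        exp = brute_cv_components(self.TOY, 3)
        from itertools import product

        for idx, mer in enumerate("".join(p) for p in product("ACGT", repeat=3)):
            assert got[idx] == pytest.approx(exp[mer], abs=1e-12), mer

    def test_rotation_near_invariance(self):
        rng = np.random.default_rng(6)
        seq = "".join(rng.choice(list("ACGT"), 3000))
        rot = seq[1000:] + seq[:1000]
        assert composition_vector_distance(seq, rot, k=5) < 0.01

    def test_short_sequence_rejected(self):
        with pytest.raises(ValueError):
            composition_vector("ACG", k=6)


class TestDistanceTree:
    def test_nj_three_taxa_closed_form(self):
        d = pd.DataFrame(
            [[0, 5, 9], [5, 0, 10], [9, 10, 0]], index=list("ABC"), columns=list("ABC")
        )
        nwk = distance_tree(d, "nj")
        from skbio import TreeNode
        import io

        tree = TreeNode.read(io.StringIO(nwk))
        # three-point formulas: a = (dAB + dAC - dBC)/2 etc.
        tips = {t.name: t.length for t in tree.tips()}
        lengths = sorted(tips.values())
        assert lengths == pytest.approx(sorted([2.0, 3.0, 7.0]))

    def test_nj_recovers_additive_four_taxon_topology(self):
        # tree ((A:1,B:2):3,(C:4,D:5)) -> additive distances
        d = pd.DataFrame(
            [
                [0, 3, 8, 9],
                [3, 0, 9, 10],
                [8, 9, 0, 9],
                [9, 10, 9, 0],
            ],
            index=list("ABCD"), columns=list("ABCD"),
        )
        nwk = distance_tree(d, "nj")
        from skbio import TreeNode
        import io

        tree = TreeNode.read(io.StringIO(nwk))
        for x, y in itertools.combinations("ABCD", 2):
            assert tree.find(x).distance(tree.find(y)) == pytest.approx(d.loc[x, y])

    def test_upgma_reproduces_ultrametric_heights(self):
        d = pd.DataFrame(
            [[0, 2, 8, 8], [2, 0, 8, 8], [8, 8, 0, 4], [8, 8, 4, 0]],
            index=list("ABCD"), columns=list("ABCD"),
        )
        nwk = distance_tree(d, "upgma")
        from skbio import TreeNode
        import io

        tree = TreeNode.read(io.StringIO(nwk))
        assert tree.find("A").distance(tree.find("B")) == pytest.approx(2)
        assert tree.find("C").distance(tree.find("D")) == pytest.approx(4)
        assert tree.find("A").distance(tree.find("C")) == pytest.approx(8)

    def test_asymmetric_matrix_rejected(self):
        d = pd.DataFrame([[0, 1], [2, 0]], index=["A", "B"], columns=["A", "B"])
        with pytest.raises(ValueError):
            distance_tree(d)
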