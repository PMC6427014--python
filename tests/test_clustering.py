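import io as _io

import numpy as np
import pytest
from Bio import Phylo

from bacaba import clustering
from bacaba.datasets import REFERENCE_TOCHER_GROUPS
from bacaba.datatypes import DistanceMatrix, ValidityError


def _dm(d, labels=None):
    d = np.asarray(d, dtype=float)
    labels = labels or tuple(chr(ord("A") + i) for i in range(d.shape[0]))
    return DistanceMatrix(tuple(labels), d)


def _random_dm(rng, n):
    x = rng.normal(0, 1, size=(n, 3))
    d = ((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=2)
    np.fill_diagonal(d, 0.0)
    return _dm(d, tuple(str(i + 1) for i in range(n)))


class TestTocher:
    def test_reference_partition(self, ref_d2):
        g = clustering.tocher(ref_d2)
        assert sorted(g.partition(), key=len) == sorted(
            [set(x) for x in REFERENCE_TOCHER_GROUPS], key=len
        )
        assert g.theta == pytest.approx(13.32)

    def test_equal_distances_single_group(self):
        d = np.ones((5, 5)) - np.eye(5)
        g = clustering.tocher(_dm(d))
        assert len(g.groups) == 1 and len(g.groups[0]) == 5

    def test_two_separated_pairs(self):
        # points at 0, 1 and 100, 101 on a line (squared distances)
        pts = np.array([0.0, 1.0, 100.0, 101.0])
        d = (pts[:, None] - pts[None, :]) ** 2
        g = clustering.tocher(_dm(d, ("a", "b", "c", "d")))
        assert sorted(g.partition(), key=sorted) == [{"a", "b"}, {"c", "d"}]

    def test_groups_partition_labels(self, rng):
        for n in (4, 7, 12):
            for _ in range(15):
                D = _random_dm(rng, n)
                g = clustering.tocher(D)
                members = [m for grp in g.groups for m in grp]
                assert sorted(members) == sorted(D.labels)


class TestUpgma:
    def test_three_leaf_hand_calculation(self):
        D = _dm([[0, 1, 4], [1, 0, 4], [4, 4, 0]], ("1", "2", "3"))
        tree = clustering.upgma(D)
        assert tree.merges[0][:3] == (0, 1, 1.0)
        assert tree.merges[1][2] == pytest.approx(4.0)

    def test_matches_hand_coded_reference(self, rng):
        # independent O(n^3) average-linkage agglomeration
        def reference_upgma(d):
            n = d.shape[0]
            clusters = {i: [i] for i in range(n)}
            nxt = n
            merges = []
            while len(clusters) > 1:
                best = None
                ids = sorted(clusters)
                for ai, a in enumerate(ids):
                    for b in ids[ai + 1 :]:
                        avg = np.mean(
                            [d[x, y] for x in clusters[a] for y in clusters[b]]
                        )
                        if best is None or avg < best[2]:
                            best = (a, b, avg)
                a, b, h = best
                clusters[nxt] = clusters.pop(a) + clusters.pop(b)
                merges.append((a, b, h, nxt))
                nxt += 1
            return merges

        for n in (4, 6):
            D = _random_dm(rng, n)
            got = clustering.upgma(D).merges
            want = reference_upgma(D.d)
            for (a, b, h, new), (a2, b2, h2, new2) in zip(got, want):
                assert {a, b} == {a2, b2} and new == new2
                assert h == pytest.approx(h2, abs=1e-12)

    def test_reference_first_merge_is_least_divergent_pair(self, ref_d2):
        tree = clustering.upgma(ref_d2)
        a, b, h, _ = tree.merges[0]
        assert {tree.labels[a], tree.labels[b]} == {"3", "15"}
        assert h == pytest.approx(0.07)

    def test_fusion_levels_monotone(self, rng):
        for _ in range(10):
            tree = clustering.upgma(_random_dm(rng, 8))
            lev = tree.fusion_levels
            assert np.all(np.diff(lev) >= -1e-12)


class TestCopheneticCorrelation:
    def test_ultrametric_input_is_exactly_represented(self):
        D = _dm([[0, 1, 4], [1, 0, 4], [4, 4, 0]], ("1", "2", "3"))
        tree = clustering.upgma(D)
        assert clustering.cophenetic_correlation(D, tree) == pytest.approx(1.0)

    def test_reference_matrix_value(self, ref_d2):
        # frozen honest recomputation from the printed distances
        tree = clustering.upgma(ref_d2)
        assert clustering.cophenetic_correlation(ref_d2, tree) == pytest.approx(
            0.7610, abs=5e-4
        )

    def test_matches_double_loop_oracle(self, rng):
        D = _random_dm(rng, 6)
        tree = clustering.upgma(D)
        # cophenetic distance via explicit lowest-common-merge search
        n = 6
        member = {i: {i} for i in range(n)}
        coph = np.zeros((n, n))
        for a, b, h, new in tree.merges:
            for x in member[a]:
                for y in member[b]:
                    coph[x, y] = coph[y, x] = h
            member[new] = member[a] | member[b]
        iu = np.triu_indices(n, 1)
        expect = np.corrcoef(coph[iu], D.d[iu])[0, 1]
        assert clustering.cophenetic_correlation(D, tree) == pytest.approx(
            expect, abs=1e-12
        )


class TestMojenaCut:
    def test_huge_constant_single_cluster(self, ref_d2):
        tree = clustering.upgma(ref_d2)
        groups = clustering.mojena_cut(tree, k=1e9)
        assert len(set(groups.values())) == 1

    def test_two_tight_clusters(self):
        pts = np.array([0.0, 0.5, 1.0, 50.0, 50.5, 51.0])
        d = (pts[:, None] - pts[None, :]) ** 2
        tree = clustering.upgma(_dm(d, tuple("abcdef")))
        groups = clustering.mojena_cut(tree, k=1.25)
        assert len(set(groups.values())) == 2

    def test_reference_cut_matches_tocher_partition(self, ref_d2):
        tree = clustering.upgma(ref_d2)
        groups = clustering.mojena_cut(tree, k=1.25)
        parts = {}
        for label, c in groups.items():
            parts.setdefault(c, set()).add(label)
        assert sorted(parts.values(), key=len) == sorted(
            [set(x) for x in REFERENCE_TOCHER_GROUPS], key=len
        )

    def test_negative_constant_rejected(self, ref_d2):
        tree = clustering.upgma(ref_d2)
        with pytest.raises(ValidityError):
            clustering.mojena_cut(tree, k=-1.0)


class TestProjectionFit:
    def test_identity_representation(self, ref_d2):
        fit = clustering.projection_fit(ref_d2, ref_d2)
        assert fit.stress_pct == 0.0 and fit.distortion_pct == 0.0

    def test_halved_distances_closed_form(self, ref_d2):
        halved = DistanceMatrix(ref_d2.labels, ref_d2.d / 2.0)
        fit = clustering.projection_fit(ref_d2, halved)
        assert fit.stress_pct == pytest.approx(50.0)
        assert fit.distortion_pct == pytest.approx(75.0)

    def test_all_zero_original_rejected(self):
        z = DistanceMatrix(("a", "b"), np.zeros((2, 2)))
        with pytest.raises(ValidityError):
            clustering.projection_fit(z, z)


class TestNewick:
    def test_two_leaf_tree(self):
        tree = clustering.Dendrogram(("A", "B"), ((0, 1, 1.0, 2),))
        assert clustering.to_newick(tree) == "(A:0.5,B:0.5);"

    def test_round_trip_preserves_topology(self, ref_d2):
        tree = clustering.upgma(ref_d2)
        parsed = Phylo.read(_io.StringIO(clustering.to_newick(tree)), "newick")
        assert sorted(t.name for t in parsed.get_terminals()) == sorted(ref_d2.labels)
        # shallowest cherry is the least divergent published pair (3, 15)
        mrca = parsed.common_ancestor(["3", "15"])
        assert {t.name for t in mrca.get_terminals()} == {"3", "15"}
        assert parsed.distance("3", "15") == pytest.approx(0.07, abs=1e-9)
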