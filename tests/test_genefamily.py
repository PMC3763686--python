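import numpy as np
import pytest

from legsyn.genefamily import (
    DistanceMatrix,
    ExonIntronProfile,
    bootstrap_support,
    compare_exon_intron,
    nj_tree,
    pairwise_distances,
)
from legsyn.io_formats import GeneModel, SequenceRecord

from conftest import random_dna
from oracles import nj_oracle


def recs(*seqs):
    return [SequenceRecord(f"s{i}", "", s) for i, s in enumerate(seqs)]


class TestDistances:
    def test_identical_sequences_zero(self):
        dm = pairwise_distances(recs("ACGT", "ACGT", "ACGT"))
        assert (dm.d == 0).all()

    def test_quarter_distance(self):
        dm = pairwise_distances(recs("ACGT", "ACGA"))
        assert dm.d[0, 1] == 0.25

    def test_gap_columns_skipped_pairwise(self):
        dm = pairwise_distances(recs("AC-T", "ACGT"))
        assert dm.d[0, 1] == 0.0

    def test_n_columns_skipped(self):
        dm = pairwise_distances(recs("ACNT", "ACGA"))
        assert dm.d[0, 1] == pytest.approx(1 / 3)

    def test_no_comparable_columns_rejected(self):
        with pytest.raises(ValueError, match="comparable"):
            pairwise_distances(recs("--AC", "AC--"))

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            pairwise_distances(recs("ACGT", "ACG"))


class TestNJ:
    def test_three_taxon_closed_form(self):
        dm = DistanceMatrix(
            ["A", "B", "C"],
            np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float),
        )
        tree = nj_tree(dm)
        lengths = {n.name: n.length for n in tree.root.children}
        assert lengths == {"A": 1.0, "B": 1.0, "C": 3.0}

    def test_four_leaf_additive_recovered_exactly(self):
        # distances from the unrooted tree with leaf edges 1 and the
        # internal AB|CD edge 1: d(A,B)=d(C,D)=2, cross-pairs 3
        d = np.array(
            [[0, 2, 3, 3], [2, 0, 3, 3], [3, 3, 0, 2], [3, 3, 2, 0]], float
        )
        tree = nj_tree(DistanceMatrix(list("ABCD"), d))
        assert tree.bipartitions() == {frozenset({"C", "D"})}
        assert tree.total_length() == pytest.approx(5.0)

    def test_additive_matrices_reproduced(self):
        """Path lengths on the NJ tree equal the input distances whenever the
        matrix is additive (random trees, up to 8 leaves)."""
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = int(rng.integers(4, 9))
            labels = [f"t{i}" for i in range(n)]
            d = _random_additive_matrix(rng, n)
            tree = nj_tree(DistanceMatrix(labels, d))
            got = _path_distances(tree)
            for i in range(n):
                for j in range(i + 1, n):
                    assert got[frozenset((f"t{i}", f"t{j}"))] == pytest.approx(
                        d[i, j], abs=1e-9
                    )

    def test_matches_naive_nj_oracle(self):
        """Same topology and total length as an independent brute-force NJ on
        random matrices, up to 7 taxa."""
        rng = np.random.default_rng(11)
        for _ in range(25):
            n = int(rng.integers(4, 8))
            labels = [f"t{i}" for i in range(n)]
            m = rng.random((n, n)) + 0.1
            m = (m + m.T) / 2
            np.fill_diagonal(m, 0)
            tree = nj_tree(DistanceMatrix(labels, m))
            want_splits, want_total = nj_oracle(labels, m)
            assert tree.bipartitions() == want_splits
            assert tree.total_length() == pytest.approx(want_total)

    def test_matches_skbio_topology(self):
        from skbio import DistanceMatrix as SkDM
        from skbio.tree import nj as sk_nj

        rng = np.random.default_rng(2)
        for _ in range(5):
            n = 7
            labels = [f"t{i}" for i in range(n)]
            m = rng.random((n, n)) + 0.2
            m = (m + m.T) / 2
            np.fill_diagonal(m, 0)
            mine = nj_tree(DistanceMatrix(labels, m)).bipartitions()
            sk = sk_nj(SkDM(m, labels))
            ref = sorted(labels)[0]
            theirs = set()
            for node in sk.non_tips():
                side = frozenset(x.name for x in node.tips())
                if ref in side:
                    side = frozenset(set(labels) - side)
                if 2 <= len(side) <= n - 2:
                    theirs.add(side)
            assert mine == theirs

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(["A", "B"], np.zeros((2, 2))))

    def test_all_equal_distances_deterministic(self):
        d = np.ones((5, 5)) - np.eye(5)
        t1 = nj_tree(DistanceMatrix(list("ABCDE"), d))
        t2 = nj_tree(DistanceMatrix(list("ABCDE"), d))
        assert t1.to_newick() == t2.to_newick()


def _random_additive_matrix(rng, n):
    """Distances from a random binary tree with positive branch lengths:
    merge random subtrees, accumulating leaf-to-join distances."""
    nodes = [{i: 0.0} for i in range(n)]
    d = np.zeros((n, n))
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        dj = nodes.pop(j)
        di = nodes.pop(i)
        li, lj = rng.uniform(0.1, 2.0, size=2)
        for a, da in di.items():
            for b, db in dj.items():
                d[a, b] = d[b, a] = da + li + db + lj
        merged = {a: da + li for a, da in di.items()}
        merged.update({b: db + lj for b, db in dj.items()})
        nodes.append(merged)
    return d


def _path_distances(tree):
    """Leaf-to-leaf path lengths via pairwise combination at each internal
    node of the rooted representation."""
    out = {}

    def collect(node):
        if node.is_leaf:
            return [(node.name, 0.0)]
        subs = []
        for child in node.children:
            sub = [
                (name, dist + (child.length or 0.0))
                for name, dist in collect(child)
            ]
            subs.append(sub)
        for x in range(len(subs)):
            for y in range(x + 1, len(subs)):
                for na, da in subs[x]:
                    for nb, db in subs[y]:
                        out[frozenset((na, nb))] = da + db
        return [pair for sub in subs for pair in sub]

    collect(tree.root)
    return out


class TestBootstrap:
    def _clustered(self, rng, n_diag=25):
        base = random_dna(rng, 120)
        g1 = base[:40] + "A" * n_diag + base[40 + n_diag:]
        g2 = base[:40] + "C" * n_diag + base[40 + n_diag:]

        def noisy(s):
            s = list(s)
            for i in rng.integers(0, len(s), 3):
                s[i] = "ACGT"[rng.integers(0, 4)]
            return "".join(s)

        return [SequenceRecord(f"x{i}", "", noisy(g1)) for i in range(4)] + [
            SequenceRecord(f"y{i}", "", noisy(g2)) for i in range(4)
        ]

    def test_diagnostic_split_strongly_supported(self, rng):
        aligned = self._clustered(rng)
        tree = bootstrap_support(aligned, reps=100, seed=3)
        supports = {}
        names = sorted(tree.leaf_names)
        ref, all_names = names[0], frozenset(names)
        for node in tree.root.walk():
            if node.is_leaf or node is tree.root or node.support is None:
                continue
            side = frozenset(x.name for x in node.walk() if x.is_leaf)
            if ref in side:
                side = all_names - side
            supports[side] = node.support
        split = frozenset({"y0", "y1", "y2", "y3"})
        assert supports[split] >= 95

    def test_single_replicate_supports_binary(self, rng):
        aligned = self._clustered(rng)
        tree = bootstrap_support(aligned, reps=1, seed=0)
        vals = {
            n.support
            for n in tree.root.walk()
            if n.support is not None and not n.is_leaf
        }
        assert vals <= {0, 100}

    def test_same_seed_reproducible(self, rng):
        aligned = self._clustered(rng)
        t1 = bootstrap_support(aligned, reps=50, seed=9)
        t2 = bootstrap_support(aligned, reps=50, seed=9)
        assert t1.to_newick() == t2.to_newick()

    def test_supports_invariant_under_relabeling(self, rng):
        """Relabeling leaves permutes bipartitions without changing the
        support of the well-resolved split (exact equivariance is limited to
        splits where the label tie-break never binds, so the strongly
        diagnostic split is the meaningful check)."""
        aligned = self._clustered(rng, n_diag=30)
        relabel = {r.id: f"z{i}" for i, r in enumerate(reversed(aligned))}
        renamed = [
            SequenceRecord(relabel[r.id], "", r.residues) for r in aligned
        ]

        def support_of(tree, side_names):
            for node in tree.root.walk():
                if node.is_leaf or node is tree.root:
                    continue
                side = frozenset(x.name for x in node.walk() if x.is_leaf)
                comp = frozenset(tree.leaf_names) - side
                if side_names in (side, comp):
                    return node.support
            return None

        t1 = bootstrap_support(aligned, reps=60, seed=4)
        t2 = bootstrap_support(renamed, reps=60, seed=4)
        split = frozenset({"y0", "y1", "y2", "y3"})
        mapped = frozenset(relabel[x] for x in split)
        assert support_of(t1, split) == support_of(t2, mapped)

    def test_nj_topology_equivariant_under_relabeling(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            n = 6
            labels = [f"t{i}" for i in range(n)]
            m = rng.random((n, n)) + 0.1
            m = (m + m.T) / 2
            np.fill_diagonal(m, 0)
            perm = list(rng.permutation(n))
            relabeled = [f"u{perm[i]}" for i in range(n)]
            t1 = nj_tree(DistanceMatrix(labels, m))
            t2 = nj_tree(DistanceMatrix(relabeled, m))
            mapping = dict(zip(labels, relabeled))

            def norm(splits, names):
                ref = sorted(names)[0]
                out = set()
                for s in splits:
                    side = s if ref not in s else frozenset(names) - s
                    out.add(side)
                return out

            mapped = {
                frozenset(mapping[x] for x in side)
                for side in t1.bipartitions()
            }
            assert norm(mapped, relabeled) == norm(t2.bipartitions(), relabeled)


class TestExonIntron:
    def profile(self, exons, introns, gid="a"):
        return ExonIntronProfile(gid, exons, introns)

    def test_identical_profiles_concordant(self):
        a = self.profile([900, 150, 200], [120, 300])
        cmp_ = compare_exon_intron(a, self.profile([900, 150, 200], [120, 300], "b"))
        assert cmp_.concordant
        assert cmp_.coding_length_diff == 0
        assert cmp_.exon_count_diff == 0

    def test_exon_gain_flagged(self):
        a = self.profile([900, 150, 200, 180, 120], [1, 1, 1, 1])
        b = self.profile([900, 150, 200, 180, 120, 90], [1, 1, 1, 1, 1], "b")
        cmp_ = compare_exon_intron(a, b)
        assert cmp_.exon_count_diff == 1
        assert not cmp_.concordant

    def test_lost_final_exon_localized(self):
        a = self.profile([900, 150, 200, 180], [1, 1, 1])
        b = self.profile([900, 150, 200], [1, 1], "b")
        cmp_ = compare_exon_intron(a, b)
        assert cmp_.discordant_exons == [4]

    def test_from_gene_model_totals(self):
        model = GeneModel("g", "c", "+", [(101, 400), (501, 700)],
                          utr5=(1, 100))
        p = ExonIntronProfile.from_gene_model(model)
        assert p.exon_lengths == [300, 200]
        assert p.intron_lengths == [100]
        assert p.coding_length == 500
        assert p.total_intron == 100

    def test_intron_exon_count_invariant(self):
        with pytest.raises(ValueError):
            self.profile([100, 200], [1, 2])
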