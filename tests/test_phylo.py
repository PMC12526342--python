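import io

import numpy as np
import pytest

from aridpop.io_core import MISSING, ValidationError
from aridpop.phylo import (DistanceMatrix, bootstrap_support, cosine_distance,
                           nj_tree, to_newick, write_newick)
from aridpop.synthetic_data import SimConfig, simulate_structured

from conftest import make_gm


def five_leaf_additive():
    # tree ((A:2,B:3):1,(C:2,D:2):2,E:4); path lengths below are exact
    ids = list("ABCDE")
    paths = {("A", "B"): 5, ("A", "C"): 7, ("A", "D"): 7, ("A", "E"): 7,
             ("B", "C"): 8, ("B", "D"): 8, ("B", "E"): 8, ("C", "D"): 4,
             ("C", "E"): 8, ("D", "E"): 8}
    D = np.zeros((5, 5))
    for (a, b), v in paths.items():
        i, j = ids.index(a), ids.index(b)
        D[i, j] = D[j, i] = v
    return DistanceMatrix(ids, D)


class TestCosineDistance:
    def test_identity_and_scale_invariance(self):
        gm = make_gm([[1, 2, 0, 1], [2, 1, 1, 0], [1, 2, 0, 1]])
        dm = cosine_distance(gm)
        assert dm.matrix[0, 2] == pytest.approx(0.0, abs=1e-12)
        gm2 = make_gm([[1, 0, 1, 0], [2, 0, 2, 0], [0, 1, 0, 1]])
        dm2 = cosine_distance(gm2)
        assert dm2.matrix[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_matches_direct_dot_product(self):
        rng = np.random.default_rng(3)
        gm = make_gm(rng.integers(0, 3, (4, 30)).astype(np.int8))
        dm = cosine_distance(gm)
        x, y = gm.dosage[1].astype(float), gm.dosage[2].astype(float)
        expect = 1 - x @ y / (np.linalg.norm(x) * np.linalg.norm(y))
        assert dm.matrix[1, 2] == pytest.approx(expect, abs=1e-12)

    def test_no_shared_sites_is_error(self):
        dosage = np.array([[1, MISSING], [MISSING, 1]], dtype=np.int8)
        with pytest.raises(ValidationError, match="share no"):
            cosine_distance(make_gm(dosage))

    def test_missing_aware_restriction(self):
        dosage = np.array([[1, 2, MISSING], [1, 2, 0]], dtype=np.int8)
        dm = cosine_distance(make_gm(dosage))
        assert dm.matrix[0, 1] == pytest.approx(0.0, abs=1e-12)


class TestNjTree:
    def test_additive_five_leaf_topology_and_lengths(self):
        tree = nj_tree(five_leaf_additive())
        assert tree.bipartitions() == {frozenset("AB"), frozenset("CD")}
        names, P = tree.leaf_distances()
        dm = five_leaf_additive()
        for i, a in enumerate(dm.sample_ids):
            for j, b in enumerate(dm.sample_ids):
                assert P[names.index(a), names.index(b)] == pytest.approx(
                    dm.matrix[i, j], abs=1e-9)

    def test_three_leaves_closed_form(self):
        D = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        tree = nj_tree(DistanceMatrix(list("ABC"), D))
        lengths = {lf.name: lf.length for lf in tree.root.leaves()}
        assert lengths == pytest.approx({"A": 1.0, "B": 2.0, "C": 3.0})

    def test_matches_reference_nj_on_random_matrix(self):
        """Cross-check topology against an independent NJ implementation."""
        skbio = pytest.importorskip("skbio")
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(11)
        n = 8
        X = rng.uniform(0, 1, (n, 12))
        D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2))
        ids = [f"t{i}" for i in range(n)]
        ours = nj_tree(DistanceMatrix(ids, D)).bipartitions()
        ref_tree = skbio_nj(SkbioDM(D, ids))
        theirs = set()
        all_leaves = frozenset(ids)
        for node in ref_tree.non_tips():
            side = frozenset(t.name for t in node.tips())
            if 1 < len(side) < n - 1:
                theirs.add(min(side, all_leaves - side,
                               key=lambda s: (len(s), sorted(s))))
        assert ours == theirs

    def test_validation_errors(self):
        bad = np.array([[0, 1], [2, 0]], dtype=float)
        with pytest.raises(ValidationError):
            nj_tree(DistanceMatrix(["a", "b"], bad))
        nan = np.full((3, 3), np.nan)
        with pytest.raises(ValidationError):
            nj_tree(DistanceMatrix(list("abc"), nan))

    def test_negative_lengths_clipped(self):
        D = np.array([[0, 0.1, 5, 5], [0.1, 0, 5, 5],
                      [5, 5, 0, 0.1], [5, 5, 0.1, 0]])
        tree = nj_tree(DistanceMatrix(list("abcd"), D))
        for lf in tree.root.leaves():
            assert lf.length >= 0


@pytest.fixture(scope="module")
def separated():
    cfg = SimConfig(seed=1, n_demes=2, deme_sizes=[6, 6],
                    bn_f=[0.4, 0.4], n_snps=300)
    gm, _ = simulate_structured(cfg)
    return gm


class TestBootstrap:

    def _edge_support(self, tree, leafset):
        out = {}
        def walk(node):
            for c in node.children:
                if not c.is_leaf:
                    out[frozenset(lf.name for lf in c.leaves())] = c.support
                walk(c)
        walk(tree.root)
        full = frozenset(tree.leaf_names())
        for key, sup in out.items():
            if key == leafset or full - key == leafset:
                return sup
        return None

    def test_separating_edge_full_support(self, separated):
        tree = bootstrap_support(separated, replicates=100, seed=0)
        deme1 = frozenset(separated.sample_ids[:6])
        assert self._edge_support(tree, deme1) == pytest.approx(100.0)

    def test_zero_replicates_no_support(self, separated):
        tree = bootstrap_support(separated, replicates=0, seed=0)
        def all_supports(node):
            for c in node.children:
                assert c.support is None
                all_supports(c)
        all_supports(tree.root)

    def test_seed_reproducibility(self, separated):
        t1 = bootstrap_support(separated, replicates=30, seed=7)
        t2 = bootstrap_support(separated, replicates=30, seed=7)
        assert to_newick(t1) == to_newick(t2)


class TestNewick:
    def test_three_leaf_format(self):
        D = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        s = to_newick(nj_tree(DistanceMatrix(list("ABC"), D)))
        assert s.endswith(";") and s.count("(") == 1
        assert "A:1" in s and "B:2" in s and "C:3" in s

    def test_labels_with_spaces_quoted(self):
        D = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        s = to_newick(nj_tree(DistanceMatrix(["a 1", "b", "c"], D)))
        assert "'a 1'" in s

    def test_round_trip_with_dendropy(self, tmp_path):
        dendropy = pytest.importorskip("dendropy")
        tree = nj_tree(five_leaf_additive())
        path = tmp_path / "t.nwk"
        write_newick(tree, path)
        parsed = dendropy.Tree.get(path=str(path), schema="newick")
        leaves = {lf.taxon.label for lf in parsed.leaf_node_iter()}
        assert leaves == set("ABCDE")
        pdm = parsed.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in parsed.taxon_namespace}
        names, P = tree.leaf_distances()
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                assert pdm.patristic_distance(taxa[a], taxa[b]) == \
                    pytest.approx(P[names.index(a), names.index(b)], abs=1e-9)

    def test_support_invariant_under_leaf_permutation(self):
        cfg = SimConfig(seed=3, n_demes=2, deme_sizes=[5, 5],
                        bn_f=[0.4, 0.4], n_snps=200)
        gm, _ = simulate_structured(cfg)
        t1 = bootstrap_support(gm, replicates=40, seed=1)
        perm_ids = list(reversed(gm.sample_ids))
        t2 = bootstrap_support(gm.subset_samples(perm_ids), replicates=40,
                               seed=1)
        deme1 = frozenset(gm.sample_ids[:5])
        get = TestBootstrap()._edge_support
        assert get(t1, deme1) == get(t2, deme1)
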