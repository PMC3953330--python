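import itertools

import dendropy
import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from txcatalog.expression_trees import (
    DistanceMatrix,
    expression_distance,
    neighbor_joining,
)
from txcatalog.feature_io import ExpressionMatrix, SampleMeta
from txcatalog.synthetic_data import generate_tree_expression


def _expr(cols):
    samples = [SampleMeta(k, k, "polyA") for k in cols]
    df = pd.DataFrame(cols, index=[f"l{i}" for i in range(len(next(iter(cols.values()))))])
    return ExpressionMatrix(df, samples)


class TestExpressionDistance:
    def test_identical_columns_distance_zero(self):
        v = [3.0, 5.0, 9.0, 2.0]
        expr = _expr({"a": v, "b": v, "c": [9.0, 2.0, 3.0, 5.0]})
        dm = expression_distance(expr, min_fpkm=1.0)
        i, j = dm.ids.index("a"), dm.ids.index("b")
        assert dm.values[i, j] == pytest.approx(0.0)

    def test_reversed_ranks_distance_two(self):
        expr = _expr(
            {"a": [1.0, 2.0, 3.0, 4.0], "b": [4.0, 3.0, 2.0, 1.0], "c": [2.0, 4.0, 1.0, 3.0]}
        )
        dm = expression_distance(expr, min_fpkm=0.5)
        i, j = dm.ids.index("a"), dm.ids.index("b")
        assert dm.values[i, j] == pytest.approx(2.0)

    def test_matches_scipy_spearman(self):
        """Independent oracle: scipy.stats.spearmanr on the filtered rows."""
        rng = np.random.default_rng(0)
        cols = {f"s{i}": rng.lognormal(1, 1, size=30) for i in range(5)}
        expr = _expr(cols)
        dm = expression_distance(expr, min_fpkm=1.0)
        kept = expr.values[(expr.values > 1.0).any(axis=1)]
        for a, b in itertools.combinations(range(len(dm.ids)), 2):
            rho = spearmanr(kept[dm.ids[a]], kept[dm.ids[b]]).statistic
            assert dm.values[a, b] == pytest.approx(1 - rho, abs=1e-12)

    def test_fpkm_filter_applied(self):
        # second locus below threshold everywhere -> dropped
        expr = _expr({"a": [5.0, 0.2, 3.0], "b": [4.0, 0.3, 6.0], "c": [2.0, 0.1, 9.0]})
        dm = expression_distance(expr, min_fpkm=1.0)
        kept = expr.values[(expr.values > 1.0).any(axis=1)]
        assert len(kept) == 2

    def test_constant_sample_errors(self):
        expr = _expr({"a": [5.0, 5.0, 5.0], "b": [1.0, 2.0, 3.0], "c": [3.0, 1.0, 2.0]})
        with pytest.raises(ValueError, match="sample a"):
            expression_distance(expr, min_fpkm=0.5)

    def test_too_few_loci_errors(self):
        expr = _expr({"a": [0.1, 0.2], "b": [0.1, 0.2], "c": [0.3, 0.1]})
        with pytest.raises(ValueError, match="fewer than 2 loci"):
            expression_distance(expr, min_fpkm=1.0)


def random_additive_tree(n_leaves, rng):
    """Random binary tree with positive branch lengths and its exact
    leaf-to-leaf path-length matrix (additivity oracle)."""
    nodes = {i: None for i in range(n_leaves)}
    lengths = {}
    parent = {}
    next_id = n_leaves
    active = list(range(n_leaves))
    while len(active) > 1:
        i, j = rng.choice(len(active), size=2, replace=False)
        a, b = active[i], active[j]
        u = next_id
        next_id += 1
        parent[a], parent[b] = u, u
        lengths[a] = float(rng.uniform(0.05, 1.0))
        lengths[b] = float(rng.uniform(0.05, 1.0))
        active = [x for x in active if x not in (a, b)] + [u]
    root = active[0]

    def path_to_root(x):
        out = {}
        d = 0.0
        while x != root:
            d += lengths[x]
            x = parent[x]
            out[x] = d
        return out

    names = [f"s{chr(ord('a') + k)}" for k in range(n_leaves)]
    D = np.zeros((n_leaves, n_leaves))
    for i in range(n_leaves):
        pi = path_to_root(i)
        pi_full = {**pi, i: 0.0}
        for j in range(i + 1, n_leaves):
            pj = {**path_to_root(j), j: 0.0}
            shared = [n for n in pi_full if n in pj]
            d = min(pi_full[n] + pj[n] for n in shared)
            D[i, j] = D[j, i] = d
    # scale into [0, 2] so the DistanceMatrix range check holds
    scale = 1.9 / D.max()
    return names, D * scale, {k: v * scale for k, v in lengths.items()}


def rf_distance(newick_a, newick_b, names):
    tns = dendropy.TaxonNamespace(names)
    ta = dendropy.Tree.get(data=newick_a, schema="newick", taxon_namespace=tns)
    tb = dendropy.Tree.get(data=newick_b, schema="newick", taxon_namespace=tns)
    ta.encode_bipartitions()
    tb.encode_bipartitions()
    return dendropy.calculate.treecompare.symmetric_difference(ta, tb)


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        d = np.array([[0, 0.6, 0.8], [0.6, 0, 1.0], [0.8, 1.0, 0]])
        tree = neighbor_joining(DistanceMatrix(("A", "B", "C"), d))
        # branch to A is (d_AB + d_AC - d_BC)/2 = 0.2, and every
        # leaf-to-leaf path reproduces the input exactly
        la = 0.5 * (0.6 + 0.8 - 1.0)
        assert tree.path_length("A", "B") == pytest.approx(0.6)
        assert tree.path_length("A", "C") == pytest.approx(0.8)
        assert tree.path_length("B", "C") == pytest.approx(1.0)
        lb = tree.path_length("A", "B") - la
        assert tree.path_length("B", "C") - lb == pytest.approx(0.8 - la)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_additive_matrix_recovery(self, seed):
        """NJ reconstructs the generating topology and all path lengths."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 11))
        names, D, _ = random_additive_tree(n, rng)
        tree = neighbor_joining(DistanceMatrix(tuple(names), D))
        for i in range(n):
            for j in range(i + 1, n):
                assert tree.path_length(names[i], names[j]) == pytest.approx(
                    D[i, j], abs=1e-9
                )

    def test_matches_skbio_topology(self):
        """Independent implementation check: scikit-bio's nj on the same
        additive matrix yields the same unrooted topology."""
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(7)
        names, D, _ = random_additive_tree(8, rng)
        ours = neighbor_joining(DistanceMatrix(tuple(names), D)).to_newick()
        theirs = str(skbio_nj(SkbioDM(D, ids=names)))
        assert rf_distance(ours, theirs, names) == 0

    def test_degenerate_equal_distances_deterministic(self):
        """All-equal distances resolve by the lexicographic tie-break."""
        d = np.full((4, 4), 1.0)
        np.fill_diagonal(d, 0.0)
        t1 = neighbor_joining(DistanceMatrix(("a", "b", "c", "d"), d)).to_newick()
        t2 = neighbor_joining(DistanceMatrix(("a", "b", "c", "d"), d)).to_newick()
        assert t1 == t2
        # first join is the lexicographically smallest pair (a, b)
        assert rf_distance(t1, "((a,b),c,d);", ["a", "b", "c", "d"]) == 0

    def test_permutation_invariance_canonical_newick(self):
        rng = np.random.default_rng(9)
        names, D, _ = random_additive_tree(7, rng)
        base = neighbor_joining(DistanceMatrix(tuple(names), D)).to_newick()
        perm = rng.permutation(len(names))
        names_p = [names[i] for i in perm]
        D_p = D[np.ix_(perm, perm)]
        permuted = neighbor_joining(DistanceMatrix(tuple(names_p), D_p)).to_newick()
        assert permuted == base

    def test_no_negative_branch_lengths(self):
        rng = np.random.default_rng(11)
        # noisy (non-additive) matrix provokes negative NJ estimates
        n = 8
        base = rng.uniform(0.2, 1.8, size=(n, n))
        D = (base + base.T) / 2
        np.fill_diagonal(D, 0.0)
        tree = neighbor_joining(DistanceMatrix(tuple("abcdefgh"), D))
        for node, nbrs in tree.adjacency.items():
            for _, ln in nbrs:
                assert ln >= 0.0

    def test_fewer_than_three_samples_errors(self):
        d = np.array([[0.0, 1.0], [1.0, 0.0]])
        with pytest.raises(ValueError, match="at least 3"):
            neighbor_joining(DistanceMatrix(("a", "b"), d))


class TestGroupingStructure:
    def _nearest_partner(self, tree, leaves):
        out = {}
        for a in leaves:
            out[a] = min(
                (b for b in leaves if b != a),
                key=lambda b: tree.path_length(a, b),
            )
        return out

    def test_tissue_effects_dominate(self):
        expr = generate_tree_expression(
            n_loci=150, tissue_sd=1.2, method_sd=0.05, seed=21
        )
        dm = expression_distance(expr, min_fpkm=1.0)
        tree = neighbor_joining(dm)
        partners = self._nearest_partner(tree, tree.leaves)
        for a, b in partners.items():
            assert a.rsplit("_", 1)[0] == b.rsplit("_", 1)[0]  # same tissue

    def test_method_effects_dominate(self):
        expr = generate_tree_expression(
            n_loci=150, tissue_sd=0.05, method_sd=1.2, seed=22
        )
        dm = expression_distance(expr, min_fpkm=1.0)
        tree = neighbor_joining(dm)
        partners = self._nearest_partner(tree, tree.leaves)
        for a, b in partners.items():
            assert a.rsplit("_", 1)[1] == b.rsplit("_", 1)[1]  # same method
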