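import itertools

import dendropy
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad
from scipy.stats import gamma as gamma_dist

import isdgkit as ik
from conftest import brute_force_loglik, clean_family
from isdgkit.msa import Alignment
from isdgkit.phylogeny import (PatternData, UndefinedDistanceError,
                               _bipartitions, deroot, discretize_gamma,
                               tree_path_distances)
from isdgkit.records import InvalidArgumentError


class TestDiscretizeGamma:
    def test_single_category_degenerate(self):
        assert discretize_gamma(2.7, 1).tolist() == [1.0]

    @settings(derandomize=True, max_examples=25)
    @given(st.floats(min_value=0.05, max_value=20.0))
    def test_mean_is_one(self, alpha):
        rates = discretize_gamma(alpha, 4)
        assert rates.mean() == pytest.approx(1.0, abs=1e-9)
        assert (np.diff(rates) > 0).all()

    def test_quadrature_oracle_alpha_one(self):
        """Category rates equal numeric quartile means of the gamma law."""
        alpha, k = 1.0, 4
        bounds = gamma_dist.ppf(np.arange(k + 1) / k, a=alpha, scale=1 / alpha)
        expected = []
        for lo, hi in zip(bounds, bounds[1:]):
            val, _ = quad(lambda x: x * gamma_dist.pdf(x, a=alpha, scale=1 / alpha),
                          lo, min(hi, 1e3))
            expected.append(val * k)
        rates = discretize_gamma(alpha, k)
        assert np.allclose(rates, expected, atol=1e-6)

    def test_invalid_alpha(self):
        with pytest.raises(InvalidArgumentError):
            discretize_gamma(0.0, 4)


class TestSubstModel:
    def test_invariants(self, g4_model):
        assert g4_model.stationary.sum() == pytest.approx(1.0)
        assert np.abs(g4_model.rate_matrix.sum(axis=1)).max() < 1e-12
        mean_rate = -(g4_model.stationary
                      * np.diag(g4_model.rate_matrix)).sum()
        assert mean_rate == pytest.approx(1.0, abs=1e-9)
        assert g4_model.rates.mean() == pytest.approx(1.0, abs=1e-9)

    def test_detailed_balance(self, lg_model):
        P = lg_model.transition_matrix(0.7)
        flux = lg_model.stationary[:, None] * P
        assert np.abs(flux - flux.T).max() < 1e-12


class TestTreeLogLikelihood:
    def test_two_taxon_closed_form(self, g4_model):
        tree = ik.parse_newick("(A:0.3,B:0.4);")
        aln = Alignment({"A": "NWHACDEFGH", "B": "NWAACDRFGH"})
        ll = ik.tree_log_likelihood(aln, tree, g4_model)
        from isdgkit.records import encode_sequence
        ca, cb = encode_sequence("NWHACDEFGH"), encode_sequence("NWAACDRFGH")
        direct = 0.0
        for i, j in zip(ca, cb):
            s = np.mean([g4_model.stationary[i]
                         * g4_model.transition_matrix(0.7, r)[i, j]
                         for r in g4_model.rates])
            direct += np.log(s)
        assert ll == pytest.approx(direct, abs=1e-10)

    def test_four_taxon_enumeration_oracle(self, lg_model, g4_model):
        for seed, model in [(1, lg_model), (2, g4_model)]:
            tree = deroot(ik.sample_tree(4, 0.4, seed=seed))
            _, aln, _ = clean_family(4, 30, model.alpha, seed, tree=tree.clone(depth=1))
            tree2 = deroot(tree.clone(depth=1))
            ll = ik.tree_log_likelihood(aln, tree2, model)
            oracle = brute_force_loglik(aln, tree2, model)
            assert ll == pytest.approx(oracle, abs=1e-8)

    def test_total_probability_three_taxon(self, g4_model, lg_model):
        tree = ik.parse_newick("(A:0.2,B:0.5,C:0.9);")
        cols = list(itertools.product(ik.AMINO_ACIDS, repeat=3))
        aln = Alignment({
            "A": "".join(c[0] for c in cols),
            "B": "".join(c[1] for c in cols),
            "C": "".join(c[2] for c in cols),
        })
        for model in (lg_model, g4_model):
            sl = ik.PruningEngine(aln, model).site_log_likelihoods(tree)
            assert np.exp(sl).sum() == pytest.approx(1.0, abs=1e-8)

    def test_pattern_compression_consistency(self, g4_model):
        tree, aln, _ = clean_family(6, 120, 1.0, seed=4)
        engine = ik.PruningEngine(aln, g4_model)
        t2 = deroot(tree.clone(depth=1))
        ll = engine.loglik(t2)
        assert engine.site_log_likelihoods(t2).sum() == pytest.approx(ll, abs=1e-10)
        assert engine.n_patterns <= aln.n_cols

    def test_pulley_principle(self, g4_model):
        """Log-likelihood is invariant under re-rooting (reversibility)."""
        tree, aln, _ = clean_family(6, 80, 1.0, seed=5)
        engine = ik.PruningEngine(aln, g4_model)
        base = engine.loglik(tree)
        for node in list(tree.preorder_internal_node_iter())[1:3]:
            t2 = tree.clone(depth=1)
            target = [n for n in t2.preorder_internal_node_iter()
                      if n.leaf_nodes()[0].taxon.label
                      == node.leaf_nodes()[0].taxon.label][0]
            t2.reroot_at_node(target, update_bipartitions=False)
            assert engine.loglik(t2) == pytest.approx(base, abs=1e-8)

    def test_leaf_mismatch_refused(self, lg_model):
        tree = ik.parse_newick("(A:0.1,B:0.1);")
        aln = Alignment({"A": "NWH", "C": "NWH"})
        with pytest.raises(InvalidArgumentError):
            ik.tree_log_likelihood(aln, tree, lg_model)


class TestMLDistance:
    def test_identical_sequences_zero(self, lg_model):
        assert ik.ml_distance("NWHAC" * 20, "NWHAC" * 20, lg_model) == 0.0

    def test_symmetry(self, lg_model):
        a = "MNWHARKDVLFEGYTPSWICQ" * 4
        b = "MNAHARKEVLFDGYTPSAICQ" * 4
        assert ik.ml_distance(a, b, lg_model) == \
            pytest.approx(ik.ml_distance(b, a, lg_model), abs=1e-6)

    def test_no_shared_columns(self, lg_model):
        with pytest.raises(UndefinedDistanceError):
            ik.ml_distance("N-", "-W", lg_model)


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        D = np.array([[0.0, 0.5, 0.9], [0.5, 0.0, 0.8], [0.9, 0.8, 0.0]])
        tree = ik.neighbor_joining(D, ["A", "B", "C"])
        lens = {l.taxon.label: l.edge.length for l in tree.leaf_node_iter()}
        assert lens["A"] == pytest.approx((0.5 + 0.9 - 0.8) / 2)
        assert lens["B"] == pytest.approx((0.5 + 0.8 - 0.9) / 2)
        assert lens["C"] == pytest.approx((0.9 + 0.8 - 0.5) / 2)

    def test_additivity_recovers_topology(self):
        for seed in range(10):
            true = ik.sample_tree(8, 0.3, seed=seed)
            labels, D = tree_path_distances(true)
            nj = ik.neighbor_joining(D, labels)
            assert ik.robinson_foulds(nj, true) == 0

    def test_invalid_matrices(self):
        with pytest.raises(InvalidArgumentError):
            ik.neighbor_joining(np.array([[0, 1.0], [2.0, 0]]), ["A", "B"])
        D = np.array([[0.0, -0.5, 0.9], [-0.5, 0.0, 0.8], [0.9, 0.8, 0.0]])
        with pytest.raises(InvalidArgumentError):
            ik.neighbor_joining(D, ["A", "B", "C"])


class TestOptimizeTree:
    def test_no_worsening_from_true_tree(self, g4_model):
        tree, aln, _ = clean_family(8, 300, 1.0, seed=6)
        engine = ik.PruningEngine(aln, g4_model)
        start_ll = engine.loglik(deroot(tree.clone(depth=1)))
        out = ik.optimize_tree(aln, tree, g4_model)
        assert ik.robinson_foulds(out, tree) == 0
        assert engine.loglik(out) >= start_ll - 1e-6

    def test_branch_optimisation_monotone(self, g4_model):
        tree, aln, _ = clean_family(6, 150, 1.0, seed=8)
        t2 = deroot(tree.clone(depth=1))
        for e in t2.preorder_edge_iter():
            if e.tail_node is not None:
                e.length = 0.5  # deliberately wrong start
        engine = ik.PruningEngine(aln, g4_model)
        ll0 = engine.loglik(t2)
        ll1 = engine.optimize_branch_lengths(t2, max_sweeps=1)
        ll2 = engine.optimize_branch_lengths(t2, max_sweeps=1)
        assert ll0 <= ll1 <= ll2 + 1e-9


class TestMidpointRoot:
    def test_two_leaf_closed_form(self):
        rooted = ik.midpoint_root(ik.parse_newick("(A:1,B:3);"))
        lens = sorted(l.edge.length for l in rooted.leaf_node_iter())
        assert lens == pytest.approx([2.0, 2.0])

    def test_three_leaf_star(self):
        rooted = ik.midpoint_root(ik.parse_newick("(A:1,B:2,C:5);"))
        labels, D = tree_path_distances(rooted)
        root_to = {lab: None for lab in labels}
        c = [l for l in rooted.leaf_node_iter() if l.taxon.label == "C"][0]
        # root sits on C's branch, 3.5 from C
        d = 0.0
        node = c
        while node.parent_node is not None:
            d += node.edge.length
            node = node.parent_node
        assert d == pytest.approx(3.5)

    def test_missing_branch_lengths_refused(self):
        with pytest.raises(InvalidArgumentError):
            ik.midpoint_root(ik.parse_newick("(A:1,(B,C:2):1);"))

    def test_brute_force_oracle(self):
        """Rooting equals the dense scan over all edges and positions."""
        for seed in range(20):
            tree = deroot(ik.sample_tree(10, 0.4, seed=seed))
            rooted = ik.midpoint_root(tree)
            # eccentricity of the chosen root
            labels, _ = tree_path_distances(tree)
            root_depths = {}
            for leaf in rooted.leaf_node_iter():
                d, node = 0.0, leaf
                while node.parent_node is not None:
                    d += node.edge.length
                    node = node.parent_node
                root_depths[leaf.taxon.label] = d
            achieved = max(root_depths.values())
            # oracle: min over edges of the optimal point on that edge
            best = np.inf
            adj = {}
            for node in tree.preorder_node_iter():
                for ch in node.child_nodes():
                    adj.setdefault(node, []).append((ch, ch.edge.length))
                    adj.setdefault(ch, []).append((node, ch.edge.length))
            leaves = list(tree.leaf_node_iter())

            def dists_from(src):
                out = {src: 0.0}
                stack = [src]
                while stack:
                    nd = stack.pop()
                    for nbr, w in adj[nd]:
                        if nbr not in out:
                            out[nbr] = out[nd] + w
                            stack.append(nbr)
                return out

            dist = {l: dists_from(l) for l in leaves}
            for node in tree.preorder_node_iter():
                for ch in node.child_nodes():
                    L = ch.edge.length
                    side_ch = set(ch.leaf_iter())
                    a = max(dist[l][node] for l in leaves if l not in side_ch) \
                        if len(side_ch) < len(leaves) else 0.0
                    b = max(dist[l][ch] for l in side_ch) if side_ch else 0.0
                    x = min(max((b + L - a) / 2.0, 0.0), L)
                    best = min(best, max(a + x, b + L - x))
            assert achieved == pytest.approx(best, abs=1e-9)
            # the two deepest leaves on opposite sides of the root tie
            sides = {}
            for child in rooted.seed_node.child_nodes():
                m = 0.0
                for leaf in child.leaf_iter():
                    m = max(m, root_depths[leaf.taxon.label])
                sides[id(child)] = m
            deepest = sorted(sides.values())[-2:]
            assert deepest[0] == pytest.approx(deepest[1], abs=1e-9)


class TestRobinsonFoulds:
    def test_identity_and_symmetry(self):
        t1 = ik.sample_tree(8, seed=1)
        t2 = ik.sample_tree(8, seed=2)
        assert ik.robinson_foulds(t1, t1) == 0
        assert ik.robinson_foulds(t1, t2) == ik.robinson_foulds(t2, t1)

    def test_four_taxon_distinct_topologies(self):
        t1 = ik.parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        t2 = ik.parse_newick("((A:1,C:1):1,(B:1,D:1):1);")
        assert ik.robinson_foulds(t1, t2) == 2

    def test_leaf_set_mismatch(self):
        t1 = ik.parse_newick("((A:1,B:1):1,C:1);")
        t2 = ik.parse_newick("((A:1,B:1):1,D:1);")
        with pytest.raises(InvalidArgumentError):
            ik.robinson_foulds(t1, t2)


class TestBootstrap:
    def test_supports_in_unit_interval_and_only_internal(self, g4_model):
        tree, aln, _ = clean_family(8, 200, 1.0, seed=9)
        cfg = ik.PhyloConfig(bootstrap_reps=30)
        out = ik.bootstrap_support(aln, deroot(tree.clone(depth=1)),
                                   g4_model, cfg, seed=0)
        n_sup = 0
        for node in out.preorder_node_iter():
            sup = getattr(node, "support", None)
            if node.is_leaf() or node.parent_node is None:
                assert sup is None
            elif sup is not None:
                assert 0.0 <= sup <= 1.0
                n_sup += 1
        assert n_sup > 0

    def test_zero_reps_means_absent(self, g4_model):
        tree, aln, _ = clean_family(6, 100, 1.0, seed=10)
        out = ik.bootstrap_support(aln, tree, g4_model,
                                   ik.PhyloConfig(bootstrap_reps=0), seed=0)
        assert all(getattr(n, "support", None) is None
                   for n in out.preorder_node_iter())

    def test_deterministic_under_seed(self, g4_model):
        tree, aln, _ = clean_family(6, 100, 1.0, seed=11)
        outs = []
        for _ in range(2):
            out = ik.bootstrap_support(aln, deroot(tree.clone(depth=1)),
                                       g4_model,
                                       ik.PhyloConfig(bootstrap_reps=20), seed=3)
            outs.append(ik.write_newick(out))
        assert outs[0] == outs[1]


class TestModelSelection:
    def test_single_candidate_returned(self, lg_model):
        tree, aln, _ = clean_family(5, 100, None, seed=12)
        model = ik.select_model_bic(aln, tree, candidates=("LG",))
        assert model.alpha is None and model.name == "LG"

    def test_full_output_reports_both_fits(self):
        tree, aln, _ = clean_family(5, 150, 0.5, seed=13)
        model, fits = ik.select_model_bic(aln, tree, full_output=True)
        assert len(fits) == 2
        assert fits[0]["bic"] <= fits[1]["bic"]
        ks = sorted(f["k"] for f in fits)
        assert ks[1] == ks[0] + 1
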