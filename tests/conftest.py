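import numpy as np
import pytest

import isdgkit as ik
from isdgkit.msa import Alignment


@pytest.fixture(scope="session")
def lg_model():
    return ik.SubstModel()


@pytest.fixture(scope="session")
def g4_model():
    return ik.SubstModel(alpha=1.0)


@pytest.fixture(scope="session")
def default_family():
    """One default 16-taxon synthetic dataset with all confounders."""
    cfg = ik.SimConfig(seed=7)
    records, truth = ik.simulate_dataset(cfg)
    return cfg, records, truth


def clean_family(n_taxa, domain_length, alpha, seed, branch_scale=0.25,
                 tree=None):
    """Insert- and confounder-free family for likelihood-level tests."""
    cfg = ik.SimConfig(
        n_taxa=n_taxa, domain_length=domain_length, insert_clade=(),
        n_decoys=0, n_duplicates=0, n_fusions=0,
        triad_positions=(), aux_positions=(), degraded_fraction=0.0,
        alpha=alpha, seed=seed,
    )
    if tree is None:
        tree = ik.sample_tree(n_taxa, branch_scale, seed=seed)
    records, truth = ik.evolve_family(tree, cfg)
    aln = Alignment([(r.id, r.sequence) for r in records])
    return tree, aln, truth


def brute_force_global_score(M, go, ge):
    """Exhaustive-recursion oracle for global affine-gap alignment.

    Independent top-down formulation over (i, j, previous move) with a
    cache; gap of length k costs go + (k-1)*ge, end gaps included.
    """
    from functools import lru_cache
    n, m = M.shape

    @lru_cache(maxsize=None)
    def best(i, j, last):
        if i == n and j == m:
            return 0.0
        options = []
        if i < n and j < m:
            options.append(M[i, j] + best(i + 1, j + 1, "M"))
        if j < m:  # gap in A, consume B
            options.append(-(ge if last == "A" else go) + best(i, j + 1, "A"))
        if i < n:  # gap in B, consume A
            options.append(-(ge if last == "B" else go) + best(i + 1, j, "B"))
        return max(options)

    return best(0, 0, "M")


def brute_force_local_score(M, go, ge):
    """Exhaustive-recursion oracle for local affine-gap alignment."""
    from functools import lru_cache
    n, m = M.shape

    @lru_cache(maxsize=None)
    def ext(i, j, last):
        """Best suffix score starting with the given pending state."""
        options = [0.0]
        if i < n and j < m:
            options.append(M[i, j] + ext(i + 1, j + 1, "M"))
        if j < m and last != "start":
            options.append(-(ge if last == "A" else go) + ext(i, j + 1, "A"))
        if i < n and last != "start":
            options.append(-(ge if last == "B" else go) + ext(i + 1, j, "B"))
        return max(options)

    best = 0.0
    for i in range(n):
        for j in range(m):
            best = max(best, M[i, j] + ext(i + 1, j + 1, "M"))
    return best


def brute_force_loglik(aln, tree, model):
    """Likelihood by exhaustive enumeration over internal-node states.

    Independent of the pruning engine: sums pi(root) * prod P(edge) over
    every assignment of states to internal nodes, per site, averaged over
    gamma categories.  Only feasible for tiny trees; columns must be
    gap-free.
    """
    import itertools
    import math

    from isdgkit.records import encode_sequence

    codes = {rid: encode_sequence(aln.row(rid)) for rid in aln.ids}
    internals = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    edges = [(e.tail_node, e.head_node, e.length)
             for e in tree.preorder_edge_iter() if e.tail_node is not None]
    ncols = aln.n_cols
    pi = model.stationary
    K = len(model.rates)
    P = [{id(h): model.transition_matrix(l, r) for _, h, l in edges}
         for r in model.rates]
    total = 0.0
    for col in range(ncols):
        state = {id(l): codes[l.taxon.label][col]
                 for l in tree.leaf_node_iter()}
        site = 0.0
        for k in range(K):
            Pk = P[k]
            for assign in itertools.product(range(20), repeat=len(internals)):
                for n, s in zip(internals, assign):
                    state[id(n)] = s
                p = pi[state[id(tree.seed_node)]]
                for t, h, _ in edges:
                    p *= Pk[id(h)][state[id(t)], state[id(h)]]
                site += p
        total += math.log(site / K)
    return total


def spread_seed_records(records, truth, k=6):
    """Pick k family leaves evenly spread in tree leaf order, as seeds."""
    leaves = [l.taxon.label for l in truth.true_tree.leaf_node_iter()]
    idx = np.linspace(0, len(leaves) - 1, k).round().astype(int)
    wanted = [leaves[i] for i in sorted(set(idx))]
    by_id = {r.id: r for r in records}
    return [by_id[w] for w in wanted]
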