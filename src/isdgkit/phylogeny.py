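"""Maximum-likelihood phylogenetics under LG(+G4).

The inference stack mirrors the classic amino-acid workflow: pairwise
maximum-likelihood distances feed a neighbor-joining starting tree, which
is refined by nearest-neighbor-interchange hill climbing with per-branch
Brent optimisation of lengths under the Le-Gascuel model, optionally with
4-category discrete-gamma rate heterogeneity.  Model choice between LG and
LG+G4 uses the Bayesian information criterion, support values come from a
nonparametric site-resampling bootstrap, and trees are midpoint rooted.

Trees are :class:`dendropy.Tree` objects throughout; unrooted trees are
represented with a trifurcating seed node.  Site likelihoods are computed
by Felsenstein pruning over compressed site patterns with per-pattern
rescaling; gaps and X count as missing data.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

from ._lg import lg_exchangeabilities, lg_stationary
from .records import AMINO_ACIDS, InvalidArgumentError, encode_sequence

BRLEN_MIN = 1e-9
BRLEN_MAX = 10.0


class UndefinedDistanceError(InvalidArgumentError):
    """Two sequences share no scoreable columns."""


# ---------------------------------------------------------------------------
# Substitution model
# ---------------------------------------------------------------------------

def discretize_gamma(alpha: float, k: int) -> np.ndarray:
    """Equal-probability discrete-gamma category rates (category means).

    Rates are the conditional means of the mean-1 gamma distribution within
    each of its k equal-probability quantile bins, renormalised to mean 1.
    """
    if alpha <= 0:
        raise InvalidArgumentError("gamma shape alpha must be > 0")
    if k < 1:
        raise InvalidArgumentError("need at least one rate category")
    if k == 1:
        return np.ones(1)
    # X ~ Gamma(alpha, rate=alpha); E[X; X<=b] = gammainc(alpha+1, alpha*b)
    bounds = gamma_dist.ppf(np.arange(k + 1) / k, a=alpha, scale=1.0 / alpha)
    upper = np.empty(k + 1)
    upper[0] = 0.0
    upper[-1] = 1.0
    upper[1:-1] = gammainc(alpha + 1, alpha * bounds[1:-1])
    rates = k * np.diff(upper)
    return rates / rates.mean()


class SubstModel:
    """Reversible amino-acid substitution model (LG by default).

    The rate matrix is normalised to one expected substitution per site per
    unit time at equilibrium; transition matrices come from the symmetrised
    eigendecomposition, shared across gamma categories.
    """

    def __init__(self, alpha: float | None = None, n_categories: int = 4,
                 exchangeabilities: np.ndarray | None = None,
                 stationary: np.ndarray | None = None, name: str | None = None):
        S = lg_exchangeabilities() if exchangeabilities is None else np.asarray(exchangeabilities, float)
        pi = lg_stationary() if stationary is None else np.asarray(stationary, float)
        if not np.allclose(S, S.T):
            raise InvalidArgumentError("exchangeability matrix must be symmetric")
        pi = pi / pi.sum()
        Q = S * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        scale = -(pi * np.diag(Q)).sum()
        Q /= scale
        self.rate_matrix = Q
        self.stationary = pi
        self.alpha = alpha
        self.n_categories = n_categories if alpha is not None else 1
        self.name = name or ("LG+G4" if alpha is not None else "LG")
        d = np.sqrt(pi)
        sym = Q * d[:, None] / d[None, :]
        sym = 0.5 * (sym + sym.T)
        lam, U = np.linalg.eigh(sym)
        self._lam = lam
        self._left = U / d[:, None]          # D^-1/2 U
        self._right = U.T * d[None, :]       # U^T D^1/2
        self.rates = (discretize_gamma(alpha, self.n_categories)
                      if alpha is not None else np.ones(1))

    def with_alpha(self, alpha: float | None) -> "SubstModel":
        m = SubstModel.__new__(SubstModel)
        m.__dict__.update(self.__dict__)
        m.alpha = alpha
        m.n_categories = self.n_categories if alpha is not None else 1
        m.name = "LG+G4" if alpha is not None else "LG"
        m.rates = (discretize_gamma(alpha, 4) if alpha is not None else np.ones(1))
        if alpha is not None:
            m.n_categories = len(m.rates)
        return m

    def transition_matrix(self, t: float, rate: float = 1.0) -> np.ndarray:
        """P(t) for a single overall rate."""
        e = np.exp(self._lam * (t * rate))
        return (self._left * e[None, :]) @ self._right

    def transition_matrices(self, t: float) -> np.ndarray:
        """Stack of P(t * r_c) over gamma categories, shape (K, 20, 20)."""
        e = np.exp(self._lam[None, :] * (t * self.rates[:, None]))  # (K, 20)
        return np.einsum("ij,kj,jl->kil", self._left, e, self._right)

    def mixture_transition_matrix(self, t: float) -> np.ndarray:
        """Category-averaged P(t); categories share eigenvectors."""
        e = np.exp(self._lam[None, :] * (t * self.rates[:, None])).mean(axis=0)
        return (self._left * e[None, :]) @ self._right

    @property
    def n_free_parameters(self) -> int:
        return 1 if self.alpha is not None else 0


# ---------------------------------------------------------------------------
# Pattern compression + pruning engine
# ---------------------------------------------------------------------------

class PatternData:
    """Compressed site patterns of an alignment (codes 0..19, 20 = missing)."""

    def __init__(self, aln):
        self.ids = list(aln.ids)
        mat = np.stack([
            encode_sequence(aln.row(i).replace("-", "X")) for i in self.ids
        ])
        self.n_cols = mat.shape[1]
        patterns, inverse, counts = np.unique(
            mat.T, axis=0, return_inverse=True, return_counts=True
        )
        self.patterns = patterns.T.astype(np.int8)   # (n_taxa, P)
        self.pattern_index = inverse                 # column -> pattern
        self.weights = counts.astype(float)
        self.row_of = {rid: i for i, rid in enumerate(self.ids)}


class PruningEngine:
    """Felsenstein pruning over a fixed alignment and model."""

    def __init__(self, data, model: SubstModel):
        if not isinstance(data, PatternData):
            data = PatternData(data)
        self.data = data
        self.model = model
        P = data.patterns.shape[1]
        eye = np.vstack([np.eye(20), np.ones(20)])  # code 20 -> all ones
        self._leaf = {
            rid: np.ascontiguousarray(eye[data.patterns[i]].T)  # (20, P)
            for rid, i in data.row_of.items()
        }
        self.n_patterns = P

    # -- helpers ----------------------------------------------------------

    def _check_tree(self, tree) -> None:
        labels = sorted(l.taxon.label for l in tree.leaf_node_iter())
        if labels != sorted(self.data.ids):
            raise InvalidArgumentError("tree leaf set does not match alignment")

    def _child_contrib(self, child, lower):
        T = self.model.transition_matrices(child.edge.length or 0.0)
        arr, scale = lower[child]
        if arr.ndim == 2:  # leaf
            return np.einsum("kij,jp->kip", T, arr), scale
        return np.einsum("kij,kjp->kip", T, arr), scale

    def _lower_partials(self, tree):
        """Post-order conditional likelihoods; leaves stored as (20, P)."""
        P = self.n_patterns
        lower = {}
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                lower[node] = (self._leaf[node.taxon.label], np.zeros(P))
                continue
            arr = None
            scale = np.zeros(P)
            for child in node.child_nodes():
                carr, cscale = self._child_contrib(child, lower)
                arr = carr if arr is None else arr * carr
                scale = scale + cscale
            m = arr.max(axis=(0, 1))
            m = np.where(m > 0, m, 1.0)
            lower[node] = (arr / m, scale + np.log(m))
        return lower

    def site_log_likelihoods(self, tree) -> np.ndarray:
        """Per-column log-likelihood (pattern values mapped back to columns)."""
        self._check_tree(tree)
        lower = self._lower_partials(tree)
        arr, scale = lower[tree.seed_node]
        lik = np.einsum("i,kip->kp", self.model.stationary, arr).mean(axis=0)
        logl = np.log(np.maximum(lik, 1e-300)) + scale
        return logl[self.data.pattern_index]

    def loglik(self, tree) -> float:
        self._check_tree(tree)
        lower = self._lower_partials(tree)
        arr, scale = lower[tree.seed_node]
        lik = np.einsum("i,kip->kp", self.model.stationary, arr).mean(axis=0)
        return float(np.dot(self.data.weights, np.log(np.maximum(lik, 1e-300)) + scale))

    # -- per-edge machinery for branch-length optimisation -----------------

    def _edge_data(self, tree, target_edge):
        """Lower partial below and outer partial above one edge.

        The outer partial A excludes the target branch entirely, so the
        edge log-likelihood is a function of that branch length alone.
        """
        lower = self._lower_partials(tree)
        P = self.n_patterns
        pi = self.model.stationary
        K = len(self.model.rates)
        outer = {tree.seed_node: (np.broadcast_to(pi[None, :, None], (K, 20, P)).copy(),
                                  np.zeros(P))}
        target_child = target_edge.head_node
        for node in tree.preorder_node_iter():
            if node.is_leaf() or node not in outer:
                continue
            O, oscale = outer[node]
            contribs = [self._child_contrib(c, lower) for c in node.child_nodes()]
            for idx, child in enumerate(node.child_nodes()):
                A = O.copy()
                ascale = oscale.copy()
                for jdx, (carr, cscale) in enumerate(contribs):
                    if jdx == idx:
                        continue
                    A = A * carr
                    ascale = ascale + cscale
                m = A.max(axis=(0, 1))
                m = np.where(m > 0, m, 1.0)
                A = A / m
                ascale = ascale + np.log(m)
                if child is target_child:
                    return A, ascale, lower[child]
                if not child.is_leaf():
                    T = self.model.transition_matrices(child.edge.length or 0.0)
                    outer[child] = (np.einsum("kij,kip->kjp", T, A), ascale)
        raise InvalidArgumentError("edge not found in tree")

    def edge_loglik(self, A, ascale, lower_child, t: float) -> float:
        T = self.model.transition_matrices(t)
        arr, lscale = lower_child
        if arr.ndim == 2:
            X = np.einsum("kij,jp->kip", T, arr)
        else:
            X = np.einsum("kij,kjp->kip", T, arr)
        lik = (A * X).sum(axis=1).mean(axis=0)
        return float(np.dot(self.data.weights,
                            np.log(np.maximum(lik, 1e-300)) + ascale + lscale))

    def optimize_branch_lengths(self, tree, tol: float = 1e-4,
                                max_sweeps: int = 2) -> float:
        """Brent-optimise every branch; log-likelihood never decreases."""
        ll = self.loglik(tree)
        for _ in range(max_sweeps):
            improved = False
            edges = [e for e in tree.preorder_edge_iter() if e.tail_node is not None]
            for edge in edges:
                A, ascale, low = self._edge_data(tree, edge)
                t0 = edge.length or 0.0
                f0 = self.edge_loglik(A, ascale, low, t0)
                res = minimize_scalar(
                    lambda t: -self.edge_loglik(A, ascale, low, t),
                    bounds=(BRLEN_MIN, BRLEN_MAX), method="bounded",
                    options={"xatol": tol},
                )
                if -res.fun > f0 + 1e-10:
                    edge.length = float(res.x)
                    improved = True
            new_ll = self.loglik(tree)
            if not improved or new_ll - ll < 10 * tol:
                ll = max(ll, new_ll)
                break
            ll = new_ll
        return ll


def tree_log_likelihood(aln, tree, model: SubstModel) -> float:
    """Pruning log-likelihood of an alignment on a tree."""
    return PruningEngine(aln, model).loglik(tree)


# ---------------------------------------------------------------------------
# Pairwise ML distances
# ---------------------------------------------------------------------------

def _pair_counts(a: str, b: str) -> np.ndarray:
    ca = encode_sequence(a.replace("-", "X"))
    cb = encode_sequence(b.replace("-", "X"))
    if len(ca) != len(cb):
        raise InvalidArgumentError("ml_distance expects an aligned pair")
    mask = (ca < 20) & (cb < 20)
    if not mask.any():
        raise UndefinedDistanceError("no shared non-gap columns")
    counts = np.zeros((20, 20))
    np.add.at(counts, (ca[mask], cb[mask]), 1.0)
    return counts


def ml_distance_from_counts(counts: np.ndarray, model: SubstModel,
                            tol: float = 1e-6) -> float:
    if counts.sum() == 0:
        raise UndefinedDistanceError("no shared non-gap columns")
    if np.trace(counts) == counts.sum():
        return 0.0
    pi = model.stationary

    def nll(t):
        P = model.mixture_transition_matrix(t)
        joint = pi[:, None] * np.maximum(P, 1e-300)
        return -(counts * np.log(joint)).sum()

    res = minimize_scalar(nll, bounds=(BRLEN_MIN, BRLEN_MAX), method="bounded",
                          options={"xatol": tol})
    return float(res.x)


def ml_distance(a: str, b: str, model: SubstModel, tol: float = 1e-6) -> float:
    """Expected substitutions/site between two aligned sequences (MLE)."""
    return ml_distance_from_counts(_pair_counts(a, b), model, tol)


def distance_matrix(aln, model: SubstModel, tol: float = 1e-6):
    """All pairwise ML distances of an alignment; returns (ids, matrix)."""
    ids = list(aln.ids)
    n = len(ids)
    D = np.zeros((n, n))
    rows = [aln.row(i) for i in ids]
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = ml_distance(rows[i], rows[j], model, tol)
    return ids, D


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def neighbor_joining(D: np.ndarray, labels) -> dendropy.Tree:
    """Canonical NJ; ties broken by smallest (i, j) index pair, negative
    branch lengths clamped to zero."""
    D = np.asarray(D, float)
    labels = list(labels)
    n = D.shape[0]
    if D.shape != (n, n) or n != len(labels):
        raise InvalidArgumentError("distance matrix/labels shape mismatch")
    if not np.allclose(D, D.T, atol=1e-12):
        raise InvalidArgumentError("distance matrix must be symmetric")
    if (D < 0).any():
        raise InvalidArgumentError("distance matrix must be non-negative")
    if np.abs(np.diag(D)).max() > 1e-12:
        raise InvalidArgumentError("distance matrix diagonal must be zero")
    if n < 2:
        raise InvalidArgumentError("need at least 2 taxa")

    taxa = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes = []
    for lab in labels:
        nd = dendropy.Node(taxon=taxa.get_taxon(lab))
        nodes.append(nd)
    D = D.copy()
    active = list(range(n))

    if n == 2:
        tree.seed_node.add_child(nodes[0])
        tree.seed_node.add_child(nodes[1])
        nodes[0].edge.length = D[0, 1] / 2
        nodes[1].edge.length = D[0, 1] / 2
        tree.is_rooted = False
        return tree

    dist = {(i, j): D[i, j] for i in range(n) for j in range(n) if i < j}

    def d(i, j):
        return dist[(i, j)] if i < j else dist[(j, i)]

    sizes = {i: 1 for i in active}
    next_id = n
    while len(active) > 3:
        m = len(active)
        r = {i: sum(d(i, k) for k in active if k != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * d(i, j) - r[i] - r[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        li = 0.5 * d(i, j) + (r[i] - r[j]) / (2 * (m - 2))
        lj = d(i, j) - li
        u = dendropy.Node()
        u.add_child(nodes[i])
        u.add_child(nodes[j])
        nodes[i].edge.length = max(0.0, li)
        nodes[j].edge.length = max(0.0, lj)
        nodes.append(u)
        for k in active:
            if k in (i, j):
                continue
            dist[(k, next_id) if k < next_id else (next_id, k)] = \
                0.5 * (d(i, k) + d(j, k) - d(i, j))
        active = [k for k in active if k not in (i, j)] + [next_id]
        next_id += 1

    a, b, c = active
    la = 0.5 * (d(a, b) + d(a, c) - d(b, c))
    lb = 0.5 * (d(a, b) + d(b, c) - d(a, c))
    lc = 0.5 * (d(a, c) + d(b, c) - d(a, b))
    for k, lk in ((a, la), (b, lb), (c, lc)):
        tree.seed_node.add_child(nodes[k])
        nodes[k].edge.length = max(0.0, lk)
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# Tree utilities
# ---------------------------------------------------------------------------

def parse_newick(source: str) -> dendropy.Tree:
    if "(" not in source:
        with open(source) as fh:
            source = fh.read()
    return dendropy.Tree.get(data=source, schema="newick",
                             suppress_internal_node_taxa=True,
                             preserve_underscores=True)


def write_newick(tree: dendropy.Tree, path=None) -> str:
    """Newick with bootstrap supports as internal-node labels."""
    for node in tree.preorder_node_iter():
        sup = getattr(node, "support", None)
        if sup is not None and not node.is_leaf():
            node.label = f"{sup:.3f}"
    s = tree.as_string(schema="newick", suppress_rooting=True,
                       unquoted_underscores=True)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(s)
    return s


def leaf_labels(tree) -> list[str]:
    return [l.taxon.label for l in tree.leaf_node_iter()]


def deroot(tree: dendropy.Tree) -> dendropy.Tree:
    """Collapse a bifurcating root into a trifurcating seed (unrooted form)."""
    root = tree.seed_node
    if len(root.child_nodes()) == 2:
        tree.collapse_basal_bifurcation()
    tree.is_rooted = False
    return tree


def _bipartitions(tree) -> set[frozenset]:
    leaves = frozenset(leaf_labels(tree))
    ref = min(leaves)
    n = len(leaves)
    splits = set()
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        if ref in side:
            side = leaves - side
        if 2 <= len(side) <= n - 2:
            splits.add(side)
    return splits


def robinson_foulds(t1, t2) -> int:
    """Symmetric difference of non-trivial bipartition sets."""
    if frozenset(leaf_labels(t1)) != frozenset(leaf_labels(t2)):
        raise InvalidArgumentError("trees must share a leaf set")
    return len(_bipartitions(t1) ^ _bipartitions(t2))


def tree_path_distances(tree):
    """Leaf-to-leaf path-length matrix; returns (labels, matrix)."""
    adj = {}
    for node in tree.preorder_node_iter():
        for child in node.child_nodes():
            w = child.edge.length
            if w is None:
                raise InvalidArgumentError("tree has missing branch lengths")
            adj.setdefault(node, []).append((child, w))
            adj.setdefault(child, []).append((node, w))
    leaves = sorted(tree.leaf_node_iter(), key=lambda l: l.taxon.label)
    labels = [l.taxon.label for l in leaves]
    n = len(leaves)
    D = np.zeros((n, n))
    for i, src in enumerate(leaves):
        dist = {src: 0.0}
        stack = [src]
        while stack:
            nd = stack.pop()
            for nbr, w in adj.get(nd, []):
                if nbr not in dist:
                    dist[nbr] = dist[nd] + w
                    stack.append(nbr)
        for j, dst in enumerate(leaves):
            D[i, j] = dist[dst]
    return labels, D


def midpoint_root(tree: dendropy.Tree) -> dendropy.Tree:
    """Root at the midpoint of the longest leaf-to-leaf path.

    Ties between equally long paths are broken by the lexicographically
    smallest (sorted) leaf-label pair.  The input tree is not modified.
    """
    tree = tree.clone(depth=1)
    leaves = list(tree.leaf_node_iter())
    if len(leaves) < 2:
        raise InvalidArgumentError("midpoint rooting needs >= 2 leaves")
    adj = {}
    for node in tree.preorder_node_iter():
        for child in node.child_nodes():
            w = child.edge.length
            if w is None:
                raise InvalidArgumentError("midpoint rooting requires branch lengths")
            adj.setdefault(node, []).append((child, w))
            adj.setdefault(child, []).append((node, w))

    def distances_from(src):
        dist = {src: 0.0}
        prev = {src: None}
        stack = [src]
        while stack:
            nd = stack.pop()
            for nbr, w in adj.get(nd, []):
                if nbr not in dist:
                    dist[nbr] = dist[nd] + w
                    prev[nbr] = nd
                    stack.append(nbr)
        return dist, prev

    best = None  # (-path_len impossible; use explicit compare)
    per_leaf = {}
    for src in leaves:
        per_leaf[src] = distances_from(src)
    for a in leaves:
        dist_a, _ = per_leaf[a]
        for b in leaves:
            if a.taxon.label >= b.taxon.label:
                continue
            key = (dist_a[b], a.taxon.label, b.taxon.label)
            if best is None or (key[0] > best[0] + 1e-15) or (
                abs(key[0] - best[0]) <= 1e-15 and (key[1], key[2]) < (best[1], best[2])
            ):
                best = (key[0], key[1], key[2], a, b)
    total, _, _, la, lb = best
    if total == 0:
        tree.reroot_at_node(la.parent_node or la, update_bipartitions=False)
        tree.is_rooted = True
        return tree
    dist_a, prev_a = per_leaf[la]
    # path from la to lb via predecessor links
    path = [lb]
    while path[-1] is not la:
        path.append(prev_a[path[-1]])
    path.reverse()  # la ... lb
    half = total / 2.0
    cum = 0.0
    for x, y in zip(path, path[1:]):
        w = next(w for nbr, w in adj[x] if nbr is y)
        if cum + w >= half - 1e-15:
            rem = half - cum
            break
        cum += w
    # locate parent/child orientation of edge (x, y)
    if y.parent_node is x:
        parent, child, off_parent = x, y, rem
    else:
        parent, child, off_parent = y, x, w - rem
    L = child.edge.length
    if off_parent <= 1e-12 and parent.parent_node is not None:
        new_root = parent
        tree.reroot_at_node(new_root, update_bipartitions=False)
    else:
        mid = dendropy.Node()
        parent.remove_child(child)
        parent.add_child(mid)
        mid.edge.length = off_parent
        mid.add_child(child)
        child.edge.length = L - off_parent
        tree.reroot_at_node(mid, update_bipartitions=False)
    tree.is_rooted = True
    return tree


# ---------------------------------------------------------------------------
# Tree search
# ---------------------------------------------------------------------------

@dataclass
class PhyloConfig:
    """Inference settings (bootstrap default mirrors the 1,000-replicate
    convention of the family analysis this package re-implements)."""

    bootstrap_reps: int = 1000
    nni_max_rounds: int = 20
    brlen_tolerance: float = 1e-4
    brlen_max: float = BRLEN_MAX
    candidate_models: tuple = ("LG", "LG+G4")
    seed: int = 0

    def __post_init__(self):
        if self.bootstrap_reps < 0:
            raise InvalidArgumentError("bootstrap_reps must be >= 0")
        if self.brlen_tolerance <= 0:
            raise InvalidArgumentError("brlen_tolerance must be > 0")


def _nni_candidates(tree):
    """Internal edges with their two sibling-swap moves."""
    for edge in tree.preorder_edge_iter():
        u = edge.tail_node
        v = edge.head_node
        if u is None or v.is_leaf():
            continue
        kids = v.child_nodes()
        sibs = [c for c in u.child_nodes() if c is not v]
        if len(kids) < 2 or not sibs:
            continue
        c = sibs[0]
        yield v, kids[0], u, c
        yield v, kids[1], u, c


def _swap_subtrees(v, a, u, c):
    v.remove_child(a)
    u.remove_child(c)
    v.add_child(c)
    u.add_child(a)


def optimize_tree(aln, start_tree, model: SubstModel,
                  cfg: PhyloConfig | None = None) -> dendropy.Tree:
    """NNI hill climbing with per-branch Brent optimisation.

    The accepted log-likelihood trace is non-decreasing; the search stops
    when no interchange improves the likelihood by more than the tolerance.
    """
    cfg = cfg or PhyloConfig()
    tree = deroot(start_tree.clone(depth=1))
    engine = PruningEngine(aln, model)
    for edge in tree.preorder_edge_iter():
        if edge.tail_node is not None and (edge.length is None or edge.length <= 0):
            edge.length = BRLEN_MIN
    ll = engine.optimize_branch_lengths(tree, tol=cfg.brlen_tolerance)
    for _ in range(cfg.nni_max_rounds):
        best_gain = 0.0
        best_move = None
        for move in _nni_candidates(tree):
            _swap_subtrees(*move)
            cand = engine.loglik(tree)
            _swap_subtrees(move[0], move[3], move[2], move[1])
            if cand - ll > best_gain + 1e-12:
                best_gain = cand - ll
                best_move = move
        if best_move is None or best_gain <= 10 * cfg.brlen_tolerance:
            break
        _swap_subtrees(*best_move)
        ll = engine.optimize_branch_lengths(tree, tol=cfg.brlen_tolerance)
    return tree


def select_model_bic(aln, tree, candidates=("LG", "LG+G4"),
                     cfg: PhyloConfig | None = None, full_output: bool = False):
    """Fit each candidate model (branch lengths, plus alpha for +G4) and
    return the BIC minimiser; ties go to the model with fewer parameters."""
    if not candidates:
        raise InvalidArgumentError("need at least one candidate model")
    cfg = cfg or PhyloConfig()
    data = PatternData(aln)
    n_cols = data.n_cols
    fits = []
    for cand in candidates:
        model = cand if isinstance(cand, SubstModel) else (
            SubstModel(alpha=1.0) if cand == "LG+G4" else SubstModel()
        )
        t = deroot(tree.clone(depth=1))
        for edge in t.preorder_edge_iter():
            if edge.tail_node is not None and (edge.length is None or edge.length <= 0):
                edge.length = BRLEN_MIN
        n_edges = sum(1 for e in t.preorder_edge_iter() if e.tail_node is not None)
        if model.alpha is None:
            engine = PruningEngine(data, model)
            ll = engine.optimize_branch_lengths(t, tol=cfg.brlen_tolerance)
            k = n_edges
        else:
            alpha = model.alpha
            ll = -np.inf
            for _ in range(2):
                engine = PruningEngine(data, model.with_alpha(alpha))
                ll = engine.optimize_branch_lengths(t, tol=cfg.brlen_tolerance)
                res = minimize_scalar(
                    lambda a: -PruningEngine(data, model.with_alpha(a)).loglik(t),
                    bounds=(0.05, 50.0), method="bounded",
                    options={"xatol": 1e-2},
                )
                alpha = float(res.x)
                ll = max(ll, -res.fun)
            model = model.with_alpha(alpha)
            k = n_edges + 1
        bic = k * math.log(n_cols) - 2.0 * ll
        fits.append({"model": model, "loglik": ll, "k": k, "bic": bic})
    fits.sort(key=lambda f: (round(f["bic"], 9), f["k"]))
    return (fits[0]["model"], fits) if full_output else fits[0]["model"]


def bootstrap_support(aln, tree, model: SubstModel,
                      cfg: PhyloConfig | None = None,
                      seed: int = 0) -> dendropy.Tree:
    """Nonparametric site-resampling bootstrap supports.

    Each replicate resamples alignment columns with replacement and infers
    a tree by neighbor joining on pairwise ML distances; the support of an
    internal edge is the fraction of replicate trees containing its
    bipartition.  With zero replicates the tree is returned without
    supports (absent, not zero).
    """
    cfg = cfg or PhyloConfig()
    out = tree.clone(depth=1)
    if cfg.bootstrap_reps == 0:
        return out
    ids = list(aln.ids)
    mat = np.stack([encode_sequence(aln.row(i).replace("-", "X")) for i in ids])
    n, ncols = mat.shape
    pairs = [(i, j) for i in range(n) for j in range(n) if i < j]
    joint = {}
    for i, j in pairs:
        mask = (mat[i] < 20) & (mat[j] < 20)
        joint[(i, j)] = (mat[i].astype(np.int64) * 20 + mat[j].astype(np.int64), mask)
    rng = np.random.default_rng(seed)
    counts = {}
    leaves = frozenset(ids)
    for _ in range(cfg.bootstrap_reps):
        cols = rng.integers(0, ncols, size=ncols)
        D = np.zeros((n, n))
        ok = True
        for i, j in pairs:
            code, mask = joint[(i, j)]
            sel = mask[cols]
            if not sel.any():
                ok = False
                break
            cm = np.bincount(code[cols][sel], minlength=400).reshape(20, 20).astype(float)
            D[i, j] = D[j, i] = ml_distance_from_counts(cm, model, tol=1e-4)
        if not ok:
            continue
        rep = neighbor_joining(D, ids)
        for split in _bipartitions(rep):
            counts[split] = counts.get(split, 0) + 1
    nleaf = len(ids)
    ref = min(leaves)
    for node in out.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        if ref in side:
            side = leaves - side
        if 2 <= len(side) <= nleaf - 2:
            node.support = counts.get(side, 0) / cfg.bootstrap_reps
    return out
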