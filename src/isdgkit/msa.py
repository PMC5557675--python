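"""Deterministic progressive multiple sequence alignment.

A light stand-in for the usual aligner in family workflows: pairwise
k-mer distances feed an average-linkage (UPGMA) guide tree with
lexicographic tie-breaking, and profiles are merged bottom-up by global
affine-gap profile-profile alignment under BLOSUM62.  No iterative
refinement; the goal is a valid, reproducible alignment, not parity with
any particular aligner.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
from Bio.Align import substitution_matrices

from ._dp import global_affine
from .records import (AA_INDEX, AMINO_ACIDS, InvalidArgumentError,
                      ProteinRecord, check_unique_ids)

_B62 = None


def blosum62() -> np.ndarray:
    """BLOSUM62 as a dense 20x20 array in canonical residue order."""
    global _B62
    if _B62 is None:
        m = substitution_matrices.load("BLOSUM62")
        out = np.zeros((20, 20))
        for i, a in enumerate(AMINO_ACIDS):
            for j, b in enumerate(AMINO_ACIDS):
                out[i, j] = m[a, b]
        _B62 = out
    return _B62


@dataclass
class AlignParams:
    matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    kmer_k: int = 3

    def __post_init__(self):
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise InvalidArgumentError("gap penalties must be > 0")
        if self.kmer_k < 1:
            raise InvalidArgumentError("k-mer size must be >= 1")


class Alignment:
    """Rectangular gapped alignment keyed by record id.

    Rows are strings over residues plus ``-``; ``.`` is accepted on input
    and normalised to ``-``; all-gap columns are stripped on construction.
    """

    def __init__(self, rows: dict[str, str] | list[tuple[str, str]]):
        items = list(rows.items()) if isinstance(rows, dict) else list(rows)
        if not items:
            raise InvalidArgumentError("alignment must have at least one row")
        ids = [rid for rid, _ in items]
        if len(set(ids)) != len(ids):
            raise InvalidArgumentError("duplicate row ids in alignment")
        seqs = [s.upper().replace(".", "-") for _, s in items]
        ncol = len(seqs[0])
        if any(len(s) != ncol for s in seqs):
            raise InvalidArgumentError("alignment rows differ in length")
        keep = [c for c in range(ncol)
                if any(s[c] != "-" for s in seqs)]
        if len(keep) != ncol:
            seqs = ["".join(s[c] for c in keep) for s in seqs]
        self.ids = ids
        self._rows = dict(zip(ids, seqs))
        self.n_cols = len(keep)

    def __len__(self):
        return len(self.ids)

    def row(self, rid: str) -> str:
        return self._rows[rid]

    def ungapped(self, rid: str) -> str:
        return self._rows[rid].replace("-", "")

    def items(self):
        return [(rid, self._rows[rid]) for rid in self.ids]

    def subset(self, ids) -> "Alignment":
        return Alignment([(rid, self._rows[rid]) for rid in ids])

    @classmethod
    def from_fasta(cls, path) -> "Alignment":
        from Bio import SeqIO
        return cls([(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")])

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for rid in self.ids:
                fh.write(f">{rid}\n")
                s = self._rows[rid]
                for i in range(0, len(s), 60):
                    fh.write(s[i:i + 60] + "\n")


# ---------------------------------------------------------------------------
# Guide tree
# ---------------------------------------------------------------------------

def _kmer_counts(seq: str, k: int) -> dict[str, int]:
    out: dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        w = seq[i:i + k]
        out[w] = out.get(w, 0) + 1
    return out


def kmer_distance(a: str, b: str, k: int = 3) -> float:
    """1 - (shared k-mer count / smaller total k-mer count), in [0, 1]."""
    ca, cb = _kmer_counts(a, k), _kmer_counts(b, k)
    ta, tb = sum(ca.values()), sum(cb.values())
    if min(ta, tb) == 0:
        return 1.0
    shared = sum(min(n, cb.get(w, 0)) for w, n in ca.items())
    return 1.0 - shared / min(ta, tb)


def kmer_guide_tree(records, params: AlignParams | None = None) -> dendropy.Tree:
    """Average-linkage (UPGMA) guide tree on k-mer distances.

    Deterministic: equal merge heights are resolved by the
    lexicographically smallest pair of cluster representative ids.
    """
    params = params or AlignParams()
    records = list(records)
    if len(records) < 2:
        raise InvalidArgumentError("guide tree needs >= 2 records")
    seqs = {r.id: r.sequence for r in records}
    check_unique_ids(records)
    taxa = dendropy.TaxonNamespace(sorted(seqs))
    clusters = []
    for r in records:
        nd = dendropy.Node(taxon=taxa.get_taxon(r.id))
        clusters.append({"rep": r.id, "node": nd, "size": 1, "height": 0.0})
    dmat = {}
    for i in range(len(clusters)):
        for j in range(i + 1, len(clusters)):
            a, b = clusters[i]["rep"], clusters[j]["rep"]
            dmat[frozenset((a, b))] = kmer_distance(seqs[a], seqs[b], params.kmer_k)

    def dist(ci, cj):
        return dmat[frozenset((ci["rep"], cj["rep"]))]

    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                dij = dist(clusters[i], clusters[j])
                pair = tuple(sorted((clusters[i]["rep"], clusters[j]["rep"])))
                key = (dij, pair)
                if best is None or key < best[0]:
                    best = (key, i, j)
        (_, _), i, j = best[0], best[1], best[2]
        ci, cj = clusters[i], clusters[j]
        h = dist(ci, cj) / 2.0
        parent = dendropy.Node()
        first, second = sorted((ci, cj), key=lambda c: c["rep"])
        for child in (first, second):
            parent.add_child(child["node"])
            child["node"].edge.length = max(0.0, h - child["height"])
        merged = {
            "rep": min(ci["rep"], cj["rep"]),
            "node": parent, "size": ci["size"] + cj["size"], "height": h,
        }
        rest = [c for k, c in enumerate(clusters) if k not in (i, j)]
        for c in rest:
            dnew = (ci["size"] * dist(ci, c) + cj["size"] * dist(cj, c)) / merged["size"]
            dmat[frozenset((merged["rep"], c["rep"]))] = dnew
        clusters = rest + [merged]
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = clusters[0]["node"]
    tree.is_rooted = True
    return tree


# ---------------------------------------------------------------------------
# Profile-profile alignment
# ---------------------------------------------------------------------------

def _profile(rows: list[str]) -> np.ndarray:
    """Per-column residue frequencies (L, 20); gaps and X contribute zero."""
    L = len(rows[0])
    F = np.zeros((L, 20))
    for s in rows:
        for c, ch in enumerate(s):
            idx = AA_INDEX.get(ch)
            if idx is not None:
                F[c, idx] += 1.0
    return F / len(rows)


def _merge(rows_a: list[str], rows_b: list[str], params: AlignParams):
    Fa, Fb = _profile(rows_a), _profile(rows_b)
    M = Fa @ blosum62() @ Fb.T
    score, ops = global_affine(M, params.gap_open, params.gap_extend)
    out_a, out_b = [], []
    for s in rows_a:
        it = iter(s)
        out_a.append("".join("-" if op == 1 else next(it) for op in ops))
    for s in rows_b:
        it = iter(s)
        out_b.append("".join("-" if op == 2 else next(it) for op in ops))
    return out_a, out_b, float(score)


def pairwise_global(a: str, b: str, params: AlignParams | None = None):
    """Global affine-gap alignment of two (possibly gapped) sequences.

    Returns (aligned_a, aligned_b, score).  Ties prefer a match column
    over a gap in the first input over a gap in the second.
    """
    params = params or AlignParams()
    if not a or not b:
        raise InvalidArgumentError("cannot align an empty sequence")
    (aa,), (bb,), score = _merge([a], [b], params)
    return aa, bb, score


def progressive_align(records, params: AlignParams | None = None) -> Alignment:
    """Align records along the guide tree; output row order = input order."""
    params = params or AlignParams()
    records = list(records)
    if len(records) < 2:
        raise InvalidArgumentError("progressive alignment needs >= 2 records")
    check_unique_ids(records)
    guide = kmer_guide_tree(records, params)
    blocks = {}
    for node in guide.postorder_node_iter():
        if node.is_leaf():
            rid = node.taxon.label
            seq = next(r.sequence for r in records if r.id == rid)
            blocks[node] = ([rid], [seq])
        else:
            kids = node.child_nodes()
            ids, rows = blocks.pop(kids[0])
            for child in kids[1:]:
                ids_b, rows_b = blocks.pop(child)
                rows, rows_b, _ = _merge(rows, rows_b, params)
                ids = ids + ids_b
                rows = rows + rows_b
            blocks[node] = (ids, rows)
    ids, rows = blocks[guide.seed_node]
    table = dict(zip(ids, rows))
    return Alignment([(r.id, table[r.id]) for r in records])
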