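"""Synthetic IsdG-like protein families with known ground truth.

The generator emulates the features of the real family that the pipeline
must cope with: ~100-residue ABM-like domains evolved along a known tree
under LG with gamma rate variation; a conserved N/W/H catalytic triad plus
F/G/W auxiliary residues, degraded in a planted subset of taxa; a
low-complexity S/G/H-rich insert carried by one clade (the single indel
event, so true site homology is known everywhere); tandem two-domain
fusion proteins; near-duplicate redundant entries; and unrelated decoy
sequences drawn from background composition.

Coordinates: planted positions are 1-based on the insert-bearing ancestral
sequence (length ``domain_length + insert_length``); taxa outside the
insert clade lack the insert block, mirroring a reference whose printed
residue numbers include its unstructured insert.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import dendropy
import numpy as np

from .phylogeny import SubstModel, parse_newick, write_newick
from .records import (AMINO_ACIDS, InvalidArgumentError, ProteinRecord,
                      read_fasta, read_taxonomy, write_fasta, write_taxonomy)

TRIAD_RESIDUES = "NWH"
AUX_RESIDUES = "FGW"
LINKER = "GGSGGS"

_TAXA_LABELS = [
    ("Bacteria", "Actinobacteria"),
    ("Bacteria", "Proteobacteria"),
    ("Bacteria", "Firmicutes"),
    ("Archaea", "Euryarchaeota"),
    ("Eukaryota", "Chlorophyta"),
    ("Bacteria", "Bacteroidetes"),
    ("Bacteria", "Cyanobacteria"),
    ("Archaea", "Crenarchaeota"),
]


@dataclass
class SimConfig:
    """Study conditions for one synthetic family.

    Defaults give a 16-taxon family of 100-residue domains, a 45-residue
    S/G/H-rich insert in one small clade, a quarter of the taxa with a
    degraded triad, and a modest load of decoys, duplicates and fusions.
    """

    n_taxa: int = 16
    domain_length: int = 100
    insert_clade: tuple[str, ...] | None = None   # None = auto-pick a clade; () = no insert
    insert_length: int = 45
    insert_start: int = 60
    triad_positions: tuple[int, int, int] = (41, 120, 130)
    aux_positions: tuple[int, int, int] = (30, 50, 115)
    degraded_fraction: float = 0.25
    n_decoys: int = 8
    n_duplicates: int = 2
    n_fusions: int = 2
    decoy_bias: float = 0.0   # extra mass on alanine in decoy composition
    branch_scale: float = 0.25
    alpha: float | None = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_taxa < 2:
            raise InvalidArgumentError("n_taxa must be >= 2")
        for name in ("domain_length", "insert_length", "n_decoys",
                     "n_duplicates", "n_fusions"):
            if getattr(self, name) < 0:
                raise InvalidArgumentError(f"{name} must be >= 0")
        if not (0.0 <= self.degraded_fraction <= 1.0):
            raise InvalidArgumentError("degraded_fraction must be in [0, 1]")
        if self.alpha is not None and self.alpha <= 0:
            raise InvalidArgumentError("alpha must be > 0")
        if not (0.0 <= self.decoy_bias < 1.0):
            raise InvalidArgumentError("decoy_bias must be in [0, 1)")
        positions = tuple(self.triad_positions) + tuple(self.aux_positions)
        if len(set(positions)) != len(positions):
            raise InvalidArgumentError("triad/aux positions must be distinct")
        full = self.full_length
        for p in positions:
            if not (1 <= p <= full):
                raise InvalidArgumentError(
                    f"planted position {p} outside sequence (1..{full})"
                )
            if self.has_insert and self.insert_start < p <= self.insert_start + self.insert_length:
                raise InvalidArgumentError(
                    f"planted position {p} collides with the insert span "
                    f"({self.insert_start + 1}..{self.insert_start + self.insert_length})"
                )
        if self.has_insert and not (0 <= self.insert_start <= self.full_length - self.insert_length):
            raise InvalidArgumentError("insert_start outside the ancestral sequence")

    @property
    def has_insert(self) -> bool:
        return self.insert_clade != () and self.insert_length > 0

    @property
    def full_length(self) -> int:
        """Length of the insert-bearing ancestral sequence."""
        return self.domain_length + (self.insert_length if self.has_insert else 0)


@dataclass
class TruthRecord:
    """Ground truth for one simulated dataset."""

    true_tree: dendropy.Tree
    triad_status: dict[str, int]
    fusion_registry: list[tuple[str, tuple[str, str], int]]
    duplicate_clusters: dict[str, list[str]]
    taxonomy_assignment: dict[str, tuple[str, str]]
    decoy_ids: list[str] = field(default_factory=list)
    degraded_ids: list[str] = field(default_factory=list)
    insert_clade_ids: list[str] = field(default_factory=list)
    site_maps: dict[str, np.ndarray] = field(default_factory=dict)
    root_sequence: str = ""
    triad_sites: tuple[int, ...] = ()
    aux_sites: tuple[int, ...] = ()

    @property
    def family_ids(self) -> list[str]:
        return list(self.triad_status)


# ---------------------------------------------------------------------------
# Tree simulation
# ---------------------------------------------------------------------------

def sample_tree(n_taxa: int, branch_scale: float = 0.25, seed: int = 0) -> dendropy.Tree:
    """Random binary rooted tree with gamma-distributed branch lengths.

    Branch lengths are Gamma(shape 2, mean ``branch_scale``) substitutions
    per site, so doubling ``branch_scale`` doubles the expected length of
    every branch (and hence of every root-to-leaf path).
    """
    if n_taxa < 2:
        raise InvalidArgumentError("n_taxa must be >= 2")
    if branch_scale <= 0:
        raise InvalidArgumentError("branch_scale must be > 0")
    rng = np.random.default_rng(seed)
    width = max(2, len(str(n_taxa)))
    labels = [f"T{i + 1:0{width}d}" for i in range(n_taxa)]
    taxa = dendropy.TaxonNamespace(labels)
    nodes = [dendropy.Node(taxon=taxa.get_taxon(l)) for l in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = dendropy.Node()
        for child in (nodes[i], nodes[j]):
            parent.add_child(child)
            child.edge.length = float(rng.gamma(2.0, branch_scale / 2.0)) + 1e-6
        nodes = [nd for k, nd in enumerate(nodes) if k not in (i, j)] + [parent]
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = nodes[0]
    tree.is_rooted = True
    return tree


# ---------------------------------------------------------------------------
# Sequence evolution
# ---------------------------------------------------------------------------

def _auto_insert_clade(tree, n_taxa: int) -> list[str]:
    """Pick a small clade (about n/8 leaves, at least 2) for the insert."""
    target = max(2, round(n_taxa / 8))
    best = None
    for node in tree.postorder_internal_node_iter():
        leaves = [l.taxon.label for l in node.leaf_iter()]
        if len(leaves) >= n_taxa:
            continue
        key = abs(len(leaves) - target)
        if best is None or key < best[0]:
            best = (key, leaves)
    return best[1] if best else []


def _assign_taxonomy(tree, min_groups: int = 5) -> dict[str, tuple[str, str]]:
    """Split the tree into a handful of clades and label them."""
    groups = [tree.seed_node]
    while len(groups) < min_groups:
        groups.sort(key=lambda nd: -len(nd.leaf_nodes()))
        big = groups[0]
        kids = big.child_nodes()
        if not kids:
            break
        groups = groups[1:] + list(kids)
    groups.sort(key=lambda nd: min(l.taxon.label for l in nd.leaf_iter()))
    out = {}
    for g, node in enumerate(groups):
        label = _TAXA_LABELS[g % len(_TAXA_LABELS)]
        for leaf in node.leaf_iter():
            out[leaf.taxon.label] = label
    return out


def _sample_states(rng, model, parent_codes, t, rates):
    """Draw child states given parent states along a branch (vectorised)."""
    S = len(parent_codes)
    child = parent_codes.copy()
    live = rates * t > 0
    if not live.any():
        return child
    idx = np.nonzero(live)[0]
    E = np.exp(model._lam[None, :] * (t * rates[idx][:, None]))  # (s, 20)
    rows = (model._left[parent_codes[idx]] * E) @ model._right    # (s, 20)
    rows = np.maximum(rows, 0.0)
    rows /= rows.sum(axis=1, keepdims=True)
    u = rng.random(len(idx))
    child[idx] = (rows.cumsum(axis=1) < u[:, None]).sum(axis=1).clip(0, 19)
    return child


def evolve_family(tree: dendropy.Tree, cfg: SimConfig):
    """Evolve a family along ``tree``; returns (records, truth).

    The root sequence is drawn from LG stationary frequencies with the
    triad/aux residues forced at their planted positions and an S/G/H-rich
    insert block; planted sites are invariant except on branches whose
    entire descendant set is degraded, and the insert is treated as a
    compositionally conserved low-complexity segment (rate zero).
    """
    leaves = [l.taxon.label for l in tree.leaf_node_iter()]
    if len(leaves) != cfg.n_taxa:
        raise InvalidArgumentError("tree leaf count does not match cfg.n_taxa")
    rng = np.random.default_rng([cfg.seed, 1])
    model = SubstModel()  # base LG; gamma handled via per-site rates
    L = cfg.full_length
    pi = model.stationary

    if cfg.insert_clade is None:
        insert_ids = _auto_insert_clade(tree, cfg.n_taxa) if cfg.has_insert else []
    else:
        insert_ids = list(cfg.insert_clade)
        unknown = set(insert_ids) - set(leaves)
        if unknown:
            raise InvalidArgumentError(f"insert_clade ids not in tree: {sorted(unknown)}")
    insert_sites = (set(range(cfg.insert_start, cfg.insert_start + cfg.insert_length))
                    if (cfg.has_insert and insert_ids) else set())

    planted = [(p - 1, r) for p, r in
               list(zip(cfg.triad_positions, TRIAD_RESIDUES)) +
               list(zip(cfg.aux_positions, AUX_RESIDUES))]
    planted_sites = {s for s, _ in planted}

    n_degraded = int(round(cfg.degraded_fraction * cfg.n_taxa))
    degraded = ({str(x) for x in rng.choice(sorted(leaves), size=n_degraded,
                                            replace=False)}
                if n_degraded else set())

    # per-site rates
    if cfg.alpha is not None:
        rates = rng.gamma(cfg.alpha, 1.0 / cfg.alpha, size=L)
    else:
        rates = np.ones(L)
    frozen = np.zeros(L, bool)
    for s in insert_sites:
        frozen[s] = True

    # root sequence
    root = rng.choice(20, size=L, p=pi)
    for s, res in planted:
        root[s] = AMINO_ACIDS.index(res)
    if insert_sites:
        ins = sorted(insert_sites)
        n_sgh = int(np.ceil(0.75 * len(ins)))
        sgh_codes = [AMINO_ACIDS.index(c) for c in "SGH"]
        block = np.concatenate([
            rng.choice(sgh_codes, size=n_sgh),
            rng.choice(20, size=len(ins) - n_sgh, p=pi),
        ])
        root[ins] = rng.permutation(block)

    # evolve: planted sites move only on branches whose whole subtree is degraded
    seqs = {}
    states = {tree.seed_node: root}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        sub_leaves = {l.taxon.label for l in node.leaf_iter()}
        branch_rates = rates.copy()
        branch_rates[frozen] = 0.0
        if not sub_leaves <= degraded:
            for s in planted_sites:
                branch_rates[s] = 0.0
        states[node] = _sample_states(
            rng, model, states[node.parent_node], node.edge.length or 0.0,
            branch_rates,
        )
        if node.is_leaf():
            seqs[node.taxon.label] = states[node]

    taxonomy = _assign_taxonomy(tree)
    full_coords = np.arange(1, L + 1)
    records = []
    site_maps = {}
    triad_status = {}
    triad_codes = [AMINO_ACIDS.index(c) for c in TRIAD_RESIDUES]
    for lab in leaves:
        codes = seqs[lab]
        keep = np.ones(L, bool)
        if insert_sites and lab not in insert_ids:
            keep[sorted(insert_sites)] = False
        seq = "".join(AMINO_ACIDS[c] for c in codes[keep])
        site_maps[lab] = full_coords[keep]
        triad_status[lab] = sum(
            int(codes[p - 1] == code)
            for p, code in zip(cfg.triad_positions, triad_codes)
        )
        records.append(ProteinRecord(id=lab, sequence=seq, taxonomy=taxonomy[lab],
                                     provenance="database"))
    truth = TruthRecord(
        true_tree=tree,
        triad_status=triad_status,
        fusion_registry=[],
        duplicate_clusters={},
        taxonomy_assignment=dict(taxonomy),
        degraded_ids=sorted(degraded),
        insert_clade_ids=sorted(insert_ids),
        site_maps=site_maps,
        root_sequence="".join(AMINO_ACIDS[c] for c in root),
        triad_sites=tuple(cfg.triad_positions),
        aux_sites=tuple(cfg.aux_positions),
    )
    return records, truth


# ---------------------------------------------------------------------------
# Confounders
# ---------------------------------------------------------------------------

def add_confounders(records, truth: TruthRecord, cfg: SimConfig):
    """Append decoys, near-duplicates and tandem fusions; update truth."""
    records = list(records)
    if not records:
        raise InvalidArgumentError("records must be non-empty")
    family = [r for r in records if r.id in truth.triad_status]
    if cfg.n_fusions > 0 and len(family) < 2:
        raise InvalidArgumentError("fusions need at least 2 family records")
    rng = np.random.default_rng([cfg.seed, 2])
    model = SubstModel()
    pi = model.stationary
    out = list(records)
    taxonomy = dict(truth.taxonomy_assignment)

    decoy_freqs = pi.copy()
    if cfg.decoy_bias > 0:
        decoy_freqs = (1 - cfg.decoy_bias) * pi
        decoy_freqs[AMINO_ACIDS.index("A")] += cfg.decoy_bias
    lo, hi = int(0.5 * cfg.domain_length), int(1.5 * cfg.domain_length)
    decoy_ids = []
    for i in range(cfg.n_decoys):
        n = int(rng.integers(lo, hi + 1))
        seq = "".join(AMINO_ACIDS[c] for c in rng.choice(20, size=n, p=decoy_freqs))
        rid = f"decoy_{i + 1:02d}"
        tax = _TAXA_LABELS[i % len(_TAXA_LABELS)]
        out.append(ProteinRecord(id=rid, sequence=seq, taxonomy=tax,
                                 provenance="synthetic"))
        taxonomy[rid] = tax
        decoy_ids.append(rid)

    clusters: dict[str, list[str]] = {}
    for i in range(cfg.n_duplicates):
        src = family[int(rng.integers(len(family)))]
        L = len(src.sequence)
        max_k = int(0.02 * L)
        k = int(rng.integers(1, max_k + 1)) if max_k >= 1 else 0
        seq = list(src.sequence)
        for p in rng.choice(L, size=k, replace=False):
            choices = [c for c in AMINO_ACIDS if c != seq[p]]
            seq[p] = choices[int(rng.integers(len(choices)))]
        rid = f"{src.id}_dup{i + 1}"
        out.append(ProteinRecord(id=rid, sequence="".join(seq),
                                 taxonomy=src.taxonomy, provenance="synthetic"))
        taxonomy[rid] = src.taxonomy
        clusters.setdefault(src.id, []).append(rid)

    registry = []
    for i in range(cfg.n_fusions):
        ia, ib = rng.choice(len(family), size=2, replace=False)
        a, b = family[int(ia)], family[int(ib)]
        rid = f"fusion_{i + 1:02d}"
        seq = a.sequence + LINKER + b.sequence
        tax = ("Eukaryota", a.taxonomy[1] if a.taxonomy else "Chlorophyta")
        out.append(ProteinRecord(id=rid, sequence=seq, taxonomy=tax,
                                 provenance="synthetic"))
        taxonomy[rid] = tax
        registry.append((rid, (a.id, b.id), len(a.sequence)))

    truth = replace(
        truth,
        decoy_ids=truth.decoy_ids + decoy_ids,
        duplicate_clusters={**truth.duplicate_clusters, **clusters},
        fusion_registry=truth.fusion_registry + registry,
        taxonomy_assignment=taxonomy,
    )
    return out, truth


def simulate_dataset(cfg: SimConfig):
    """Tree + family + confounders in one call; returns (records, truth)."""
    tree = sample_tree(cfg.n_taxa, cfg.branch_scale, seed=cfg.seed)
    records, truth = evolve_family(tree, cfg)
    return add_confounders(records, truth, cfg)


# ---------------------------------------------------------------------------
# Fixture I/O
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_fixture(records, truth: TruthRecord, out_dir) -> dict:
    """Write FASTA + taxonomy TSV + Newick + truth table + manifest.

    The truth table is a line-oriented tab-separated key-value format;
    every line starts with a section keyword (documented in the header).
    """
    records = list(records)
    if not records:
        raise InvalidArgumentError("cannot write an empty fixture")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(records, out / "sequences.fasta")
    write_taxonomy({r.id: r.taxonomy for r in records if r.taxonomy},
                   out / "taxonomy.tsv")
    write_newick(truth.true_tree, out / "true_tree.nwk")
    with open(out / "truth.tsv", "w") as fh:
        fh.write("# synthetic-family ground truth; tab-separated sections:\n")
        fh.write("# root_sequence/triad_sites/aux_sites; triad_status id n;\n")
        fh.write("# degraded id; insert_clade id; decoy id; duplicate src dup;\n")
        fh.write("# fusion id compA compB junction; site_map id csv-coords\n")
        fh.write(f"root_sequence\t{truth.root_sequence}\n")
        fh.write("triad_sites\t" + ",".join(map(str, truth.triad_sites)) + "\n")
        fh.write("aux_sites\t" + ",".join(map(str, truth.aux_sites)) + "\n")
        for rid, n in truth.triad_status.items():
            fh.write(f"triad_status\t{rid}\t{n}\n")
        for rid in truth.degraded_ids:
            fh.write(f"degraded\t{rid}\n")
        for rid in truth.insert_clade_ids:
            fh.write(f"insert_clade\t{rid}\n")
        for rid in truth.decoy_ids:
            fh.write(f"decoy\t{rid}\n")
        for src, dups in truth.duplicate_clusters.items():
            for d in dups:
                fh.write(f"duplicate\t{src}\t{d}\n")
        for fid, (a, b), junction in truth.fusion_registry:
            fh.write(f"fusion\t{fid}\t{a}\t{b}\t{junction}\n")
        for rid, coords in truth.site_maps.items():
            fh.write(f"site_map\t{rid}\t" + ",".join(map(str, coords)) + "\n")
    manifest = {
        "n_records": len(records),
        "files": {p.name: _sha256(p) for p in sorted(out.iterdir())
                  if p.name != "manifest.json"},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def read_fixture(in_dir):
    """Round-trip reader for :func:`write_fixture` output."""
    src = Path(in_dir)
    taxonomy = read_taxonomy(src / "taxonomy.tsv")
    records = read_fasta(src / "sequences.fasta", taxonomy=taxonomy)
    tree = parse_newick(str(src / "true_tree.nwk"))
    triad_status, degraded, insert_ids, decoys = {}, [], [], []
    dup_clusters: dict[str, list[str]] = {}
    fusions = []
    site_maps = {}
    root_seq = ""
    triad_sites = aux_sites = ()
    with open(src / "truth.tsv") as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            tag = parts[0]
            if tag == "root_sequence":
                root_seq = parts[1]
            elif tag == "triad_sites":
                triad_sites = tuple(int(x) for x in parts[1].split(","))
            elif tag == "aux_sites":
                aux_sites = tuple(int(x) for x in parts[1].split(","))
            elif tag == "triad_status":
                triad_status[parts[1]] = int(parts[2])
            elif tag == "degraded":
                degraded.append(parts[1])
            elif tag == "insert_clade":
                insert_ids.append(parts[1])
            elif tag == "decoy":
                decoys.append(parts[1])
            elif tag == "duplicate":
                dup_clusters.setdefault(parts[1], []).append(parts[2])
            elif tag == "fusion":
                fusions.append((parts[1], (parts[2], parts[3]), int(parts[4])))
            elif tag == "site_map":
                site_maps[parts[1]] = np.array([int(x) for x in parts[2].split(",")])
    truth = TruthRecord(
        true_tree=tree, triad_status=triad_status, fusion_registry=fusions,
        duplicate_clusters=dup_clusters,
        taxonomy_assignment=dict(taxonomy),
        decoy_ids=decoys, degraded_ids=degraded, insert_clade_ids=insert_ids,
        site_maps=site_maps, root_sequence=root_seq,
        triad_sites=triad_sites, aux_sites=aux_sites,
    )
    return records, truth
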