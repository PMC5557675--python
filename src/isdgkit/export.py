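"""Tree annotation exports and the end-to-end pipeline.

Produces the deliverables of a family-expansion analysis: a
midpoint-rooted Newick tree with bootstrap supports, two iTOL
``DATASET_COLORSTRIP`` annotation files (taxonomy inner strip,
conserved-catalytic-residue count outer strip), a per-division summary
table, and a JSON run manifest that makes the whole run reproducible from
(inputs, config, seed).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .curation import CurationConfig, curate
from .msa import Alignment, AlignParams, progressive_align
from .phylogeny import (PhyloConfig, bootstrap_support, deroot,
                        distance_matrix, midpoint_root, neighbor_joining,
                        optimize_tree, select_model_bic, write_newick)
from .records import InvalidArgumentError, ProteinRecord, read_fasta, read_taxonomy
from .search import (SearchConfig, build_profile, search_database,
                     write_domains_tsv, write_hits_tsv)
from .simulate import (AUX_RESIDUES, TRIAD_RESIDUES, SimConfig, simulate_dataset,
                       write_fixture)
from .triad import TriadSpec, annotate_records, write_annotations_tsv

__version__ = "0.1.0"


class MissingAnnotationError(InvalidArgumentError):
    """A tree leaf has no category in an annotation dataset."""


# Fixed palettes: deterministic output across runs.
TAXONOMY_PALETTE = {
    ("Bacteria", "Actinobacteria"): "#1b9e77",
    ("Bacteria", "Proteobacteria"): "#d95f02",
    ("Bacteria", "Firmicutes"): "#7570b3",
    ("Bacteria", "Bacteroidetes"): "#e7298a",
    ("Bacteria", "Cyanobacteria"): "#66a61e",
    ("Archaea", "Euryarchaeota"): "#e6ab02",
    ("Archaea", "Crenarchaeota"): "#a6761d",
    ("Eukaryota", "Chlorophyta"): "#666666",
}
_FALLBACK_COLORS = ["#8dd3c7", "#bebada", "#fb8072", "#80b1d3",
                    "#fdb462", "#b3de69", "#fccde5", "#d9d9d9"]

# Outer strip always carries the 4 possible conserved-residue counts.
TRIAD_PALETTE = {"0": "#d73027", "1": "#fc8d59", "2": "#fee090", "3": "#4575b4"}


@dataclass
class AnnotationDataset:
    label: str
    categories: dict[str, str]          # leaf id -> category
    colors: dict[str, str]              # category -> #rrggbb
    strip_index: int = 0                # 0 = inner, 1 = outer


def taxonomy_dataset(taxonomy: dict[str, tuple[str, str]]) -> AnnotationDataset:
    categories = {rid: f"{dom}|{div}" for rid, (dom, div) in taxonomy.items()}
    colors = {}
    extra = 0
    for rid, (dom, div) in sorted(taxonomy.items()):
        cat = f"{dom}|{div}"
        if cat not in colors:
            col = TAXONOMY_PALETTE.get((dom, div))
            if col is None:
                col = _FALLBACK_COLORS[extra % len(_FALLBACK_COLORS)]
                extra += 1
            colors[cat] = col
    return AnnotationDataset("taxonomy", categories, colors, strip_index=0)


def triad_dataset(annotations) -> AnnotationDataset:
    categories = {rid: str(a.catalytic_count) for rid, a in annotations.items()}
    return AnnotationDataset("conserved_catalytic_residues", categories,
                             dict(TRIAD_PALETTE), strip_index=1)


def write_colorstrip(tree, dataset: AnnotationDataset, out_path) -> None:
    """iTOL DATASET_COLORSTRIP file covering every tree leaf."""
    leaves = [l.taxon.label for l in tree.leaf_node_iter()]
    for leaf in leaves:
        if leaf not in dataset.categories:
            raise MissingAnnotationError(
                f"leaf {leaf!r} has no category in dataset {dataset.label!r}")
    for cat, col in dataset.colors.items():
        if not (col.startswith("#") and len(col) == 7):
            raise InvalidArgumentError(f"bad color {col!r} for {cat!r}")
    lines = [
        "DATASET_COLORSTRIP",
        "SEPARATOR TAB",
        f"DATASET_LABEL\t{dataset.label}",
        f"COLOR\t{next(iter(dataset.colors.values()))}",
        "LEGEND_TITLE\t" + dataset.label,
        "LEGEND_LABELS\t" + "\t".join(sorted(dataset.colors)),
        "LEGEND_COLORS\t" + "\t".join(dataset.colors[c]
                                      for c in sorted(dataset.colors)),
        "DATA",
    ]
    for leaf in leaves:
        cat = dataset.categories[leaf]
        lines.append(f"{leaf}\t{dataset.colors[cat]}\t{cat}")
    Path(out_path).write_text("\n".join(lines) + "\n")


def read_colorstrip(path):
    """Parse a colorstrip file back into (label, {leaf: (color, category)})."""
    label = None
    data = {}
    in_data = False
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        if line.startswith("DATASET_LABEL"):
            label = line.split("\t", 1)[1]
        elif line == "DATA":
            in_data = True
        elif in_data:
            leaf, color, cat = line.split("\t")
            data[leaf] = (color, cat)
    return label, data


def summarize_taxonomy(annotations, taxonomy) -> pd.DataFrame:
    """Counts of homologs and triad classes per (domain, division)."""
    rows = {}
    for rid, ann in annotations.items():
        if rid not in taxonomy:
            raise InvalidArgumentError(f"record {rid!r} has no taxonomy labels")
        key = taxonomy[rid]
        row = rows.setdefault(key, {"total": 0, "isdg_like": 0,
                                    "triad_0": 0, "triad_1": 0, "triad_2": 0})
        row["total"] += 1
        if ann.is_isdg_like:
            row["isdg_like"] += 1
        else:
            row[f"triad_{ann.catalytic_count}"] += 1
    out = pd.DataFrame(
        [{"domain": dom, "division": div, **vals}
         for (dom, div), vals in sorted(rows.items())],
        columns=["domain", "division", "total", "isdg_like",
                 "triad_0", "triad_1", "triad_2"],
    )
    return out


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """End-to-end run configuration.

    Either a ``simulate`` block (synthetic family with ground truth) or
    ``input_fasta`` + ``input_taxonomy`` paths must be provided.
    """

    out_dir: str = "isdgkit_run"
    seed: int = 0
    simulate: SimConfig | None = None
    input_fasta: str | None = None
    input_taxonomy: str | None = None
    seed_ids: tuple[str, ...] | None = None
    n_seed_sequences: int = 6
    search: SearchConfig = field(default_factory=SearchConfig)
    curation: CurationConfig = field(default_factory=CurationConfig)
    align: AlignParams = field(default_factory=AlignParams)
    triad: TriadSpec | None = None       # auto-derived in simulate mode
    phylo: PhyloConfig = field(default_factory=PhyloConfig)
    run_full_ml: bool = True
    restrict_to_isdg_like: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kw = {}
        for key, val in raw.items():
            if key == "simulate":
                kw[key] = SimConfig(**val) if val else None
            elif key == "search":
                kw[key] = SearchConfig(**val)
            elif key == "curation":
                kw[key] = CurationConfig(**val)
            elif key == "align":
                kw[key] = AlignParams(**val)
            elif key == "phylo":
                kw[key] = PhyloConfig(**val)
            elif key == "triad":
                val = dict(val)
                for f in ("catalytic", "auxiliary"):
                    if f in val:
                        val[f] = tuple((int(p), str(r)) for p, r in val[f])
                kw[key] = TriadSpec(**val)
            else:
                kw[key] = val
        return cls(**kw)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _pick_seed_records(records, truth, config):
    if config.seed_ids:
        wanted = list(config.seed_ids)
    elif truth is not None:
        fam = [l.taxon.label for l in truth.true_tree.leaf_node_iter()]
        k = min(config.n_seed_sequences, len(fam))
        idx = np.linspace(0, len(fam) - 1, k).round().astype(int)
        wanted = [fam[i] for i in sorted(set(idx))]
    else:
        wanted = [r.id for r in records[:config.n_seed_sequences]]
    by_id = {r.id: r for r in records}
    missing = [w for w in wanted if w not in by_id]
    if missing:
        raise InvalidArgumentError(f"seed ids not in database: {missing}")
    return [by_id[w].with_(provenance="seed") for w in wanted]


def _auto_triad_spec(truth, curated_ids, cfg: SimConfig) -> TriadSpec:
    """Reference-anchored spec from simulator ground truth.

    Picks the first intact, insert-free family member that survived
    curation and converts the planted full-sequence positions to that
    record's own residue numbering via the truth site map.
    """
    candidates = [rid for rid in truth.triad_status
                  if rid in curated_ids
                  and rid not in truth.degraded_ids
                  and rid not in truth.insert_clade_ids
                  and truth.triad_status[rid] == 3]
    if not candidates:
        candidates = [rid for rid in truth.triad_status if rid in curated_ids]
    if not candidates:
        raise InvalidArgumentError("no curated family member available as "
                                   "triad reference")
    ref = sorted(candidates)[0]
    coords = list(truth.site_maps[ref])
    local = {full: i + 1 for i, full in enumerate(coords)}
    catalytic = tuple((local[p], r) for p, r in
                      zip(truth.triad_sites, TRIAD_RESIDUES))
    auxiliary = tuple((local[p], r) for p, r in
                      zip(truth.aux_sites, AUX_RESIDUES))
    return TriadSpec(reference_id=ref, catalytic=catalytic, auxiliary=auxiliary)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute search -> curation -> split -> align -> triad -> tree ->
    annotate and write all artifacts plus a JSON manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed, "stages": {}}
    stage = "inputs"
    try:
        truth = None
        if config.simulate is not None:
            stage = "simulate"
            sim_cfg = replace(config.simulate, seed=config.seed)
            records, truth = simulate_dataset(sim_cfg)
            write_fixture(records, truth, out / "fixture")
            manifest["stages"]["simulate"] = {
                "records": len(records),
                "family": len(truth.triad_status),
                "decoys": len(truth.decoy_ids),
                "duplicates": sum(len(v) for v in truth.duplicate_clusters.values()),
                "fusions": len(truth.fusion_registry),
            }
        else:
            if not config.input_fasta:
                raise InvalidArgumentError(
                    "config needs a simulate block or input_fasta")
            taxonomy = (read_taxonomy(config.input_taxonomy)
                        if config.input_taxonomy else {})
            records = read_fasta(config.input_fasta, taxonomy=taxonomy)
            manifest["stages"]["inputs"] = {"records": len(records)}

        stage = "seeds"
        seeds = _pick_seed_records(records, truth, config)
        seed_aln = progressive_align(seeds, config.align)
        profile = build_profile(seed_aln)
        manifest["stages"]["seeds"] = {"n_seeds": len(seeds),
                                       "profile_columns": profile.length}

        stage = "search"
        hits = search_database(profile, records, config.search,
                               seed=config.seed)
        write_hits_tsv(hits, out / "hits.tsv")
        write_domains_tsv(hits, out / "hit_domains.tsv")
        manifest["stages"]["search"] = {
            "database": len(records), "hits": len(hits),
            "multi_domain": sum(1 for h in hits if h.n_domains >= 2),
        }

        stage = "curation"
        by_id = {r.id: r for r in records}
        hit_records = [by_id[h.target_id] for h in hits]
        spans = {h.target_id: h.domain_spans for h in hits}
        result = curate(hit_records, spans, config.curation)
        result.write_report(out / "curation.tsv")
        manifest["stages"]["curation"] = {
            "input": len(hit_records),
            "kept": len(result.kept),
            "flagged": sum(1 for _, s, _ in result.report if s == "flagged"),
            "split": sum(1 for _, s, _ in result.report if s == "split"),
            "merged": sum(1 for _, s, _ in result.report if s == "merged"),
        }

        stage = "align"
        aln = progressive_align(result.kept, config.align)
        aln.to_fasta(out / "aligned.fasta")
        manifest["stages"]["align"] = {"rows": len(aln), "columns": aln.n_cols}

        stage = "triad"
        if config.triad is not None:
            spec = config.triad
        elif truth is not None:
            spec = _auto_triad_spec(truth, {r.id for r in result.kept},
                                    config.simulate)
        else:
            raise InvalidArgumentError("triad spec required for real inputs")
        annotations = annotate_records(aln, spec)
        write_annotations_tsv(annotations, out / "triad.tsv")
        n_like = sum(1 for a in annotations.values() if a.is_isdg_like)
        manifest["stages"]["triad"] = {
            "reference": spec.reference_id,
            "annotated": len(annotations), "isdg_like": n_like,
        }

        stage = "tree"
        tip_ids = list(aln.ids)
        if config.restrict_to_isdg_like:
            tip_ids = [i for i in tip_ids if annotations[i].is_isdg_like]
        tree_aln = aln.subset(tip_ids) if len(tip_ids) < len(aln.ids) else aln
        # NJ starting tree on ML distances under LG+G4(alpha=1) as a
        # working model, then BIC model choice, then ML refinement.
        from .phylogeny import SubstModel
        work_model = SubstModel(alpha=1.0)
        ids, D = distance_matrix(tree_aln, work_model, tol=1e-5)
        nj = neighbor_joining(D, ids)
        model = select_model_bic(tree_aln, nj,
                                 candidates=config.phylo.candidate_models,
                                 cfg=config.phylo)
        tree = (optimize_tree(tree_aln, nj, model, config.phylo)
                if config.run_full_ml else deroot(nj.clone(depth=1)))
        tree = bootstrap_support(tree_aln, tree, model, config.phylo,
                                 seed=config.seed + 1)
        tree = midpoint_root(tree)
        write_newick(tree, out / "tree.nwk")
        manifest["stages"]["tree"] = {
            "tips": len(tip_ids), "model": model.name,
            "alpha": None if model.alpha is None else round(model.alpha, 4),
            "bootstrap_reps": config.phylo.bootstrap_reps,
        }

        stage = "annotate"
        taxonomy = {r.id: r.taxonomy for r in result.kept if r.taxonomy}
        tax_ds = taxonomy_dataset({i: taxonomy[i] for i in tip_ids})
        tri_ds = triad_dataset({i: annotations[i] for i in tip_ids})
        write_colorstrip(tree, tax_ds, out / "colorstrip_taxonomy.txt")
        write_colorstrip(tree, tri_ds, out / "colorstrip_triad.txt")
        summary = summarize_taxonomy(annotations, taxonomy)
        summary.to_csv(out / "taxonomy_summary.tsv", sep="\t", index=False)
        manifest["stages"]["annotate"] = {
            "summary_rows": len(summary),
            "isdg_like": int(summary["isdg_like"].sum()) if len(summary) else 0,
        }
    except Exception as exc:  # noqa: BLE001 - abort with the stage named
        manifest["failed_stage"] = stage
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
        raise PipelineError(stage, exc) from exc

    manifest["files"] = {
        str(p.relative_to(out)): _sha256(p)
        for p in sorted(out.rglob("*"))
        if p.is_file() and p.name != "manifest.json"
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
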