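"""Hit-set curation: composition filtering, redundancy collapse and
tandem-domain splitting.

Three auditable composition tests replace the ad-hoc filtering scripts
such datasets usually pass through: a single-residue dominance cap, a
length window, and a chi-square test of a record's residue composition
against the pooled composition of the whole hit set.  Redundancy is
collapsed by greedy identity clustering, and records carrying two domain
spans are split into ``_NTERM`` / ``_CTERM`` halves at the midpoint
between the spans.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .msa import AlignParams, pairwise_global
from .records import AA_INDEX, InvalidArgumentError, ProteinRecord


@dataclass
class CurationConfig:
    max_single_residue_fraction: float = 0.5
    # 19-df chi-square cutoff; deliberately tolerant so that family members
    # carrying a low-complexity insert keep their place in the dataset
    composition_chi2_threshold: float = 100.0
    dedup_identity: float = 0.97
    min_length: int = 30
    max_length: int = 5000
    keep_rule: str = "longest"                 # or "first"

    def __post_init__(self):
        if not (0 < self.dedup_identity <= 1):
            raise InvalidArgumentError("dedup_identity must be in (0, 1]")
        if self.min_length > self.max_length:
            raise InvalidArgumentError("min_length must be <= max_length")
        if self.keep_rule not in ("longest", "first"):
            raise InvalidArgumentError("keep_rule must be 'longest' or 'first'")


def _composition(seq: str) -> np.ndarray:
    counts = np.zeros(20)
    for ch in seq:
        idx = AA_INDEX.get(ch)
        if idx is not None:
            counts[idx] += 1.0
    return counts


def composition_filter(records, cfg: CurationConfig | None = None):
    """Flag composition outliers; returns (kept, flagged) with reasons.

    A record is flagged when its most frequent residue exceeds the
    dominance cap, its length falls outside the window, or its
    composition chi-square against the pooled composition of all input
    records exceeds the threshold.
    """
    cfg = cfg or CurationConfig()
    records = list(records)
    if not records:
        raise InvalidArgumentError("records must be non-empty")
    pooled = np.zeros(20)
    per_rec = {}
    for r in records:
        per_rec[r.id] = _composition(r.sequence)
        pooled += per_rec[r.id]
    pooled_freq = pooled / max(pooled.sum(), 1.0)
    kept, flagged = [], []
    for r in records:
        counts = per_rec[r.id]
        n = counts.sum()
        reasons = []
        if n > 0:
            frac = counts.max() / n
            if frac > cfg.max_single_residue_fraction:
                top = "ARNDCQEGHILKMFPSTWYV"[int(counts.argmax())]
                reasons.append(
                    f"max_residue_fraction({top})={frac:.3f}"
                    f">{cfg.max_single_residue_fraction}")
        if not (cfg.min_length <= len(r.sequence) <= cfg.max_length):
            reasons.append(f"length={len(r.sequence)} outside "
                           f"[{cfg.min_length},{cfg.max_length}]")
        if n > 0:
            expected = n * pooled_freq
            ok = expected > 0
            chi2 = float(((counts[ok] - expected[ok]) ** 2 / expected[ok]).sum())
            if chi2 > cfg.composition_chi2_threshold:
                reasons.append(f"composition_chi2={chi2:.1f}"
                               f">{cfg.composition_chi2_threshold}")
        if reasons:
            flagged.append((r, "; ".join(reasons)))
        else:
            kept.append(r)
    return kept, flagged


def pairwise_identity(a: str, b: str) -> float:
    """Global-alignment identity: matches / columns with both residues."""
    if a == b:
        return 1.0
    if len(a) == len(b):
        matches = sum(1 for x, y in zip(a, b) if x == y)
        return matches / len(a)
    aa, bb, _ = pairwise_global(a, b, AlignParams())
    both = [(x, y) for x, y in zip(aa, bb) if x != "-" and y != "-"]
    if not both:
        return 0.0
    return sum(1 for x, y in both if x == y) / len(both)


def deduplicate(records, cfg: CurationConfig | None = None):
    """Greedy identity clustering in input order.

    A record joins the first cluster whose founder it matches at
    >= dedup_identity, otherwise founds a new cluster; the reported
    representative is re-chosen by ``keep_rule`` once clustering is done.
    Returns (representatives, cluster_map) with cluster_map keyed by
    representative id (each representative is a member of its cluster).
    """
    cfg = cfg or CurationConfig()
    records = list(records)
    founders: list[ProteinRecord] = []
    members: dict[str, list[ProteinRecord]] = {}
    for r in records:
        for f in founders:
            if pairwise_identity(r.sequence, f.sequence) >= cfg.dedup_identity:
                members[f.id].append(r)
                break
        else:
            founders.append(r)
            members[r.id] = [r]
    reps = []
    cluster_map: dict[str, list[str]] = {}
    for f in founders:
        group = members[f.id]
        if cfg.keep_rule == "longest":
            rep = max(group, key=lambda r: len(r.sequence))
        else:
            rep = group[0]
        reps.append(rep)
        cluster_map[rep.id] = [r.id for r in group]
    return reps, cluster_map


def split_tandem(record: ProteinRecord, domain_spans) -> list[ProteinRecord]:
    """Split a multi-domain record at inter-span midpoints.

    With two spans the halves are labeled ``<id>_NTERM`` and
    ``<id>_CTERM``; with one span the record is returned unchanged.  More
    than two spans is beyond the two-domain convention: pieces are labeled
    ``<id>_DOM1..`` and tagged synthetic so downstream reports flag them.
    """
    spans = [(s.start, s.end) if hasattr(s, "start") else tuple(s)
             for s in domain_spans]
    spans.sort()
    for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
        if s2 <= e1:
            raise InvalidArgumentError(
                f"overlapping domain spans on {record.id}: "
                f"({s1},{e1}) and ({s2},{e2})")
    if len(spans) <= 1:
        return [record]
    cuts = [(e1 + s2) // 2 for (_, e1), (s2, _) in zip(spans, spans[1:])]
    bounds = [0] + cuts + [len(record.sequence)]
    pieces = []
    for k, (lo, hi) in enumerate(zip(bounds, bounds[1:])):
        if len(spans) == 2:
            suffix, prov = (("NTERM", "split-NTERM") if k == 0
                            else ("CTERM", "split-CTERM"))
        else:
            suffix, prov = f"DOM{k + 1}", "synthetic"
        pieces.append(ProteinRecord(
            id=f"{record.id}_{suffix}", sequence=record.sequence[lo:hi],
            taxonomy=record.taxonomy, provenance=prov, start=record.start + lo,
        ))
    return pieces


@dataclass
class CurationResult:
    kept: list[ProteinRecord]
    report: list[tuple[str, str, str]]       # (id, status, detail)
    cluster_map: dict[str, list[str]] = field(default_factory=dict)

    def write_report(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("id\tstatus\tdetail\n")
            for rid, status, detail in self.report:
                fh.write(f"{rid}\t{status}\t{detail}\n")


def curate(records, domain_spans: dict[str, list] | None = None,
           cfg: CurationConfig | None = None) -> CurationResult:
    """Composition filter, tandem splitting, then redundancy collapse.

    ``domain_spans`` maps record id to its search domain spans; records
    with two or more spans are split before deduplication.  Sequence
    content is never altered - curation only removes, splits or merges.
    """
    cfg = cfg or CurationConfig()
    domain_spans = domain_spans or {}
    report: list[tuple[str, str, str]] = []
    kept, flagged = composition_filter(records, cfg)
    for r, reason in flagged:
        report.append((r.id, "flagged", reason))
    expanded = []
    for r in kept:
        pieces = split_tandem(r, domain_spans.get(r.id, []))
        if len(pieces) > 1:
            report.append((r.id, "split",
                           ",".join(p.id for p in pieces)))
        expanded.extend(pieces)
    reps, cluster_map = deduplicate(expanded, cfg)
    rep_ids = {r.id for r in reps}
    for rep_id, group in cluster_map.items():
        for member in group:
            if member != rep_id:
                report.append((member, "merged", f"into {rep_id}"))
    for r in reps:
        report.append((r.id, "kept", ""))
    return CurationResult(kept=reps, report=report, cluster_map=cluster_map)
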