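"""Catalytic-triad conservation mapping through a multiple alignment.

IsdG-family heme oxygenases are defined by an N/W/H catalytic triad
(asparagine, tryptophan, histidine) plus three conserved auxiliary
residues (F/G/W).  Given a reference sequence whose residue numbers are
known - by default positions 41/100/110 for the triad and 69/70/91 for
the auxiliary set, the printed coordinates of the algal family member the
analysis is anchored on - the reference's positions are projected through
the alignment onto every row, each mapped column is checked for the
required residue, and records conserving all three catalytic residues are
classified IsdG-like.

Coordinates are 1-based throughout (residue positions and alignment
columns); a gap never matches.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .records import AMINO_ACIDS, InvalidArgumentError

DEFAULT_CATALYTIC = ((41, "N"), (100, "W"), (110, "H"))
DEFAULT_AUXILIARY = ((69, "F"), (70, "G"), (91, "W"))

# Fixed similarity partition used by similarity-group matching.
SIMILARITY_GROUPS = ("AG", "ST", "C", "DE", "NQ", "KR", "H", "ILMV", "FWY", "P")
_GROUP_OF = {aa: g for g, grp in enumerate(SIMILARITY_GROUPS) for aa in grp}


class ReferenceNotFoundError(InvalidArgumentError):
    """The reference row is missing from the alignment."""


class UndefinedIdentityError(InvalidArgumentError):
    """Two rows share no non-gap columns."""


@dataclass(frozen=True)
class TriadSpec:
    reference_id: str
    catalytic: tuple = DEFAULT_CATALYTIC
    auxiliary: tuple = DEFAULT_AUXILIARY
    match_mode: str = "identity"           # or "similarity-group"

    def __post_init__(self):
        for pos, res in tuple(self.catalytic) + tuple(self.auxiliary):
            if pos < 1:
                raise InvalidArgumentError(f"position {pos} must be >= 1")
            if res not in AMINO_ACIDS:
                raise InvalidArgumentError(f"invalid required residue {res!r}")
        if self.match_mode not in ("identity", "similarity-group"):
            raise InvalidArgumentError(
                "match_mode must be 'identity' or 'similarity-group'")


@dataclass
class TriadAnnotation:
    record_id: str
    catalytic_flags: tuple[bool, ...]
    auxiliary_flags: tuple[bool, ...]

    @property
    def catalytic_count(self) -> int:
        return sum(self.catalytic_flags)

    @property
    def aux_count(self) -> int:
        return sum(self.auxiliary_flags)

    @property
    def is_isdg_like(self) -> bool:
        return self.catalytic_count == len(self.catalytic_flags)


def map_reference_columns(msa, reference_id: str, positions) -> list[int]:
    """Alignment column (1-based) holding each reference position.

    Position p maps to the column containing the reference row's p-th
    residue, counting residues and skipping gaps.
    """
    try:
        row = msa.row(reference_id)
    except KeyError:
        raise ReferenceNotFoundError(
            f"reference {reference_id!r} not in alignment") from None
    residue_cols = [c + 1 for c, ch in enumerate(row) if ch != "-"]
    cols = []
    for p in positions:
        if p < 1:
            raise InvalidArgumentError(f"reference position {p} must be >= 1")
        if p > len(residue_cols):
            raise InvalidArgumentError(
                f"reference position {p} beyond reference length "
                f"{len(residue_cols)}")
        cols.append(residue_cols[p - 1])
    return cols


def _matches(observed: str, required: str, mode: str) -> bool:
    if observed == "-" or observed == "X":
        return False
    if mode == "identity":
        return observed == required
    return _GROUP_OF.get(observed) == _GROUP_OF.get(required)


def annotate_records(msa, spec: TriadSpec) -> dict[str, TriadAnnotation]:
    """Per-row conservation flags and counts for the catalytic and
    auxiliary sites of ``spec``, keyed by record id."""
    cat_cols = map_reference_columns(msa, spec.reference_id,
                                     [p for p, _ in spec.catalytic])
    aux_cols = map_reference_columns(msa, spec.reference_id,
                                     [p for p, _ in spec.auxiliary])
    out = {}
    for rid in msa.ids:
        row = msa.row(rid)
        cat = tuple(
            _matches(row[c - 1], res, spec.match_mode)
            for c, (_, res) in zip(cat_cols, spec.catalytic))
        aux = tuple(
            _matches(row[c - 1], res, spec.match_mode)
            for c, (_, res) in zip(aux_cols, spec.auxiliary))
        out[rid] = TriadAnnotation(rid, cat, aux)
    return out


def percent_identity(msa, row_id: str, ref_id: str) -> float:
    """100 x matches / shared non-gap columns between two rows."""
    a, b = msa.row(row_id), msa.row(ref_id)
    both = [(x, y) for x, y in zip(a, b) if x != "-" and y != "-"]
    if not both:
        raise UndefinedIdentityError(
            f"{row_id} and {ref_id} share no non-gap columns")
    return 100.0 * sum(1 for x, y in both if x == y) / len(both)


def write_annotations_tsv(annotations: dict[str, TriadAnnotation], path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tcatalytic_count\taux_count\tis_isdg_like\n")
        for rid, ann in annotations.items():
            fh.write(f"{rid}\t{ann.catalytic_count}\t{ann.aux_count}\t"
                     f"{int(ann.is_isdg_like)}\n")
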