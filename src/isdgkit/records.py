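"""Protein records and flat-file I/O.

The pipeline's atomic unit is a :class:`ProteinRecord`: one protein chain
(or one split domain of a tandem fusion) with its residues, taxonomy labels
and a provenance tag recording how the record entered the analysis.

Sequences are strings over the 20 standard amino acids plus ``X`` for an
unknown residue.  Ambiguity codes ``B``, ``Z``, ``J``, ``U`` and ``O`` are
mapped to ``X`` on sanitisation (with a warning); anything else is refused.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

# Canonical residue order used by every matrix in the package (the classic
# PAML ordering that amino-acid rate matrices are published in).
AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
GAP = "-"
UNKNOWN = "X"
_AMBIGUOUS = set("BZJUO")

PROVENANCE_TAGS = frozenset(
    {"seed", "database", "synthetic", "split-NTERM", "split-CTERM"}
)


class InvalidArgumentError(ValueError):
    """An argument violates an operation's preconditions."""


class InvalidResidueError(InvalidArgumentError):
    """A sequence contains a character outside the accepted alphabet."""


def sanitize_sequence(seq: str) -> str:
    """Uppercase, map ambiguity codes to X, reject anything else."""
    seq = seq.upper().replace("*", "")
    out = []
    warned = False
    for ch in seq:
        if ch in AA_INDEX or ch == UNKNOWN:
            out.append(ch)
        elif ch in _AMBIGUOUS:
            if not warned:
                warnings.warn(
                    f"ambiguous residue code(s) mapped to X in sequence", stacklevel=3
                )
                warned = True
            out.append(UNKNOWN)
        else:
            raise InvalidResidueError(f"invalid residue {ch!r}")
    return "".join(out)


def encode_sequence(seq: str) -> np.ndarray:
    """Residues to integer codes; X (and gap) code as 20 (= missing)."""
    codes = np.full(len(seq), 20, dtype=np.int8)
    for i, ch in enumerate(seq):
        codes[i] = AA_INDEX.get(ch, 20)
    return codes


@dataclass(frozen=True)
class ProteinRecord:
    """One protein (or split domain).

    ``start`` is the 1-based coordinate of the first residue on the parent
    chain, so split domains keep their original numbering.
    """

    id: str
    sequence: str
    taxonomy: tuple[str, str] | None = None
    provenance: str = "database"
    start: int = 1

    def __post_init__(self):
        if not self.id:
            raise InvalidArgumentError("record id must be non-empty")
        if not self.sequence:
            raise InvalidArgumentError(f"record {self.id}: empty sequence")
        if self.provenance not in PROVENANCE_TAGS:
            raise InvalidArgumentError(
                f"record {self.id}: unknown provenance {self.provenance!r}"
            )
        bad = set(self.sequence) - set(AMINO_ACIDS) - {UNKNOWN}
        if bad:
            raise InvalidResidueError(
                f"record {self.id}: invalid residue(s) {sorted(bad)!r}; "
                "sanitize_sequence() maps ambiguity codes to X"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def with_(self, **kw) -> "ProteinRecord":
        return replace(self, **kw)


def check_unique_ids(records) -> None:
    seen = set()
    for r in records:
        if r.id in seen:
            raise InvalidArgumentError(f"duplicate record id {r.id!r}")
        seen.add(r.id)


# ---------------------------------------------------------------------------
# FASTA / taxonomy TSV
# ---------------------------------------------------------------------------

def read_fasta(path, taxonomy: dict[str, tuple[str, str]] | None = None,
               provenance: str = "database") -> list[ProteinRecord]:
    """Read a (possibly wrapped) FASTA file into records."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = sanitize_sequence(str(rec.seq))
        tax = taxonomy.get(rec.id) if taxonomy else None
        records.append(
            ProteinRecord(id=rec.id, sequence=seq, taxonomy=tax, provenance=provenance)
        )
    check_unique_ids(records)
    return records


def write_fasta(records, path) -> None:
    """Write records as 60-column-wrapped FASTA."""
    seqs = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        SeqIO.write(seqs, fh, "fasta")


def read_taxonomy(path) -> dict[str, tuple[str, str]]:
    """Read the ``id<TAB>domain<TAB>division`` sidecar table."""
    out: dict[str, tuple[str, str]] = {}
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None:
            return out
        if [h.strip().lower() for h in header[:3]] != ["id", "domain", "division"]:
            raise InvalidArgumentError(
                f"taxonomy table {path}: expected header id<TAB>domain<TAB>division"
            )
        for row in reader:
            if not row or not row[0].strip():
                continue
            out[row[0]] = (row[1], row[2])
    return out


def write_taxonomy(taxonomy: dict[str, tuple[str, str]], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["id", "domain", "division"])
        for rid in taxonomy:
            dom, div = taxonomy[rid]
            w.writerow([rid, dom, div])
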