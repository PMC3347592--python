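"""Catalytic-residue annotations: loading, validation, serialization.

A residue counts as catalytic when it is directly involved in the catalytic
mechanism (e.g. a nucleophile), alters the acid-base properties of another
active-site residue or an ordered water, or stabilizes the transition state
or a reaction intermediate.  Annotations arrive as a CSA-style TSV — one row
per catalytic residue with its mechanistic role and the evidence source
(hand-annotated CSA entry, homology-transferred CSA entry, literature, or
user-supplied) — so the same file contract serves database exports and
manual curation alike.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .structure_model import ResidueID, Structure

__all__ = [
    "ROLES",
    "EVIDENCE",
    "STANDARD_AMINO_ACIDS",
    "CatalyticResidue",
    "SiteAnnotation",
    "AnnotationError",
    "load_catalytic_annotations",
    "dump_catalytic_annotations",
    "validate_annotation",
]

ROLES = frozenset({"nucleophile", "acid_base", "transition_state_stabilizer", "other"})
EVIDENCE = frozenset({"csa_original", "csa_homologous", "literature", "user"})
STANDARD_AMINO_ACIDS = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)
_COLUMNS = ["entry_id", "chain", "resnum", "icode", "resname", "role", "evidence"]


class AnnotationError(ValueError):
    """Raised for malformed or inconsistent annotation tables."""


@dataclass(frozen=True)
class CatalyticResidue:
    id: ResidueID
    expected_name: str
    role: str
    evidence: str

    def __post_init__(self) -> None:
        if self.expected_name not in STANDARD_AMINO_ACIDS:
            raise AnnotationError(f"{self.id}: {self.expected_name!r} is not a standard amino acid")
        if self.role not in ROLES:
            raise AnnotationError(f"{self.id}: unknown role {self.role!r}")
        if self.evidence not in EVIDENCE:
            raise AnnotationError(f"{self.id}: unknown evidence {self.evidence!r}")


@dataclass(frozen=True)
class SiteAnnotation:
    entry_id: str
    residues: tuple[CatalyticResidue, ...]

    def __post_init__(self) -> None:
        if not self.residues:
            raise AnnotationError(f"{self.entry_id}: annotation has no residues")
        ids = [r.id for r in self.residues]
        if len(set(ids)) != len(ids):
            raise AnnotationError(f"{self.entry_id}: duplicate residue ids in annotation")

    def ids(self) -> set[ResidueID]:
        return {r.id for r in self.residues}


def load_catalytic_annotations(path: str | Path) -> list[SiteAnnotation]:
    """Parse a catalytic-annotation TSV into one SiteAnnotation per entry.

    Expected header columns: entry_id, chain, resnum, icode, resname, role,
    evidence.  Row order is preserved within each entry.  Unknown role or
    evidence tokens, duplicated residues, and missing columns are rejected
    with the offending row number (1-based data rows).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise AnnotationError(f"{path}: missing column(s) {', '.join(missing)}")

    by_entry: dict[str, list[CatalyticResidue]] = {}
    seen: set[tuple[str, ResidueID]] = set()
    for row_no, row in enumerate(df.itertuples(index=False), start=1):
        entry = row.entry_id.strip()
        try:
            number = int(row.resnum)
        except ValueError:
            raise AnnotationError(f"{path} row {row_no}: resnum {row.resnum!r} is not an integer") from None
        rid = ResidueID(row.chain.strip(), number, row.icode.strip())
        if (entry, rid) in seen:
            raise AnnotationError(f"{path} row {row_no}: duplicate residue {rid} for entry {entry}")
        seen.add((entry, rid))
        role = row.role.strip()
        evidence = row.evidence.strip()
        if role not in ROLES:
            raise AnnotationError(f"{path} row {row_no}: unknown role token {role!r}")
        if evidence not in EVIDENCE:
            raise AnnotationError(f"{path} row {row_no}: unknown evidence token {evidence!r}")
        by_entry.setdefault(entry, []).append(
            CatalyticResidue(rid, row.resname.strip().upper(), role, evidence)
        )

    return [SiteAnnotation(entry, tuple(residues)) for entry, residues in by_entry.items()]


def dump_catalytic_annotations(annotations: list[SiteAnnotation], path: str | Path) -> Path:
    """Serialize annotations back to the seven-column TSV (lossless inverse)."""
    rows = [
        {
            "entry_id": ann.entry_id,
            "chain": res.id.chain,
            "resnum": res.id.number,
            "icode": res.id.icode,
            "resname": res.expected_name,
            "role": res.role,
            "evidence": res.evidence,
        }
        for ann in annotations
        for res in ann.residues
    ]
    path = Path(path)
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, sep="\t", index=False)
    return path


def validate_annotation(structure: Structure, annotation: SiteAnnotation) -> SiteAnnotation:
    """Check every annotated residue exists in the structure under the expected name.

    Catalytic residues anchor every downstream step, so any failure aborts
    the run rather than silently dropping the residue.  Idempotent; returns
    the annotation unchanged on success.
    """
    problems: list[str] = []
    for res in annotation.residues:
        found = structure.get(res.id)
        if found is None:
            problems.append(f"{res.id}: not in structure")
        elif found.name.upper() != res.expected_name:
            problems.append(
                f"{res.id}: identity mismatch (structure has {found.name}, annotation expects {res.expected_name})"
            )
    if problems:
        raise AnnotationError(
            f"annotation {annotation.entry_id} failed validation: " + "; ".join(problems)
        )
    return annotation
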