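"""Coordinate data model: PDB reading/writing, geometry, secondary structure.

The model is deliberately minimal — a single-conformer, single-model view of a
crystal structure keyed by author numbering (chain, residue number, insertion
code), which is the numbering every downstream annotation and report uses.
Alternate locations are resolved to the highest-occupancy conformer, waters and
heteroatoms are dropped, and HELIX/SHEET records from the file are kept as
first-class secondary-structure intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "ResidueID",
    "Residue",
    "SSERecord",
    "Structure",
    "PDBFormatError",
    "read_pdb",
    "write_pdb_subset",
    "residue_min_distance",
    "assign_secondary_structure",
    "dihedral_angle",
]

#: φ/ψ windows (degrees) for the dihedral fallback assignment.  A residue is
#: helical if φ ∈ [−90, −30] and ψ ∈ [−77, −17]; strand if φ ∈ [−150, −90]
#: and ψ ∈ [90, 170].  Runs must span at least MIN_SSE_RUN residues.
HELIX_PHI = (-90.0, -30.0)
HELIX_PSI = (-77.0, -17.0)
STRAND_PHI = (-150.0, -90.0)
STRAND_PSI = (90.0, 170.0)
MIN_SSE_RUN = 3


class PDBFormatError(ValueError):
    """Raised when a coordinate file cannot be parsed."""


@dataclass
class Atom:
    """One atom with coordinates in Å."""

    name: str
    element: str
    coords: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""
    bfactor: float = 0.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name}: coordinates must be a finite 3-vector")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.name}: occupancy {self.occupancy} outside [0, 1]")

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() not in ("H", "D")


@dataclass(frozen=True, order=True)
class ResidueID:
    """Author numbering: chain id, residue number, insertion code."""

    chain: str
    number: int
    icode: str = ""

    def __str__(self) -> str:
        return f"{self.chain}:{self.number}{self.icode}"


@dataclass
class Residue:
    id: ResidueID
    name: str
    atoms: list[Atom]

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError(f"residue {self.id} has no atoms")

    def heavy_coords(self) -> np.ndarray:
        """(n, 3) array of heavy-atom coordinates."""
        coords = [a.coords for a in self.atoms if a.is_heavy]
        if not coords:
            raise ValueError(f"residue {self.id} has no heavy atoms")
        return np.array(coords)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass(frozen=True)
class SSERecord:
    """A helix or strand interval, from file records or dihedral assignment."""

    kind: str  # "helix" | "strand"
    start: ResidueID
    end: ResidueID
    source: str  # "file_record" | "dihedral_assigned"

    def __post_init__(self) -> None:
        if self.kind not in ("helix", "strand"):
            raise ValueError(f"SSE kind must be helix or strand, got {self.kind!r}")
        if self.source not in ("file_record", "dihedral_assigned"):
            raise ValueError(f"unknown SSE source {self.source!r}")


@dataclass
class Structure:
    """One model of a PDB entry: ordered residues per chain plus SSE records."""

    entry_id: str
    chains: dict[str, list[Residue]] = field(default_factory=dict)
    sse_records: list[SSERecord] = field(default_factory=list)
    model_index: int = 0

    def residues(self) -> Iterator[Residue]:
        for chain in self.chains.values():
            yield from chain

    def residue_ids(self) -> list[ResidueID]:
        return [r.id for r in self.residues()]

    def get(self, rid: ResidueID) -> Residue | None:
        for res in self.chains.get(rid.chain, []):
            if res.id == rid:
                return res
        return None

    def __contains__(self, rid: ResidueID) -> bool:
        return self.get(rid) is not None

    def __len__(self) -> int:
        return sum(len(c) for c in self.chains.values())

    def chain_index(self, rid: ResidueID) -> int:
        """Position of a residue within its chain (file order)."""
        for i, res in enumerate(self.chains.get(rid.chain, [])):
            if res.id == rid:
                return i
        raise KeyError(f"residue {rid} not in structure {self.entry_id}")

    def translated(self, shift: Sequence[float]) -> "Structure":
        """Rigidly translated copy (geometry tests and grid invariance)."""
        shift = np.asarray(shift, dtype=float)
        chains = {
            cid: [
                Residue(r.id, r.name, [replace(a, coords=a.coords + shift) for a in r.atoms])
                for r in residues
            ]
            for cid, residues in self.chains.items()
        }
        return Structure(self.entry_id, chains, list(self.sse_records), self.model_index)


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------


def _prescan(path: Path) -> None:
    """Cheap format check that can point at the offending line."""
    n_atoms = 0
    with open(path, "r", errors="replace") as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec in ("ATOM  ", "HETATM"):
                try:
                    float(line[30:38])
                    float(line[38:46])
                    float(line[46:54])
                except (ValueError, IndexError):
                    raise PDBFormatError(
                        f"{path}: unparseable coordinate field on line {lineno}"
                    ) from None
                if rec == "ATOM  ":
                    n_atoms += 1
    if n_atoms == 0:
        raise PDBFormatError(f"{path}: no ATOM records")


def _icode(gem_icode: str) -> str:
    return "" if gem_icode in (" ", "\x00", "") else gem_icode


def read_pdb(path: str | Path, model_index: int = 0) -> Structure:
    """Read one model of a PDB file into a Structure.

    Alternate locations are resolved per atom name to the highest-occupancy
    conformer (ties: first in file).  Waters and HETATM records are excluded.
    HELIX and SHEET records become SSERecords with source ``file_record``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _prescan(path)

    st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    if model_index >= len(st):
        raise IndexError(f"{path}: model {model_index} not present ({len(st)} models)")
    model = st[model_index]

    chains: dict[str, list[Residue]] = {}
    for chain in model:
        residues: list[Residue] = []
        for res in chain:
            if res.het_flag != "A" or res.is_water():
                continue
            # altloc resolution: per atom name keep the highest occupancy,
            # first-in-file on ties
            best: dict[str, Atom] = {}
            order: list[str] = []
            for a in res:
                atom = Atom(
                    name=a.name,
                    element=a.element.name,
                    coords=np.array([a.pos.x, a.pos.y, a.pos.z]),
                    occupancy=min(max(a.occ, 0.0), 1.0),
                    altloc=_icode(a.altloc),
                    bfactor=a.b_iso,
                )
                if a.name not in best:
                    best[a.name] = atom
                    order.append(a.name)
                elif atom.occupancy > best[a.name].occupancy:
                    best[a.name] = atom
            rid = ResidueID(chain.name, res.seqid.num, _icode(res.seqid.icode))
            residues.append(Residue(rid, res.name, [best[n] for n in order]))
        if residues:
            chains.setdefault(chain.name, []).extend(residues)

    sse: list[SSERecord] = []
    for h in st.helices:
        sse.append(
            SSERecord(
                "helix",
                ResidueID(h.start.chain_name, h.start.res_id.seqid.num, _icode(h.start.res_id.seqid.icode)),
                ResidueID(h.end.chain_name, h.end.res_id.seqid.num, _icode(h.end.res_id.seqid.icode)),
                "file_record",
            )
        )
    for sheet in st.sheets:
        for strand in sheet.strands:
            sse.append(
                SSERecord(
                    "strand",
                    ResidueID(strand.start.chain_name, strand.start.res_id.seqid.num, _icode(strand.start.res_id.seqid.icode)),
                    ResidueID(strand.end.chain_name, strand.end.res_id.seqid.num, _icode(strand.end.res_id.seqid.icode)),
                    "file_record",
                )
            )

    entry_id = st.name.strip() if st.name.strip() else path.stem
    return Structure(entry_id=entry_id, chains=chains, sse_records=sse, model_index=model_index)


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------


def _format_atom_name(name: str) -> str:
    # column convention: 1-char element symbols start in column 14
    if len(name) >= 4:
        return name[:4]
    return f" {name:<3s}"


def write_pdb_subset(
    structure: Structure,
    selection: Sequence[ResidueID],
    path: str | Path,
    remarks: Sequence[str] = (),
) -> Path:
    """Write the selected residues as a standard PDB file.

    Residues keep their original chain order and author numbering; each
    supplied remark becomes a ``REMARK 999`` line; TER closes each chain.
    """
    if not selection:
        raise ValueError("empty selection: an empty substructure is meaningless")
    wanted = set(selection)
    for rid in wanted:
        if rid not in structure:
            raise KeyError(f"selection residue {rid} not in structure {structure.entry_id}")

    path = Path(path)
    lines: list[str] = []
    for remark in remarks:
        lines.append(f"REMARK 999 {remark}".rstrip())
    serial = 0
    for cid, residues in structure.chains.items():
        wrote_any = False
        for res in residues:
            if res.id not in wanted:
                continue
            wrote_any = True
            for atom in res.atoms:
                serial += 1
                x, y, z = atom.coords
                lines.append(
                    "ATOM  {serial:>5d} {name:<4s}{alt:1s}{res:<3s} {chain:1s}"
                    "{num:>4d}{icode:1s}   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}"
                    "          {el:>2s}".format(
                        serial=serial,
                        name=_format_atom_name(atom.name),
                        alt=atom.altloc[:1] if atom.altloc else " ",
                        res=res.name[:3],
                        chain=cid[:1] if cid else " ",
                        num=res.id.number,
                        icode=res.id.icode[:1] if res.id.icode else " ",
                        x=x,
                        y=y,
                        z=z,
                        occ=atom.occupancy,
                        b=atom.bfactor,
                        el=atom.element[:2],
                    )
                )
        if wrote_any:
            serial += 1
            lines.append(f"TER   {serial:>5d}")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------


def residue_min_distance(r1: Residue, r2: Residue) -> float:
    """Minimum heavy-atom–heavy-atom Euclidean distance between two residues."""
    a = r1.heavy_coords()
    b = r2.heavy_coords()
    diff = a[:, None, :] - b[None, :, :]
    return float(np.sqrt((diff**2).sum(axis=2)).min())


def dihedral_angle(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed dihedral p0-p1-p2-p3 in degrees, in (-180, 180]."""
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - (b0 @ b1) * b1
    w = b2 - (b2 @ b1) * b1
    return math.degrees(math.atan2(float(np.cross(b1, v) @ w), float(v @ w)))


def _backbone_dihedrals(chain: list[Residue]) -> list[tuple[float | None, float | None]]:
    """Per-residue (φ, ψ); None where a flanking residue or atom is missing."""
    out: list[tuple[float | None, float | None]] = []
    for i, res in enumerate(chain):
        n, ca, c = res.atom("N"), res.atom("CA"), res.atom("C")
        phi = psi = None
        if n and ca and c:
            if i > 0:
                c_prev = chain[i - 1].atom("C")
                if c_prev is not None:
                    phi = dihedral_angle(c_prev.coords, n.coords, ca.coords, c.coords)
            if i + 1 < len(chain):
                n_next = chain[i + 1].atom("N")
                if n_next is not None:
                    psi = dihedral_angle(n.coords, ca.coords, c.coords, n_next.coords)
        out.append((phi, psi))
    return out


def _in_window(value: float | None, window: tuple[float, float]) -> bool:
    return value is None or window[0] <= value <= window[1]


def _classify(phi: float | None, psi: float | None) -> str | None:
    if phi is None and psi is None:
        return None
    if _in_window(phi, HELIX_PHI) and _in_window(psi, HELIX_PSI):
        return "helix"
    if _in_window(phi, STRAND_PHI) and _in_window(psi, STRAND_PSI):
        return "strand"
    return None


def assign_secondary_structure(structure: Structure) -> list[SSERecord]:
    """File HELIX/SHEET records plus φ/ψ-window assignment for uncovered residues.

    Chain-terminal residues, which have only one defined backbone dihedral,
    are classified on that angle alone.  Assigned runs must span at least
    three consecutive residues and never overlap file records.
    """
    records: list[SSERecord] = list(structure.sse_records)
    covered: set[ResidueID] = set()
    for rec in structure.sse_records:
        chain = structure.chains.get(rec.start.chain, [])
        ids = [r.id for r in chain]
        if rec.start in ids and rec.end in ids:
            i0, i1 = ids.index(rec.start), ids.index(rec.end)
            covered.update(ids[i0 : i1 + 1])

    for cid, chain in structure.chains.items():
        if len(chain) < 3:
            continue
        dihedrals = _backbone_dihedrals(chain)
        labels = [
            None if chain[i].id in covered else _classify(*dihedrals[i])
            for i in range(len(chain))
        ]
        i = 0
        while i < len(labels):
            if labels[i] is None:
                i += 1
                continue
            j = i
            while j + 1 < len(labels) and labels[j + 1] == labels[i]:
                j += 1
            if j - i + 1 >= MIN_SSE_RUN:
                records.append(
                    SSERecord(labels[i], chain[i].id, chain[j].id, "dihedral_assigned")
                )
            i = j + 1

    order: dict[ResidueID, tuple[int, int]] = {}
    for ci, (cid, chain) in enumerate(structure.chains.items()):
        for ri, res in enumerate(chain):
            order[res.id] = (ci, ri)
    records.sort(key=lambda r: order.get(r.start, (len(order), 0)))
    return records
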