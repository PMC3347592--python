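"""Merge catalytic and pocket residues into one integral active-site substructure.

Catalytic residues and cavity-lining residues rarely form contiguous stretches
of chain; to yield a structurally coherent fragment they are joined with
surrounding residues that complete secondary-structure elements and bridge
short sequence gaps.  The result — an ordered, tagged residue selection — is
written out as a standard PDB file whose REMARK 999 block records the entry,
the build parameters and the per-residue tags, so the file is self-describing.

Selection rules, applied per chain in file order:

1. Seed with catalytic ∪ pocket lining; catalytic tag wins on overlap.
2. If ``complete_sse``, extend over every helix/strand interval intersecting
   the selection (new residues tagged ``connective``).
3. Bridge sequence gaps of at most ``max_gap`` unselected residues between
   selected residues on the same chain.
4. Runs shorter than ``min_fragment``: a run containing a catalytic residue
   is extended with flanking residues until it reaches ``min_fragment``
   (catalytic runs are never dropped); a run without one is dropped.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

from .pocket_finder import Pocket
from .site_annotation import SiteAnnotation
from .structure_model import ResidueID, Structure, assign_secondary_structure, write_pdb_subset

__all__ = [
    "SelectionTag",
    "BuilderParams",
    "SubstructureSpec",
    "build_selection",
    "write_substructure",
    "read_substructure_tags",
    "spec_to_json",
    "coverage_percentage",
    "coverage_stats",
]


class SelectionTag(str, Enum):
    CATALYTIC = "catalytic"
    BINDING = "binding"
    CONNECTIVE = "connective"


#: precedence on overlap: the strongest reason for inclusion wins
_TAG_RANK = {SelectionTag.CATALYTIC: 0, SelectionTag.BINDING: 1, SelectionTag.CONNECTIVE: 2}


@dataclass(frozen=True)
class BuilderParams:
    max_gap: int = 3  # bridge gaps of at most this many residues
    complete_sse: bool = True  # cover whole intersected helices/strands
    min_fragment: int = 3  # shortest surviving contiguous run

    def __post_init__(self) -> None:
        if self.max_gap < 0:
            raise ValueError("max_gap must be >= 0")
        if self.min_fragment < 1:
            raise ValueError("min_fragment must be >= 1")


@dataclass
class SubstructureSpec:
    entry_id: str
    members: list[tuple[ResidueID, SelectionTag]]
    params: BuilderParams = field(default_factory=BuilderParams)

    def ids(self) -> list[ResidueID]:
        return [rid for rid, _ in self.members]

    def tags(self) -> dict[ResidueID, SelectionTag]:
        return dict(self.members)


def _runs(indices: list[int]) -> list[list[int]]:
    """Maximal runs of consecutive integers (input sorted)."""
    runs: list[list[int]] = []
    for i in indices:
        if runs and i == runs[-1][-1] + 1:
            runs[-1].append(i)
        else:
            runs.append([i])
    return runs


def build_selection(
    structure: Structure,
    annotation: SiteAnnotation,
    pocket: Pocket,
    params: BuilderParams = BuilderParams(),
) -> SubstructureSpec:
    """Apply the four selection rules and return the ordered, tagged residue set."""
    if annotation.entry_id != structure.entry_id:
        raise ValueError(
            f"annotation entry {annotation.entry_id!r} does not match structure {structure.entry_id!r}"
        )
    stray = [str(r) for r in pocket.lining if r not in structure]
    if stray:
        raise ValueError(
            f"pocket lining references residues absent from {structure.entry_id}: "
            + ", ".join(sorted(stray))
        )

    catalytic_ids = annotation.ids()
    tags: dict[ResidueID, SelectionTag] = {rid: SelectionTag.BINDING for rid in pocket.lining}
    for rid in catalytic_ids:
        tags[rid] = SelectionTag.CATALYTIC

    def add(rid: ResidueID, tag: SelectionTag) -> None:
        if rid not in tags or _TAG_RANK[tag] < _TAG_RANK[tags[rid]]:
            tags[rid] = tag

    # 2. complete intersected secondary-structure elements
    if params.complete_sse:
        sse = assign_secondary_structure(structure)
        for rec in sse:
            chain = structure.chains.get(rec.start.chain, [])
            ids = [r.id for r in chain]
            if rec.start not in ids or rec.end not in ids:
                continue
            i0, i1 = ids.index(rec.start), ids.index(rec.end)
            span = ids[i0 : i1 + 1]
            if any(rid in tags for rid in span):
                for rid in span:
                    add(rid, SelectionTag.CONNECTIVE)

    # 3. bridge short gaps, per chain
    for cid, chain in structure.chains.items():
        ids = [r.id for r in chain]
        selected = [i for i, rid in enumerate(ids) if rid in tags]
        for a, b in zip(selected, selected[1:]):
            gap = b - a - 1
            if 0 < gap <= params.max_gap:
                for i in range(a + 1, b):
                    add(ids[i], SelectionTag.CONNECTIVE)

    # 4. repair or drop short runs (iterate: extension can merge runs)
    changed = True
    while changed:
        changed = False
        for cid, chain in structure.chains.items():
            ids = [r.id for r in chain]
            selected = sorted(i for i, rid in enumerate(ids) if rid in tags)
            for run in _runs(selected):
                if len(run) >= params.min_fragment:
                    continue
                has_catalytic = any(ids[i] in catalytic_ids for i in run)
                if not has_catalytic:
                    for i in run:
                        del tags[ids[i]]
                    changed = True
                    continue
                left, right = run[0], run[-1]
                prefer_left = True  # alternate sides for a symmetric extension
                while right - left + 1 < params.min_fragment:
                    can_left, can_right = left > 0, right + 1 < len(ids)
                    if can_left and (prefer_left or not can_right):
                        left -= 1
                        add(ids[left], SelectionTag.CONNECTIVE)
                    elif can_right:
                        right += 1
                        add(ids[right], SelectionTag.CONNECTIVE)
                    else:  # chain shorter than min_fragment: keep it whole
                        break
                    prefer_left = not prefer_left
                    changed = True

    members = [
        (res.id, tags[res.id]) for res in structure.residues() if res.id in tags
    ]
    member_ids = {rid for rid, _ in members}
    missing = catalytic_ids - member_ids
    if missing:  # unreachable by construction; guard the contract anyway
        raise AssertionError(f"catalytic residue(s) dropped: {sorted(map(str, missing))}")
    return SubstructureSpec(entry_id=structure.entry_id, members=members, params=params)


def write_substructure(structure: Structure, spec: SubstructureSpec, path: str | Path) -> Path:
    """Write the substructure as a PDB file with a REMARK 999 provenance block."""
    if any(rid not in structure for rid in spec.ids()):
        raise ValueError(f"spec was not built from structure {structure.entry_id}")
    remarks = [
        f"ENTRY {spec.entry_id}",
        "PARAMS max_gap={p.max_gap} complete_sse={p.complete_sse} "
        "min_fragment={p.min_fragment}".format(p=spec.params),
    ]
    remarks += [
        f"TAG {rid.chain} {rid.number}{rid.icode or '.'} {tag.value}"
        for rid, tag in spec.members
    ]
    return write_pdb_subset(structure, spec.ids(), path, remarks=remarks)


def read_substructure_tags(path: str | Path) -> dict[ResidueID, SelectionTag]:
    """Parse the REMARK 999 TAG lines back into a tag assignment."""
    tags: dict[ResidueID, SelectionTag] = {}
    for line in Path(path).read_text().splitlines():
        if not line.startswith("REMARK 999 TAG "):
            continue
        _, _, _, chain, numicode, tag = line.split()
        if numicode.endswith("."):
            number, icode = int(numicode[:-1]), ""
        elif numicode[-1].isdigit():
            number, icode = int(numicode), ""
        else:
            number, icode = int(numicode[:-1]), numicode[-1]
        tags[ResidueID(chain, number, icode)] = SelectionTag(tag)
    return tags


def spec_to_json(spec: SubstructureSpec, path: str | Path) -> Path:
    """Companion JSON sidecar with the full selection and parameters."""
    payload = {
        "entry_id": spec.entry_id,
        "params": {
            "max_gap": spec.params.max_gap,
            "complete_sse": spec.params.complete_sse,
            "min_fragment": spec.params.min_fragment,
        },
        "members": [
            {"chain": rid.chain, "number": rid.number, "icode": rid.icode, "tag": tag.value}
            for rid, tag in spec.members
        ],
    }
    path = Path(path)
    path.write_text(json.dumps(payload, indent=2) + "\n")
    return path


def coverage_percentage(selected: int, total: int) -> int:
    """Substructure size as a percentage of the full structure, nearest integer."""
    return int(round(100.0 * selected / total)) if total else 0


def coverage_stats(spec: SubstructureSpec, structure: Structure) -> tuple[int, int, int]:
    """(selected residues, total residues, percentage rounded to nearest integer)."""
    selected = len(spec.members)
    total = len(structure)
    return selected, total, coverage_percentage(selected, total)
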