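"""Shared fixtures: tiny hand-built structures and generated inputs."""

from __future__ import annotations

import numpy as np
import pytest

from asitekit.fixtures import ToyStructureSpec, make_toy_enzyme
from asitekit.site_annotation import CatalyticResidue, SiteAnnotation
from asitekit.structure_model import Atom, Residue, ResidueID, Structure


def mini_structure(
    entries: list[tuple[str, int, str, tuple[float, float, float]]],
    entry_id: str = "mini",
) -> Structure:
    """Structure of single-CA residues at given coordinates: (chain, number, name, xyz)."""
    chains: dict[str, list[Residue]] = {}
    for chain, number, name, xyz in entries:
        res = Residue(
            ResidueID(chain, number), name, [Atom("CA", "C", np.array(xyz, dtype=float))]
        )
        chains.setdefault(chain, []).append(res)
    return Structure(entry_id=entry_id, chains=chains)


def coil_chain(n_res: int, chain: str = "A", entry_id: str = "coil") -> Structure:
    """n single-CA residues spaced 4 Å apart on a line — no assignable SSE."""
    return mini_structure(
        [(chain, i + 1, "ALA", (4.0 * i, 0.0, 0.0)) for i in range(n_res)], entry_id
    )


def annotation_for(structure: Structure, ids, role: str = "nucleophile") -> SiteAnnotation:
    residues = tuple(
        CatalyticResidue(rid, structure.get(rid).name, role, "user") for rid in ids
    )
    return SiteAnnotation(structure.entry_id, residues)


@pytest.fixture
def toy_enzyme():
    return make_toy_enzyme(ToyStructureSpec(seed=11))


@pytest.fixture
def coil60():
    return coil_chain(60)
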