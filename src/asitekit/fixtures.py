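"""Synthetic test structures and alignments with known ground truth.

Everything here is generated deterministically from a seed — no downloads,
no committed coordinate files.  Toy structures are ideal poly-helix bundles
built from internal coordinates (NeRF chain growth at fixed φ/ψ), which makes
their backbone dihedrals, inter-residue distances and distance shells exactly
known.  Synthetic alignments plant fully conserved columns on a stated
background composition, which makes the truth of every conservation rank
known.  Truth tables are computed with plain double loops, deliberately
independent of the library code they are used to check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .conservation_stats import AMINO_ACIDS, GAP, Alignment
from .structure_model import Atom, Residue, ResidueID, Structure

__all__ = [
    "ToyStructureSpec",
    "SyntheticAlignmentSpec",
    "make_chain_from_dihedrals",
    "make_ideal_helix",
    "make_toy_enzyme",
    "make_synthetic_alignment",
    "SHELL_RADII",
]

SHELL_RADII = (5.0, 7.0, 10.0, 15.0)

_AA3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}

# ideal backbone internal coordinates (Å, degrees)
_B_N_CA, _B_CA_C, _B_C_N = 1.458, 1.525, 1.329
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA = 111.2, 116.2, 121.7
_B_C_O, _A_CA_C_O = 1.231, 120.5
_B_CA_CB, _A_N_CA_CB, _T_C_N_CA_CB = 1.530, 110.5, 122.6
_OMEGA = 180.0


@dataclass(frozen=True)
class ToyStructureSpec:
    """Parallel helix bundle with planted catalytic residues."""

    n_helices: int = 2
    helix_length: int = 10
    separation: float = 8.0  # Å between adjacent helix axes
    catalytic_positions: tuple[tuple[int, int], ...] = ((0, 5),)  # (helix idx, residue number)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.helix_length < 4:
            raise ValueError("helix_length must be >= 4")
        if self.separation <= 0:
            raise ValueError("separation must be positive")
        if self.separation < 5.0:
            raise ValueError("helices closer than 5 Å overlap; increase separation")
        for h, r in self.catalytic_positions:
            if not 0 <= h < self.n_helices:
                raise ValueError(f"catalytic helix index {h} out of range")
            if not 1 <= r <= self.helix_length:
                raise ValueError(f"catalytic residue number {r} out of range")


@dataclass(frozen=True)
class SyntheticAlignmentSpec:
    """Alignment with planted fully conserved columns over a random background."""

    n_seqs: int = 12
    n_cols: int = 90
    planted_cols: tuple[int, ...] = tuple(range(10))  # 0-based column indices
    planted_residue: str | tuple[str, ...] = "S"
    background: tuple[float, ...] = field(default=tuple([0.05] * 20))  # over AMINO_ACIDS
    gap_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if len(set(self.planted_cols)) != len(self.planted_cols):
            raise ValueError("planted columns collide")
        if any(not 0 <= c < self.n_cols for c in self.planted_cols):
            raise ValueError("planted column index out of range")
        if not 0.0 <= self.gap_rate <= 0.5:
            raise ValueError("gap_rate must be in [0, 0.5]")
        if len(self.background) != 20 or abs(sum(self.background) - 1.0) > 1e-9:
            raise ValueError("background must be a composition over the 20 amino acids")

    def planted_letters(self) -> list[str]:
        if isinstance(self.planted_residue, str):
            return [self.planted_residue] * len(self.planted_cols)
        return list(self.planted_residue)


# ---------------------------------------------------------------------------
# Backbone construction (NeRF)
# ---------------------------------------------------------------------------


def _place(
    a: np.ndarray, b: np.ndarray, c: np.ndarray, bond: float, angle: float, torsion: float
) -> np.ndarray:
    """Next atom position from three predecessors and internal coordinates."""
    ang = math.radians(angle)
    tor = math.radians(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array(
        [
            -bond * math.cos(ang),
            bond * math.sin(ang) * math.cos(tor),
            bond * math.sin(ang) * math.sin(tor),
        ]
    )
    return c + d[0] * bc + d[1] * m + d[2] * n


def make_chain_from_dihedrals(
    phi: float,
    psi: float,
    n_res: int,
    sequence: str | None = None,
    chain_id: str = "A",
    first_number: int = 1,
) -> Structure:
    """Grow an ideal backbone (N, CA, C, O + CB) at constant φ/ψ, ω = 180°.

    φ = −57°, ψ = −47° yields an ideal α-helix (rise ≈ 1.5 Å per residue,
    twist ≈ 100°, consecutive CA–CA ≈ 3.8 Å); φ = −120°, ψ = +130° an
    extended strand.  Glycines carry no CB.
    """
    if n_res < 4:
        raise ValueError("need at least 4 residues")
    if sequence is None:
        sequence = "A" * n_res
    if len(sequence) != n_res:
        raise ValueError("sequence length must equal n_res")

    # seed triad for residue 1
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([_B_N_CA, 0.0, 0.0])
    ang = math.radians(180.0 - _A_N_CA_C)
    c0 = ca0 + _B_CA_C * np.array([math.cos(ang), math.sin(ang), 0.0])

    backbone: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = [(n0, ca0, c0)]
    for _ in range(1, n_res):
        n_prev, ca_prev, c_prev = backbone[-1]
        n_i = _place(n_prev, ca_prev, c_prev, _B_C_N, _A_CA_C_N, psi)
        ca_i = _place(ca_prev, c_prev, n_i, _B_N_CA, _A_C_N_CA, _OMEGA)
        c_i = _place(c_prev, n_i, ca_i, _B_CA_C, _A_N_CA_C, phi)
        backbone.append((n_i, ca_i, c_i))

    residues: list[Residue] = []
    for i, (n_i, ca_i, c_i) in enumerate(backbone):
        atoms = [
            Atom("N", "N", n_i),
            Atom("CA", "C", ca_i),
            Atom("C", "C", c_i),
        ]
        # carbonyl O, anti to the next N (or to the chain direction at the C-terminus)
        o_tor = psi + 180.0 if i + 1 < n_res else 180.0
        atoms.append(Atom("O", "O", _place(n_i, ca_i, c_i, _B_C_O, _A_CA_C_O, o_tor)))
        letter = sequence[i]
        if letter != "G":
            prev_c = backbone[i - 1][2] if i > 0 else c_i + np.array([0.0, 0.0, 1.0])
            atoms.append(
                Atom("CB", "C", _place(prev_c, n_i, ca_i, _B_CA_CB, _A_N_CA_CB, _T_C_N_CA_CB))
            )
        rid = ResidueID(chain_id, first_number + i)
        residues.append(Residue(rid, _AA3[letter], atoms))
    return Structure(entry_id="chain", chains={chain_id: residues})


def make_ideal_helix(n_res: int, sequence: str | None = None, chain_id: str = "A") -> Structure:
    """Ideal α-helix; its dihedrals fall inside the helix assignment window."""
    st = make_chain_from_dihedrals(-57.0, -47.0, n_res, sequence, chain_id=chain_id)
    st.entry_id = "helix"
    return st


# ---------------------------------------------------------------------------
# Toy enzyme with brute-force truth
# ---------------------------------------------------------------------------


def _brute_force_truth(
    structure: Structure, catalytic: set[ResidueID]
) -> dict:
    """Distance table and shell membership, plain double loops on purpose."""
    residues = list(structure.residues())
    heavy = {
        r.id: [a.coords for a in r.atoms if a.element.upper() not in ("H", "D")]
        for r in residues
    }
    distances: dict[tuple[ResidueID, ResidueID], float] = {}
    for i in range(len(residues)):
        for j in range(i + 1, len(residues)):
            ri, rj = residues[i], residues[j]
            best = float("inf")
            for a in heavy[ri.id]:
                for b in heavy[rj.id]:
                    d = math.dist(a, b)
                    if d < best:
                        best = d
            distances[(ri.id, rj.id)] = best

    def dist(a: ResidueID, b: ResidueID) -> float:
        if a == b:
            return 0.0
        return distances.get((a, b), distances.get((b, a)))

    shells: dict[float, set[ResidueID]] = {}
    for radius in SHELL_RADII:
        members = set(catalytic)
        for r in residues:
            for c in catalytic:
                if dist(r.id, c) <= radius:
                    members.add(r.id)
                    break
        shells[radius] = members
    return {"distances": distances, "shells": shells}


def make_toy_enzyme(spec: ToyStructureSpec) -> tuple[Structure, dict]:
    """Parallel helix bundle plus its brute-force distance/shell truth tables.

    Helix k lives on chain chr('A'+k), residues numbered 1..helix_length, and
    is translated k*separation Å along x.  Sequences are drawn uniformly from
    the 20 amino acids using the spec seed.  The truth dict holds the all-pairs
    minimum heavy-atom distance table and the shell membership (lining) of the
    planted catalytic set at radii 5, 7, 10 and 15 Å.
    """
    rng = np.random.default_rng(spec.seed)
    chains: dict[str, list[Residue]] = {}
    for k in range(spec.n_helices):
        cid = chr(ord("A") + k)
        seq = "".join(rng.choice(list(AMINO_ACIDS), size=spec.helix_length))
        helix = make_ideal_helix(spec.helix_length, sequence=seq, chain_id=cid)
        shifted = helix.translated([k * spec.separation, 0.0, 0.0])
        chains[cid] = shifted.chains[cid]
    structure = Structure(entry_id=f"toy{spec.seed}", chains=chains)
    catalytic = {
        ResidueID(chr(ord("A") + h), r) for h, r in spec.catalytic_positions
    }
    truth = _brute_force_truth(structure, catalytic)
    truth["catalytic"] = catalytic
    return structure, truth


# ---------------------------------------------------------------------------
# Synthetic alignments
# ---------------------------------------------------------------------------


def make_synthetic_alignment(spec: SyntheticAlignmentSpec) -> tuple[Alignment, dict]:
    """Random alignment with planted fully conserved (never gapped) columns.

    Background cells draw a residue from the stated composition and are then
    gapped with probability ``gap_rate``.  The truth dict carries the planted
    column indices and a per-column boolean mask.
    """
    rng = np.random.default_rng(spec.seed)
    letters = np.array(list(AMINO_ACIDS))
    planted = dict(zip(spec.planted_cols, spec.planted_letters()))
    rows: list[str] = []
    for _ in range(spec.n_seqs):
        draw = rng.choice(letters, size=spec.n_cols, p=spec.background)
        gaps = rng.random(spec.n_cols) < spec.gap_rate
        cells = np.where(gaps, GAP, draw)
        for col, letter in planted.items():
            cells[col] = letter
        rows.append("".join(cells))
    ids = [f"seq{i + 1:02d}" for i in range(spec.n_seqs)]
    alignment = Alignment(ids=ids, rows=rows, ref_id=ids[0])
    mask = np.zeros(spec.n_cols, dtype=bool)
    mask[list(spec.planted_cols)] = True
    truth = {"planted_cols": sorted(spec.planted_cols), "planted_mask": mask}
    return alignment, truth
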