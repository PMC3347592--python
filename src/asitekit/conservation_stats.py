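"""Column conservation statistics for multiple alignments.

The pipeline ranks alignment columns by evolutionary conservation and attaches
significance levels, following the Valdar–Thornton / Vingron–Argos tradition:

* Sequences are weighted by their mean pairwise "genetic" distance
  d(i, j) = 1 − identity(i, j), so redundant sequences are down-weighted
  (Vingron–Argos weights, rescaled to mean 1).

* A column's conservation is the weighted average pairwise similarity

      C_I = γ · Σ_{i<j} w_i w_j M(s_i, s_j),     γ = 1 / Σ_{i<j} w_i w_j,

  with a substitution matrix M normalized to unit diagonal and clipped to
  [0, 1], so C ∈ [0, 1] and C = 1 exactly for a fully conserved, ungapped
  column.  Pairs involving a gap contribute similarity 0 but stay in γ's
  denominator, so gapped columns are penalized.

* Scores are standardized against a null of randomly assembled columns:
  each null column draws, independently per sequence, a residue from a
  uniformly random position of that same sequence, preserving per-row
  composition (including gaps).  One shared null serves all columns, so
  identical columns receive identical Z-scores.

* Significance is assessed with a Bernoulli rank-order (B-cutoff) statistic:
  with Z-scores sorted in decreasing order, the rank-i p-value is the
  binomial upper tail P(X ≥ i) with n trials (the total column count) and
  per-trial success probability Φ̄(z_i), the standard-normal upper tail at
  that rank's score.  The significant set is the longest prefix of ranks
  whose P stays below α.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio import AlignIO
from Bio.Align import substitution_matrices
from scipy.stats import binom, norm

__all__ = [
    "AMINO_ACIDS",
    "GAP",
    "Alignment",
    "SubstitutionMatrix",
    "NullModel",
    "ColumnScore",
    "RankRow",
    "RankTable",
    "read_alignment",
    "pairwise_identity",
    "distance_matrix",
    "vingron_argos_weights",
    "valdar_thornton_column_score",
    "column_scores",
    "null_model",
    "z_scores",
    "bcutoff_pvalues",
    "calibrate_total_columns",
    "significance_cutoff",
    "conservation_report",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
_ALPHABET = AMINO_ACIDS + GAP
_CODE = {aa: i for i, aa in enumerate(_ALPHABET)}
_GAP_CODE = _CODE[GAP]


@dataclass
class Alignment:
    """A multiple alignment over the 20 amino acids plus the gap character."""

    ids: list[str]
    rows: list[str]
    ref_id: str | None = None

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if len(self.rows) < 2:
            raise ValueError("an alignment needs at least 2 sequences")
        width = len(self.rows[0])
        for sid, row in zip(self.ids, self.rows):
            if len(row) != width:
                raise ValueError(f"sequence {sid}: length {len(row)} != {width}")
            bad = set(row) - set(_ALPHABET)
            if bad:
                raise ValueError(f"sequence {sid}: illegal characters {sorted(bad)}")
        if self.ref_id is not None and self.ref_id not in self.ids:
            raise ValueError(f"reference id {self.ref_id!r} not among sequence ids")

    @property
    def n_seqs(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0])

    def column(self, j: int) -> str:
        return "".join(row[j] for row in self.rows)

    def codes(self) -> np.ndarray:
        """(n_seqs, n_cols) integer encoding; gap = 20."""
        return np.array([[_CODE[c] for c in row] for row in self.rows], dtype=np.int8)


def read_alignment(path: str | Path, fmt: str | None = None, ref_id: str | None = None) -> Alignment:
    """Read a FASTA or Clustal alignment (format sniffed from the first line)."""
    path = Path(path)
    if fmt is None:
        first = path.read_text().lstrip()[:1]
        fmt = "fasta" if first == ">" else "clustal"
    msa = AlignIO.read(str(path), fmt)
    ids = [rec.id for rec in msa]
    rows = [str(rec.seq).upper().replace(".", GAP) for rec in msa]
    return Alignment(ids=ids, rows=rows, ref_id=ref_id)


@dataclass
class SubstitutionMatrix:
    """Symmetric similarity matrix over amino-acid pairs, unit diagonal, in [0, 1]."""

    entries: np.ndarray  # (20, 20), indexed by AMINO_ACIDS order
    name: str = "custom"

    def __post_init__(self) -> None:
        m = np.asarray(self.entries, dtype=float)
        if m.shape != (20, 20):
            raise ValueError("substitution matrix must be 20x20")
        if not np.allclose(m, m.T):
            raise ValueError("substitution matrix must be symmetric")
        if not np.allclose(np.diag(m), 1.0):
            raise ValueError("substitution matrix must have a unit diagonal")
        if m.min() < -1e-12 or m.max() > 1 + 1e-12:
            raise ValueError("substitution matrix entries must lie in [0, 1]")
        self.entries = np.clip(m, 0.0, 1.0)

    @classmethod
    def from_blosum(cls, name: str = "BLOSUM62") -> "SubstitutionMatrix":
        """Log-odds matrix normalized to M'(a,b) = M(a,b)/sqrt(M(a,a) M(b,b)), clipped to [0,1].

        The normalization forces a unit diagonal, so every fully conserved
        column attains the same maximal conservation score regardless of the
        residue type.
        """
        raw = substitution_matrices.load(name.upper())
        m = np.empty((20, 20))
        for i, a in enumerate(AMINO_ACIDS):
            for j, b in enumerate(AMINO_ACIDS):
                m[i, j] = raw[a, b]
        diag = np.sqrt(np.diag(m))
        m = m / np.outer(diag, diag)
        np.fill_diagonal(m, 1.0)
        return cls(entries=np.clip(m, 0.0, 1.0), name=name.lower())

    def padded(self) -> np.ndarray:
        """(21, 21) lookup with zero similarity for any pair involving a gap."""
        out = np.zeros((21, 21))
        out[:20, :20] = self.entries
        return out


@dataclass(frozen=True)
class ColumnScore:
    C: float
    gamma: float

    def __post_init__(self) -> None:
        if not -1e-9 <= self.C <= 1 + 1e-9:
            raise ValueError(f"conservation score {self.C} outside [0, 1]")


@dataclass(frozen=True)
class NullModel:
    n_samples: int
    seed: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n_samples < 100:
            raise ValueError("null model needs at least 100 samples")
        if not self.sd > 0:
            raise ValueError(
                "null score distribution has zero spread (every random column scores "
                "identically); Z-scores are undefined for this alignment"
            )


# ---------------------------------------------------------------------------
# Weights
# ---------------------------------------------------------------------------


def pairwise_identity(row_i: str, row_j: str) -> float:
    """Fraction of identical compared positions.

    Positions gapped in both rows are excluded; gap-vs-residue counts as a
    compared mismatch.  Two all-gap rows have no compared positions and
    return identity 0 (maximally uninformative).
    """
    if len(row_i) != len(row_j):
        raise ValueError(f"length mismatch: {len(row_i)} vs {len(row_j)}")
    compared = matches = 0
    for a, b in zip(row_i, row_j):
        if a == GAP and b == GAP:
            continue
        compared += 1
        if a == b:
            matches += 1
    return matches / compared if compared else 0.0


def distance_matrix(alignment: Alignment) -> np.ndarray:
    """Pairwise genetic distances d(i, j) = 1 − identity(i, j)."""
    n = alignment.n_seqs
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = 1.0 - pairwise_identity(alignment.rows[i], alignment.rows[j])
    return d


def vingron_argos_weights(alignment: Alignment) -> np.ndarray:
    """Distance-proportional sequence weights, rescaled to mean 1.

    w_i is the mean genetic distance of sequence i to all others, so outliers
    are up-weighted and near-duplicates down-weighted.  If all distances are
    zero (identical sequences) the weights degenerate to uniform.
    """
    if alignment.n_seqs < 2:
        raise ValueError("weights need at least 2 sequences")
    d = distance_matrix(alignment)
    n = alignment.n_seqs
    raw = d.sum(axis=1) / (n - 1)
    if raw.sum() == 0.0:
        return np.ones(n)
    return raw * n / raw.sum()


# ---------------------------------------------------------------------------
# Column scores
# ---------------------------------------------------------------------------


def _pair_products(weights: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n = len(weights)
    iu, ju = np.triu_indices(n, k=1)
    return iu, ju, weights[iu] * weights[ju]


def valdar_thornton_column_score(
    column: str | Sequence[str], weights: np.ndarray, matrix: SubstitutionMatrix
) -> ColumnScore:
    """Weighted average pairwise similarity of one alignment column.

    All-gap columns score 0 by convention.  Gap-containing pairs contribute
    similarity 0 while remaining in the normalization, so partial gapping
    lowers the score smoothly.
    """
    column = "".join(column)
    weights = np.asarray(weights, dtype=float)
    if len(column) != len(weights):
        raise ValueError("column length must equal the number of weights")
    if np.any(weights < 0) or not np.any(weights > 0):
        raise ValueError("weights must be non-negative and not all zero")
    codes = np.array([_CODE[c] for c in column])
    iu, ju, ww = _pair_products(weights)
    denom = ww.sum()
    if denom <= 0:
        raise ValueError("weighted pair sum is zero; cannot normalize")
    gamma = 1.0 / denom
    m = matrix.padded()
    c = gamma * float((ww * m[codes[iu], codes[ju]]).sum())
    return ColumnScore(C=min(max(c, 0.0), 1.0), gamma=gamma)


def column_scores(
    alignment: Alignment, weights: np.ndarray, matrix: SubstitutionMatrix
) -> np.ndarray:
    """Conservation score of every column (vectorized over the pair list)."""
    codes = alignment.codes()
    return _scores_for_codes(codes, np.asarray(weights, dtype=float), matrix)


def _scores_for_codes(
    codes: np.ndarray, weights: np.ndarray, matrix: SubstitutionMatrix
) -> np.ndarray:
    iu, ju, ww = _pair_products(weights)
    denom = ww.sum()
    if denom <= 0:
        raise ValueError("weighted pair sum is zero; cannot normalize")
    m = matrix.padded()
    sims = m[codes[iu, :], codes[ju, :]]  # (n_pairs, n_cols)
    return np.clip((ww[:, None] * sims).sum(axis=0) / denom, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Null model and Z-scores
# ---------------------------------------------------------------------------


def null_model(
    alignment: Alignment,
    weights: np.ndarray,
    matrix: SubstitutionMatrix,
    n_samples: int = 10000,
    seed: int = 0,
) -> NullModel:
    """Score distribution of randomly assembled columns.

    Each null column draws, independently for every sequence, the residue at
    a uniformly random column of that same sequence — preserving per-row
    composition including gaps.  A single null is shared by all columns.
    """
    if n_samples < 100:
        raise ValueError("n_samples must be at least 100")
    rng = np.random.default_rng(seed)
    codes = alignment.codes()
    n_seqs, n_cols = codes.shape
    idx = rng.integers(0, n_cols, size=(n_seqs, n_samples))
    null_columns = codes[np.arange(n_seqs)[:, None], idx]
    scores = _scores_for_codes(null_columns, np.asarray(weights, dtype=float), matrix)
    return NullModel(
        n_samples=n_samples, seed=seed, mean=float(scores.mean()), sd=float(scores.std(ddof=1))
    )


def z_scores(
    alignment: Alignment,
    weights: np.ndarray,
    matrix: SubstitutionMatrix,
    null: NullModel,
) -> np.ndarray:
    """Standardized conservation per column: Z_I = (C_I − μ_null) / σ_null."""
    c = column_scores(alignment, weights, matrix)
    return (c - null.mean) / null.sd


# ---------------------------------------------------------------------------
# B-cutoff rank-order significance
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RankRow:
    rank: int
    z: float
    p_tail: float  # per-trial success probability Φ̄(z)
    P: float  # binomial upper tail P(X >= rank)
    label: str
    column: str


@dataclass
class RankTable:
    rows: list[RankRow]
    n: int  # total number of scored columns (binomial trial count)
    alpha: float = 0.05
    cutoff_rank: int = field(init=False, default=0)

    def __post_init__(self) -> None:
        self.cutoff_rank = significance_cutoff(self, self.alpha)

    def to_tsv(self, path: str | Path | None = None) -> str:
        lines = ["Rank\tZ-score\tp-value\tPosition\tAlignment column content"]
        for r in self.rows:
            lines.append(f"{r.rank}\t{r.z:.6f}\t{r.P:.6E}\t{r.label}\t{r.column}")
        text = "\n".join(lines) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "n_columns": self.n,
            "alpha": self.alpha,
            "cutoff_rank": self.cutoff_rank,
            "rows": [
                {
                    "rank": r.rank,
                    "z_score": r.z,
                    "tail_probability": r.p_tail,
                    "p_value": r.P,
                    "position": r.label,
                    "column": r.column,
                }
                for r in self.rows
            ],
        }
        text = json.dumps(payload, indent=2) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text


def bcutoff_pvalues(
    zvec: Sequence[float],
    n: int | None = None,
    labels: Sequence[str] | None = None,
    columns: Sequence[str] | None = None,
    alpha: float = 0.05,
) -> RankTable:
    """Bernoulli rank-order p-values for a vector of Z-scores.

    Z-scores are sorted in decreasing order (stable: ties keep input order).
    For rank i, P_i = P(X ≥ i) where X ~ Binomial(n, Φ̄(z_(i))) — the chance
    that i or more of n random columns reach that rank's score.  ``n``
    defaults to len(zvec) but may be larger when only the top scores of a
    bigger column set are supplied.  Evaluated through the binomial survival
    function, which stays accurate for tail probabilities down to ~1e-12.
    """
    z = np.asarray(zvec, dtype=float)
    if z.size == 0:
        raise ValueError("empty Z-score vector")
    if not np.all(np.isfinite(z)):
        raise ValueError("non-finite Z-score")
    if n is None:
        n = z.size
    if n < z.size:
        raise ValueError(f"n={n} smaller than the number of scores ({z.size})")
    order = np.argsort(-z, kind="stable")
    rows: list[RankRow] = []
    for rank, idx in enumerate(order, start=1):
        p = float(norm.sf(z[idx]))
        P = float(binom.sf(rank - 1, n, p))
        rows.append(
            RankRow(
                rank=rank,
                z=float(z[idx]),
                p_tail=p,
                P=P,
                label=labels[idx] if labels is not None else str(idx + 1),
                column=columns[idx] if columns is not None else "",
            )
        )
    return RankTable(rows=rows, n=n, alpha=alpha)


def calibrate_total_columns(z1: float, P1: float) -> int:
    """Recover the binomial trial count n from a rank-1 score and its p-value.

    The rank-1 p-value is P(X ≥ 1) = 1 − (1 − Φ̄(z1))^n, so
    n = log(1 − P1) / log(1 − Φ̄(z1)), rounded to the nearest integer.
    Useful when a published ranking prints only its top scores.
    """
    q = float(norm.sf(z1))
    if not 0 < q < 1 or not 0 < P1 < 1:
        raise ValueError("z1 and P1 must give tail probabilities strictly inside (0, 1)")
    return int(round(math.log1p(-P1) / math.log1p(-q)))


def significance_cutoff(table: RankTable, alpha: float = 0.05) -> int:
    """Largest k such that every rank up to k has P ≤ α (longest significant prefix)."""
    k = 0
    for row in table.rows:
        if row.P <= alpha:
            k = row.rank
        else:
            break
    return k


# ---------------------------------------------------------------------------
# End-to-end report
# ---------------------------------------------------------------------------


def _reference_labels(alignment: Alignment) -> list[str]:
    """Per-column position labels in reference-sequence numbering.

    Columns where the reference holds a residue get "<number><letter>"
    (numbering counts reference residues only, skipping its gaps); columns
    where the reference is gapped get an insertion label "ins<column>".
    Without a reference, labels are 1-based column indices.
    """
    if alignment.ref_id is None:
        return [str(j + 1) for j in range(alignment.n_cols)]
    ref_row = alignment.rows[alignment.ids.index(alignment.ref_id)]
    labels: list[str] = []
    resnum = 0
    for j, c in enumerate(ref_row):
        if c == GAP:
            labels.append(f"ins{j + 1}")
        else:
            resnum += 1
            labels.append(f"{resnum}{c}")
    return labels


def conservation_report(
    alignment: Alignment,
    matrix: SubstitutionMatrix | None = None,
    n_samples: int = 10000,
    seed: int = 0,
    alpha: float = 0.05,
) -> RankTable:
    """Full pipeline: weights → column scores → null → Z → B-cutoff ranking."""
    if matrix is None:
        matrix = SubstitutionMatrix.from_blosum("BLOSUM62")
    weights = vingron_argos_weights(alignment)
    null = null_model(alignment, weights, matrix, n_samples=n_samples, seed=seed)
    z = z_scores(alignment, weights, matrix, null)
    labels = _reference_labels(alignment)
    columns = [alignment.column(j) for j in range(alignment.n_cols)]
    return bcutoff_pvalues(z, n=alignment.n_cols, labels=labels, columns=columns, alpha=alpha)
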