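# Methods

## Scope and model

`asitekit` implements a three-step procedure for isolating an enzyme's
active-site substructure from a crystal structure, plus the statistics used
to compare such substructures across remote homologues through a multiple
alignment. Homologue gathering, multiple-alignment computation and
visualization are upstream/downstream of the package: alignments and
catalytic-residue annotations are inputs.

### Step 1 — catalytic residues

A residue is treated as catalytic if it is directly involved in the catalytic
mechanism (nucleophile), modulates the acid-base properties of another
active-site residue or an ordered water, or stabilizes the transition state
or intermediate. The package does not predict such residues; it loads them
from a CSA-style TSV (`entry_id, chain, resnum, icode, resname, role,
evidence`) covering both database exports and manual curation, and validates
them against the structure (existence and residue identity). Validation
failures abort: catalytic residues anchor every later step, so silently
dropping one would corrupt the result. Where an annotation database offers
both hand-annotated and homology-transferred sites, both are representable
through the `evidence` field; the package records provenance and leaves
conflict resolution to the user.

### Step 2 — cavity-lining residues

Substrate binding happens in pockets and cavities, and residues affecting
specificity and activity are empirically found within 7–15 Å of the key
catalytic residues. Pocket detection is a pluggable contract with two
built-in modes:

* **shell** (default): all residues with a heavy atom within `radius` Å
  (default 10.0, the midpoint of the 7–15 Å range) of any catalytic residue,
  by minimum heavy-atom distance. Deterministic, parameter-light, monotone
  in the radius.
* **grid**: a buriedness grid in the LIGSITE tradition. Cell centers sit at
  integer multiples of `grid_spacing` (default 1.0 Å) over the heavy-atom
  bounding box padded by 5 Å — snapping to multiples makes the result
  invariant under translations by whole grid steps. A cell is occupied
  within `occupied_radius` (2.5 Å) of a heavy atom. An empty cell is a
  pocket cell if at least `psp_min` (default 3) of the 7 scan direction
  pairs (3 axes + 4 cube diagonals) hit protein on both sides
  (protein–solvent–protein events). Pocket cells are clustered by
  6-connectivity; clusters with a cell within `lining_cutoff` (4.0 Å) of the
  catalytic machinery are kept — all of them, not just the largest, since
  the choice of a single "best" pocket would be arbitrary — and the lining
  is every residue with a heavy atom within `lining_cutoff` of a kept cell.

Both modes always include the catalytic seeds. All geometry uses heavy atoms
only (crystal structures typically lack hydrogens).

### Step 3 — substructure assembly

Catalytic and lining residues are merged into contiguous fragments:
selection is seeded with catalytic ∪ lining (tag precedence
catalytic > binding > connective); every intersected secondary-structure
element is completed wholesale when `complete_sse` is on (whole elements
rather than partial stretches — switchable, since either reading of
"surrounding residues" is defensible); sequence gaps of at most `max_gap`
(default 3) are bridged; and fragments shorter than `min_fragment`
(default 3) are repaired. The repair rule is a deliberate tie-break between
two readings of "extend when possible, else drop": a short run containing a
catalytic residue is extended symmetrically with flanking residues
(catalytic runs are never dropped — the catalytic machinery is the point of
the comparison); a short run without one is dropped as a structurally
meaningless orphan. This choice also keeps the selection monotone in the
pocket: enlarging the lining can only merge or extend runs, never shorten
them. Defaults `max_gap = 3`, `min_fragment = 3` are the smallest values
that prevent single-residue orphans.

The output PDB keeps author numbering and chain order unchanged, closes
chains with TER, and carries a REMARK 999 block (entry, parameters,
per-residue tags) making the file self-describing; a JSON sidecar holds the
same selection machine-readably.

### Structure model

One model per entry (the first by default; crystal structures are treated
as single conformers). Alternate locations resolve to the highest-occupancy
conformer (ties: first in file). Waters and HETATM are excluded — the method
operates on amino-acid residues. File HELIX/SHEET records are authoritative;
residues they do not cover are assigned by a P-SEA-like φ/ψ-window rule
(helix: φ ∈ [−90°, −30°], ψ ∈ [−77°, −17°]; strand: φ ∈ [−150°, −90°],
ψ ∈ [90°, 170°]; runs of ≥ 3 residues; chain-terminal residues are
classified on their single defined angle). The windows are generous enough
to capture ideal geometries and are exercised against fixtures built from
internal coordinates at exactly those dihedrals.

## Conservation statistics

* **Distances and weights.** Pairwise identity counts positions gapped in
  both rows as not compared and gap-vs-residue as a compared mismatch;
  d = 1 − identity. Vingron–Argos weights are each sequence's mean distance
  to the others, rescaled to mean 1; all-identical sequences degenerate to
  uniform weights.
* **Column score.** C_I = γ Σ_{i<j} w_i w_j M(s_i, s_j) with
  γ = 1/Σ_{i<j} w_i w_j. Pairs involving a gap contribute similarity 0 but
  remain in γ's denominator; all-gap columns score 0 by convention. With
  the unit-diagonal matrix this bounds C in [0, 1] with C = 1 exactly for
  fully conserved ungapped columns.
* **Substitution matrix.** BLOSUM62 normalized to
  M′(a,b) = M(a,b)/√(M(a,a)M(b,b)), clipped to [0, 1]. The unit diagonal is
  forced by the requirement that all fully conserved columns share one
  maximal score regardless of residue type.
* **Null model.** Each of `n_samples` (default 10 000) random columns draws,
  independently per sequence, the residue at a uniformly random column of
  that same sequence, preserving per-row composition including gaps.
  Alignment-wide draws were rejected because they destroy per-sequence gap
  structure. One null is shared by the whole alignment so that identical
  columns receive identical Z — a per-column null would break that. A null
  with zero spread (every random column scores the same) is an error, not a
  silent degenerate Z.
* **B-cutoff.** Z-scores sorted decreasing (stable ties); rank-i p-value is
  the binomial upper tail P(X ≥ i) at n trials with success probability
  Φ̄(z_i), evaluated via the survival functions of scipy (erfc-quality
  normal tail; a naive 1 − CDF underflows near Z ≈ 5.9, and a Poisson
  approximation is inadequate at the mid ranks). The significant set is the
  longest prefix with P ≤ α; no additional multiple-testing correction is
  layered on top, as the rank-order procedure is itself the correction.
  When only the top of a ranking is available, the trial count n is
  recoverable from the rank-1 row via P₁ = 1 − (1 − Φ̄(z₁))ⁿ
  (`calibrate_total_columns`).
* **Position labels.** With a reference sequence set, columns are labelled
  `<residue number><letter>` counting reference residues only; columns where
  the reference is gapped get an `ins<column>` insertion label (the
  reference cannot name them). Without a reference, 1-based column indices.

## Synthetic data

Test structures are parallel bundles of ideal helices grown from internal
coordinates (N–CA 1.458 Å, CA–C 1.525 Å, C–N 1.329 Å; τ(N-CA-C) 111.2°;
ω = 180°; φ/ψ = −57°/−47° for helices), with CB on non-glycines and
sequences drawn uniformly from the 20 amino acids. They exercise every
geometric predicate exactly — all-pairs distance tables and shell
memberships at 5/7/10/15 Å ship with each structure, computed by plain
double loops kept deliberately independent of the library code — but they
are not realistic proteins: no side chains beyond CB, no packing
irregularities, no B-factor or occupancy noise, no insertion codes. Passing
geometry tests therefore demonstrates correctness of the predicates, not
robustness to crystallographic pathology (which enters only through the
altloc/HETATM handling of the parser).

Synthetic alignments (defaults: 12 sequences × 90 columns, 10 planted fully
conserved never-gapped columns, uniform background over the 20 amino acids,
5% gap rate) mirror the scale of a curated active-site alignment of remote
homologues. They lack phylogenetic correlation between sequences —
background columns are i.i.d. — so recovery of planted columns shows the
pipeline separates full conservation from uncorrelated background at this
size; it does not measure sensitivity to partial conservation under real
evolutionary covariance.

## Numerical choices and degenerate inputs

* Stable sorts everywhere ranking matters; ties keep input order.
* Distance-shell and grid computations use KD-trees; the grid refuses more
  than 10⁷ cells and suggests a coarser spacing.
* Empty residue selections, empty catalytic sets, all-gap alignments,
  sub-3-residue chains and zero-spread nulls are rejected with specific
  errors rather than producing empty or NaN output.
* Problem sizes in the test suite (50 geometry fixtures, 200 builder runs,
  100 statistics runs at 10 000 null samples) keep the full suite under
  roughly a minute while giving the stochastic checks comfortable margins.

## Known limitations

* mmCIF, multi-model ensembles, hydrogens and ligand-defined pockets are out
  of scope; the grid mode is a buriedness heuristic, not an alpha-shape
  cavity computation, and computes no volumes or areas.
* The published case-study numbers that depend on third-party programs
  (structure-similarity searches, structural aligners, the original cavity
  program) and on external PDB entries — pairwise identities 7.8/12.4/13.7%,
  161/408 alignable residues, extracted sizes 170/287/159 — are shipped as
  declared metadata (`asitekit.case_study`), with only their internal
  arithmetic checked. The exact Z magnitudes of the published table depend
  on the authors' unpublished 19-sequence alignment and null draw and are
  not reproduced; the rank-order p-value layer on top of them is, to ~10⁻⁵
  relative.
* The exact gap treatment inside the original study's conservation score is
  not recoverable from its text; the package's convention (gap pairs score
  0 but stay in the normalization) is the canonical one and is validated
  indirectly through the p-value reconstruction.
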