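"""Rank alignment columns by conservation and mark the significant prefix.

Generates a synthetic 12-sequence alignment with 10 planted fully conserved
columns over a uniform background, then runs the full statistics pipeline:
sequence weights, weighted column conservation scores, a shuffled-column
null, Z-scores, and Bernoulli rank-order p-values.
"""

from asitekit import SyntheticAlignmentSpec, conservation_report, make_synthetic_alignment

alignment, truth = make_synthetic_alignment(
    SyntheticAlignmentSpec(n_seqs=12, n_cols=90, planted_cols=tuple(range(10)),
                           gap_rate=0.05, seed=21)
)
table = conservation_report(alignment, n_samples=10000, seed=17, alpha=0.01)

print(f"{alignment.n_seqs} sequences x {alignment.n_cols} columns; "
      f"planted conserved columns: {truth['planted_cols']}")
print("Rank  Z-score    p-value       Position")
for row in table.rows[:12]:
    print(f"{row.rank:>4d}  {row.z:8.4f}  {row.P:.6E}  {row.label}")
print(f"significant prefix at alpha=0.01: ranks 1..{table.cutoff_rank}")
print("The planted columns share one maximal Z (identical columns always do, since")
print("one null serves the whole alignment) and fall inside the significant prefix;")
print("background columns fall outside it.")
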