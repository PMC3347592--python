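"""Conservation statistics: weights, column scores, null model, B-cutoff ranking."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm

from asitekit.conservation_stats import (
    AMINO_ACIDS,
    Alignment,
    NullModel,
    SubstitutionMatrix,
    bcutoff_pvalues,
    calibrate_total_columns,
    column_scores,
    conservation_report,
    null_model,
    pairwise_identity,
    read_alignment,
    significance_cutoff,
    valdar_thornton_column_score,
    vingron_argos_weights,
    z_scores,
)
from asitekit.fixtures import SyntheticAlignmentSpec, make_synthetic_alignment

BLOSUM = SubstitutionMatrix.from_blosum("BLOSUM62")

aligned_pair = st.integers(5, 30).flatmap(
    lambda n: st.tuples(
        st.text(alphabet=AMINO_ACIDS + "-", min_size=n, max_size=n),
        st.text(alphabet=AMINO_ACIDS + "-", min_size=n, max_size=n),
    )
)


class TestPairwiseIdentity:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("ACDE", "ACDE", 1.0),
            ("ACDE", "ACDK", 0.75),
            ("AC-E", "ACDE", 0.75),  # gap vs residue is a compared mismatch
            ("A--E", "A--E", 1.0),  # double gaps are excluded from comparison
        ],
    )
    def test_examples(self, a, b, expected):
        assert pairwise_identity(a, b) == pytest.approx(expected)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            pairwise_identity("ACD", "AC")

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(aligned_pair)
    def test_symmetric_and_bounded(self, pair):
        a, b = pair
        ident = pairwise_identity(a, b)
        assert 0.0 <= ident <= 1.0
        assert pairwise_identity(b, a) == pytest.approx(ident)


class TestVingronArgosWeights:
    def test_identical_pair_degenerates_to_uniform(self):
        aln = Alignment(ids=["a", "b"], rows=["ACDE", "ACDE"])
        assert np.allclose(vingron_argos_weights(aln), [1.0, 1.0])

    def test_outlier_gets_largest_weight(self):
        aln = Alignment(ids=["a", "b", "c"], rows=["ACDEFGHI", "ACDEFGHI", "ACDEWYWY"])
        w = vingron_argos_weights(aln)
        assert w[2] > w[0] == pytest.approx(w[1])

    def test_matches_double_loop_oracle(self):
        rows = ["ACDEFGHIKL", "ACDEFGHIKV", "ACDEWYWYKL", "PMNQRSTACD", "AC-EFGHIKL"]
        aln = Alignment(ids=list("abcde"), rows=rows)
        n = len(rows)
        # independent oracle: explicit loops, no shared code path
        raw = []
        for i in range(n):
            total = 0.0
            for j in range(n):
                if i == j:
                    continue
                compared = matches = 0
                for x, y in zip(rows[i], rows[j]):
                    if x == "-" and y == "-":
                        continue
                    compared += 1
                    matches += x == y
                total += 1.0 - matches / compared
            raw.append(total / (n - 1))
        expected = np.array(raw) * n / sum(raw)
        assert np.allclose(vingron_argos_weights(aln), expected, atol=1e-12)

    def test_mean_one_normalization(self):
        aln, _ = make_synthetic_alignment(SyntheticAlignmentSpec(seed=5))
        assert vingron_argos_weights(aln).mean() == pytest.approx(1.0)


class TestSubstitutionMatrix:
    def test_unit_diagonal_symmetric_bounded(self):
        m = BLOSUM.entries
        assert np.allclose(np.diag(m), 1.0)
        assert np.allclose(m, m.T)
        assert m.min() >= 0.0 and m.max() <= 1.0

    def test_rejects_nonunit_diagonal(self):
        bad = np.eye(20) * 0.5
        with pytest.raises(ValueError, match="unit diagonal"):
            SubstitutionMatrix(entries=bad)


class TestColumnScore:
    def test_fully_conserved_scores_one(self):
        score = valdar_thornton_column_score("SSSS", np.array([1.0, 0.5, 2.0, 0.5]), BLOSUM)
        assert score.C == pytest.approx(1.0)

    def test_all_gap_scores_zero(self):
        score = valdar_thornton_column_score("----", np.ones(4), BLOSUM)
        assert score.C == 0.0

    def test_matches_pair_enumeration_oracle(self):
        column = "SSTA"
        w = np.ones(4)
        idx = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
        num = den = 0.0
        for i in range(4):
            for j in range(i + 1, 4):
                den += w[i] * w[j]
                num += w[i] * w[j] * BLOSUM.entries[idx[column[i]], idx[column[j]]]
        score = valdar_thornton_column_score(column, w, BLOSUM)
        assert score.C == pytest.approx(num / den, abs=1e-12)
        assert score.gamma == pytest.approx(1.0 / den, abs=1e-12)

    def test_gap_pairs_zero_but_in_denominator(self):
        full = valdar_thornton_column_score("SSSS", np.ones(4), BLOSUM).C
        gapped = valdar_thornton_column_score("SSS-", np.ones(4), BLOSUM).C
        # 3 of 6 pairs involve the gap: score halves exactly
        assert gapped == pytest.approx(full * 0.5)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(
        st.text(alphabet=AMINO_ACIDS + "-", min_size=3, max_size=10),
        st.randoms(use_true_random=False),
    )
    def test_bounded_and_reorder_invariant(self, column, rnd):
        w = np.array([1.0 + 0.1 * i for i in range(len(column))])
        c = valdar_thornton_column_score(column, w, BLOSUM).C
        assert 0.0 <= c <= 1.0
        perm = list(range(len(column)))
        rnd.shuffle(perm)
        permuted = "".join(column[i] for i in perm)
        assert valdar_thornton_column_score(permuted, w[perm], BLOSUM).C == pytest.approx(c)

    def test_vectorized_agrees_with_scalar(self):
        aln, _ = make_synthetic_alignment(SyntheticAlignmentSpec(seed=2, n_cols=30))
        w = vingron_argos_weights(aln)
        vec = column_scores(aln, w, BLOSUM)
        for j in (0, 7, 15, 29):
            assert vec[j] == pytest.approx(
                valdar_thornton_column_score(aln.column(j), w, BLOSUM).C
            )


class TestNullModel:
    def test_uniform_alignment_has_zero_spread(self):
        aln = Alignment(ids=["a", "b", "c"], rows=["AAAA", "AAAA", "AAAA"])
        with pytest.raises(ValueError, match="zero spread"):
            null_model(aln, np.ones(3), BLOSUM, n_samples=200, seed=1)

    def test_seed_reproducibility(self):
        aln, _ = make_synthetic_alignment(SyntheticAlignmentSpec(seed=3))
        w = vingron_argos_weights(aln)
        a = null_model(aln, w, BLOSUM, n_samples=500, seed=42)
        b = null_model(aln, w, BLOSUM, n_samples=500, seed=42)
        assert (a.mean, a.sd) == (b.mean, b.sd)

    def test_null_mean_matches_permuted_columns(self):
        # stochastic oracle: the null's mean should match the average score of
        # an explicitly row-permuted copy of the alignment within 3 SE
        spec = SyntheticAlignmentSpec(seed=9, planted_cols=(), gap_rate=0.0)
        aln, _ = make_synthetic_alignment(spec)
        w = vingron_argos_weights(aln)
        null = null_model(aln, w, BLOSUM, n_samples=4000, seed=7)
        rng = np.random.default_rng(123)
        permuted_rows = ["".join(rng.permutation(list(row))) for row in aln.rows]
        permuted = Alignment(ids=aln.ids, rows=permuted_rows)
        scores = column_scores(permuted, w, BLOSUM)
        se = null.sd * math.sqrt(1 / null.n_samples + 1 / len(scores))
        assert abs(null.mean - scores.mean()) < 3 * se

    def test_minimum_samples_enforced(self):
        aln, _ = make_synthetic_alignment(SyntheticAlignmentSpec(seed=3))
        with pytest.raises(ValueError, match="at least 100"):
            null_model(aln, vingron_argos_weights(aln), BLOSUM, n_samples=50, seed=1)


class TestZScores:
    def make(self):
        aln, _ = make_synthetic_alignment(SyntheticAlignmentSpec(seed=4))
        w = vingron_argos_weights(aln)
        null = null_model(aln, w, BLOSUM, n_samples=1000, seed=5)
        return aln, w, null

    def test_identical_columns_share_z(self):
        aln, w, null = self.make()
        z = z_scores(aln, w, null=null, matrix=BLOSUM)
        planted = z[:10]  # ten planted fully conserved columns
        assert np.allclose(planted, planted[0])
        assert planted[0] == pytest.approx(z.max())

    def test_affine_in_score(self):
        aln, w, null = self.make()
        c = column_scores(aln, w, BLOSUM)
        z = z_scores(aln, w, BLOSUM, null)
        assert np.allclose(z, (c - null.mean) / null.sd)
        assert np.all(np.diff(z[np.argsort(c)]) >= -1e-12)  # strictly increasing in C


def direct_binomial_tail(i, n, p):
    """Direct summation oracle for P(X >= i)."""
    return math.fsum(
        math.comb(n, j) * p**j * (1 - p) ** (n - j) for j in range(i, n + 1)
    )


def exhaustive_binomial_tail(i, n, p):
    """Enumeration over all 2^n Bernoulli outcome vectors."""
    total = 0.0
    for outcome in itertools.product((0, 1), repeat=n):
        k = sum(outcome)
        if k >= i:
            total += p**k * (1 - p) ** (n - k)
    return total


class TestBCutoff:
    def test_single_trial_fair_coin(self):
        table = bcutoff_pvalues([0.0])
        assert table.rows[0].P == pytest.approx(0.5)

    def test_nonfinite_z_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            bcutoff_pvalues([1.0, float("nan")])

    def test_ties_keep_input_order(self):
        table = bcutoff_pvalues([2.0, 3.0, 2.0], labels=["x", "y", "z"])
        assert [r.label for r in table.rows] == ["y", "x", "z"]

    @pytest.mark.parametrize("p", [0.4, 0.05, 1e-6, 1e-12])
    def test_matches_direct_summation(self, p):
        n = 87
        z = float(norm.isf(p))
        table = bcutoff_pvalues([z] * 15, n=n)
        for row in table.rows:
            direct = direct_binomial_tail(row.rank, n, p)
            if direct > 0:
                assert abs(row.P - direct) / direct < 1e-10

    @pytest.mark.parametrize("n", [4, 8, 11])
    @pytest.mark.parametrize("p", [0.5, 0.1, 1e-3])
    def test_matches_exhaustive_enumeration_small_n(self, n, p):
        z = float(norm.isf(p))
        table = bcutoff_pvalues([z] * n)
        for row in table.rows:
            exact = exhaustive_binomial_tail(row.rank, n, p)
            assert abs(row.P - exact) <= 1e-12 * max(exact, 1e-300)

    def test_calibration_round_trip(self):
        q = float(norm.sf(4.0))
        for n in (20, 87, 300):
            p1 = 1.0 - (1.0 - q) ** n
            assert calibrate_total_columns(4.0, p1) == n


class TestSignificanceCutoff:
    def test_longest_prefix_on_reference_pvalues(self):
        from asitekit.case_study import CONSERVATION_TABLE

        zs = [row[1] for row in CONSERVATION_TABLE]
        table = bcutoff_pvalues(zs, n=87)
        # published p-value column: rank 12 has P=9.0e-3 <= 0.05, rank 13 has 0.141
        assert significance_cutoff(table, alpha=0.05) == 12

    def test_none_significant(self):
        table = bcutoff_pvalues([0.0, -1.0], n=2)
        assert significance_cutoff(table, alpha=1e-6) == 0

    def test_all_significant(self):
        table = bcutoff_pvalues([6.0, 5.9, 5.8])
        assert significance_cutoff(table, alpha=0.05) == 3


class TestConservationReport:
    def test_planted_columns_occupy_top_ranks_with_equal_z(self):
        aln, truth = make_synthetic_alignment(SyntheticAlignmentSpec(seed=6))
        table = conservation_report(aln, n_samples=1000, seed=8)
        top = table.rows[:10]
        assert len({r.z for r in top}) == 1
        top_cols = {r.column for r in top}
        planted_cols = {aln.column(j) for j in truth["planted_cols"]}
        assert top_cols == planted_cols

    def test_tsv_is_deterministic(self, tmp_path):
        aln, _ = make_synthetic_alignment(SyntheticAlignmentSpec(seed=6))
        a = conservation_report(aln, n_samples=500, seed=3).to_tsv(tmp_path / "a.tsv")
        b = conservation_report(aln, n_samples=500, seed=3).to_tsv(tmp_path / "b.tsv")
        assert (tmp_path / "a.tsv").read_bytes() == (tmp_path / "b.tsv").read_bytes()
        assert a == b

    def test_reference_labels_skip_leading_gap(self):
        # 6-column fixture, reference row gapped at columns 1 and 4; all
        # column contents are distinct so labels can be recovered per column
        aln = Alignment(
            ids=["ref", "x", "y"],
            rows=["-AC-DE", "KACQDE", "RACWDE"],
            ref_id="ref",
        )
        table = conservation_report(aln, n_samples=150, seed=2)
        # hand-indexed: reference residues A,C,D,E are positions 1..4,
        # gapped reference columns get insertion labels by column index
        expected = {0: "ins1", 1: "1A", 2: "2C", 3: "ins4", 4: "3D", 5: "4E"}
        got = dict(enumerate(_labels_in_column_order(aln, table)))
        assert got == expected

    def test_alignment_io_fasta_and_clustal(self, tmp_path):
        aln, _ = make_synthetic_alignment(SyntheticAlignmentSpec(seed=1, n_seqs=4, n_cols=20))
        fasta = tmp_path / "aln.fasta"
        fasta.write_text("".join(f">{i}\n{r}\n" for i, r in zip(aln.ids, aln.rows)))
        loaded = read_alignment(fasta, ref_id=aln.ids[0])
        assert loaded.rows == aln.rows
        clustal = tmp_path / "aln.aln"
        body = "\n".join(f"{i:<10s}{r}" for i, r in zip(aln.ids, aln.rows))
        clustal.write_text("CLUSTAL W (demo)\n\n" + body + "\n")
        assert read_alignment(clustal).rows == aln.rows


def _labels_in_column_order(aln, table):
    """Recover per-column labels from a rank table (columns are unique here)."""
    by_column = {}
    for r in table.rows:
        by_column.setdefault(r.column, r.label)
    return [by_column[aln.column(j)] for j in range(aln.n_cols)]


class TestAlignmentValidation:
    def test_rejects_ragged_rows(self):
        with pytest.raises(ValueError, match="length"):
            Alignment(ids=["a", "b"], rows=["ACD", "AC"])

    def test_rejects_single_sequence(self):
        with pytest.raises(ValueError, match="at least 2"):
            Alignment(ids=["a"], rows=["ACD"])

    def test_rejects_illegal_characters(self):
        with pytest.raises(ValueError, match="illegal"):
            Alignment(ids=["a", "b"], rows=["ACX", "ACD"])
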