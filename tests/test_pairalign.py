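import random

import pytest

from retrodate.gene_coords import GeneModel, Region
from retrodate.pairalign import (
    Alignment,
    DEFAULT_SCORING,
    Scoring,
    VariantKind,
    apply_variants,
    call_variants,
    global_align,
    normalize_repeats,
)

NEG = float("-inf")


def gotoh_score(a: str, b: str, sc: Scoring = DEFAULT_SCORING) -> float:
    """Independent affine-gap DP oracle (score only). A gap of length g
    costs gap_open + g * gap_extend."""
    n, m = len(a), len(b)
    open_ = sc.gap_open + sc.gap_extend
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (consumes a)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (consumes b)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = sc.gap_open + sc.gap_extend * i
    for j in range(1, m + 1):
        Y[0][j] = sc.gap_open + sc.gap_extend * j
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = sc.match if a[i - 1] == b[j - 1] else sc.mismatch
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] + open_, X[i - 1][j] + sc.gap_extend, Y[i - 1][j] + open_)
            Y[i][j] = max(M[i][j - 1] + open_, Y[i][j - 1] + sc.gap_extend, X[i][j - 1] + open_)
    return max(M[n][m], X[n][m], Y[n][m])


def random_seq(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))


class TestGlobalAlign:
    def test_identity(self):
        aln = global_align("ACGTACGTAC", "ACGTACGTAC")
        assert aln.row_a == aln.row_b
        assert aln.score == DEFAULT_SCORING.match * 10

    def test_single_deletion(self):
        aln = global_align("ACGTACGT", "ACGACGT")
        assert aln.row_b.count("-") == 1
        matches = sum(1 for a, b in aln.columns if a == b)
        assert matches == 7
        assert aln.score == gotoh_score("ACGTACGT", "ACGACGT")

    def test_22nt_block_deletion(self):
        rng = random.Random(42)
        seq = random_seq(rng, 2000)
        cut = 900
        derived = seq[:cut] + seq[cut + 22 :]
        aln = global_align(seq, derived)
        gaps = aln.row_b.count("-")
        assert gaps == 22
        # single contiguous gap
        stripped = aln.row_b.strip("-")
        runs = [r for r in stripped.split("-") if r == ""]
        assert "-" * 22 in aln.row_b and aln.row_b.count("-" * 22) == 1

    def test_matches_dp_oracle_on_random_pairs(self):
        rng = random.Random(7)
        for _ in range(300):
            a = random_seq(rng, rng.randint(1, 12))
            b = random_seq(rng, rng.randint(1, 12))
            assert global_align(a, b).score == gotoh_score(a, b), (a, b)

    def test_score_at_least_all_gap_concatenation(self):
        rng = random.Random(8)
        sc = DEFAULT_SCORING
        for _ in range(100):
            a = random_seq(rng, rng.randint(1, 15))
            b = random_seq(rng, rng.randint(1, 15))
            trivial = 2 * sc.gap_open + sc.gap_extend * (len(a) + len(b))
            assert global_align(a, b).score >= trivial

    def test_rows_reproduce_inputs(self):
        rng = random.Random(9)
        a, b = random_seq(rng, 40), random_seq(rng, 38)
        aln = global_align(a, b)
        assert aln.ungapped("a") == a and aln.ungapped("b") == b

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            global_align("", "ACGT")

    def test_gap_gap_column_rejected(self):
        with pytest.raises(ValueError):
            Alignment("a", "b", "A-C", "A-C", 0)


def _flat_model(seq: str, cds_start: int, cds_end: int) -> GeneModel:
    return GeneModel("m", seq, [(1, len(seq))], cds_start, cds_end)


class TestCallVariants:
    def test_single_substitution_label(self):
        rng = random.Random(3)
        utr5, cds_len, utr3 = 20, 300, 50
        seq = random_seq(rng, utr5 + cds_len + utr3)
        t = utr5 + 144  # CDS position 144
        seq = seq[: t - 1] + "G" + seq[t:]
        derived = seq[: t - 1] + "A" + seq[t:]
        model = _flat_model(seq, utr5 + 1, utr5 + cds_len)
        aln = global_align(seq, derived)
        calls = call_variants(aln, model)
        assert [v.label for v in calls] == ["144G>A"]

    def test_no_differences(self):
        seq = "ACGT" * 30
        model = _flat_model(seq, 11, 100)
        assert call_variants(global_align(seq, seq), model) == []

    def test_planted_substitutions_recovered_exactly(self):
        rng = random.Random(17)
        for _ in range(200):
            seq = random_seq(rng, 300)
            model = _flat_model(seq, 31, 270)
            n_edit = rng.randint(1, 10)
            positions = rng.sample(range(300), n_edit)
            derived = list(seq)
            planted = set()
            for p in positions:
                alt = rng.choice([b for b in "ACGT" if b != seq[p]])
                derived[p] = alt
                planted.add((p + 1, seq[p], alt))
            calls = call_variants(global_align(seq, "".join(derived)), model)
            got = {(v.start_t, v.ancestral, v.derived) for v in calls}
            assert got == planted

    def test_roundtrip_with_indels(self):
        rng = random.Random(23)
        for _ in range(50):
            seq = random_seq(rng, 240)
            model = _flat_model(seq, 16, 225)
            derived = list(seq)
            # a substitution, a deletion, and an insertion, well separated
            derived[40] = "A" if seq[40] != "A" else "C"
            del derived[120:123]
            derived.insert(180, rng.choice("ACGT"))
            derived_s = "".join(derived)
            aln = global_align(seq, derived_s)
            calls = call_variants(aln, model)
            assert apply_variants(seq, calls) == derived_s

    def test_polarity_flip_preserves_count(self):
        rng = random.Random(29)
        seq = random_seq(rng, 200)
        derived = seq[:50] + "T" + seq[51:120] + seq[125:]
        if derived[50] == seq[50]:
            derived = seq[:50] + ("A" if seq[50] != "A" else "G") + seq[51:120] + seq[125:]
        model = _flat_model(seq, 11, 190)
        aln_fwd = global_align(seq, derived)
        n_fwd = len(call_variants(aln_fwd, model))
        aln_rev = global_align(derived, seq)
        model_rev = _flat_model(derived, 11, 190)
        n_rev = len(call_variants(aln_rev, model_rev, polarity="a"))
        assert n_fwd == n_rev


class TestNormalizeRepeats:
    @staticmethod
    def _run_model(run_len: int = 15, at_utr3: int = 184):
        """Single-exon gene whose 3' UTR carries a poly-T run starting at
        UTR3 position ``at_utr3``."""
        rng = random.Random(101)
        utr5, cds_len = 10, 30
        utr3_len = at_utr3 + run_len + 30
        seq = random_seq(rng, utr5 + cds_len + utr3_len)
        start = utr5 + cds_len + at_utr3 - 1  # 0-based
        seq = seq[:start] + "T" * run_len + seq[start + run_len :]
        # bound the run with non-T
        seq = seq[: start - 1] + "C" + seq[start:]
        end = start + run_len
        seq = seq[:end] + "G" + seq[end + 1 :]
        model = _flat_model(seq, utr5 + 1, utr5 + cds_len)
        return seq, model, start

    def test_deletion_in_long_run_becomes_repeat_length(self):
        seq, model, start = self._run_model()
        derived = seq[:start] + "T" * 12 + seq[start + 15 :]
        aln = global_align(seq, derived)
        calls = normalize_repeats(call_variants(aln, model), aln, model)
        assert len(calls) == 1
        v = calls[0]
        assert v.kind is VariantKind.REPEAT_LENGTH
        assert v.repeat_unit == "T"
        assert sorted(v.repeat_copies) == [12, 15]
        assert v.label == "*184T(12-15)"

    def test_indel_away_from_runs_unchanged(self):
        rng = random.Random(55)
        seq = "".join(
            rng.choice("AC") + rng.choice("GT") for _ in range(120)
        )  # no long mononucleotide runs
        model = _flat_model(seq, 11, 100)
        derived = seq[:60] + seq[63:]
        aln = global_align(seq, derived)
        calls = normalize_repeats(call_variants(aln, model), aln, model)
        assert all(v.kind is not VariantKind.REPEAT_LENGTH for v in calls)

    def test_gap_placement_within_run_is_canonical(self):
        seq, model, start = self._run_model()
        results = []
        for gap_at in range(start, start + 15):
            row_b = seq[:gap_at] + "-" + seq[gap_at + 1 :]
            aln = Alignment("a", "b", seq, row_b, 0.0)
            calls = normalize_repeats(call_variants(aln, model), aln, model)
            results.append([(v.label, v.repeat_copies) for v in calls])
        assert all(r == results[0] for r in results)
        assert results[0][0][1] == (15, 14)

    def test_repeat_roundtrip(self):
        seq, model, start = self._run_model()
        derived = seq[:start] + "T" * 12 + seq[start + 15 :]
        aln = global_align(seq, derived)
        calls = normalize_repeats(call_variants(aln, model), aln, model)
        assert apply_variants(seq, calls) == derived
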