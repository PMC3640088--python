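"""Pairwise distances: alignment difference counts vs an exhaustive oracle,
retention rule, submatrix, serialization."""

from __future__ import annotations

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import barcodeaudit as ba
from barcodeaudit.distance import (
    AlignmentScoring,
    align_count_diffs,
    align_diff_stats,
    build_matrix,
    iupac_match,
    pair_threshold,
    read_matrix_tsv,
    submatrix,
    write_matrix_tsv,
)
from conftest import make_dataset


# --- independent oracle: exhaustive enumeration of end-gap-free alignments ----

def enumerate_alignment_diffs(a: str, b: str, scoring: AlignmentScoring | None = None):
    """All difference counts achievable by optimal-score end-gap-free global
    alignments of *a* and *b*, by brute-force path enumeration.

    A gap run is free only when it starts the alignment or ends it (one run
    per end); every other run costs open + (len-1)*extend.  Differences =
    mismatch columns + non-terminal gap columns.
    """
    s = scoring or AlignmentScoring()
    results: dict[float, set[int]] = {}

    cols: list[str] = []

    def walk(i: int, j: int):
        if i == len(a) and j == len(b):
            runs = []  # (kind, length, start_index)
            k = 0
            while k < len(cols):
                kind = cols[k][0]
                start = k
                while k < len(cols) and cols[k][0] == kind:
                    k += 1
                runs.append((kind, k - start, start))
            score = 0.0
            diffs = 0
            for idx, (kind, length, start) in enumerate(runs):
                terminal = (idx == 0 or idx == len(runs) - 1) and kind in "ID"
                if kind == "M":
                    score += sum(s.match if c[1] == "=" else s.mismatch
                                 for c in cols[start:start + length])
                    diffs += sum(1 for c in cols[start:start + length] if c[1] == "X")
                elif terminal:
                    pass  # free end gap, excluded from the count
                else:
                    score += s.gap_open + s.gap_extend * (length - 1)
                    diffs += 1 if s.indel_as_single else length
            results.setdefault(score, set()).add(diffs)
            return
        if i < len(a) and j < len(b):
            sym = "=" if iupac_match(a[i], b[j]) else "X"
            cols.append(f"M{sym}")
            walk(i + 1, j + 1)
            cols.pop()
        if i < len(a):
            cols.append("D.")
            walk(i + 1, j)
            cols.pop()
        if j < len(b):
            cols.append("I.")
            walk(i, j + 1)
            cols.pop()

    walk(0, 0)
    best = max(results)
    return best, results[best]


class TestAlignCountDiffs:
    def test_identity(self):
        assert align_count_diffs("ACGT", "ACGT") == 0

    def test_single_substitution(self):
        assert align_count_diffs("ACGT", "ACCT") == 1

    def test_single_internal_gap_column(self):
        # deletion anchored by non-periodic matching flanks: one internal gap column
        a, b = "ACGATCGA", "ACGTCGA"
        best, diffs = enumerate_alignment_diffs(a, b)
        assert diffs == {1}
        assert align_count_diffs(a, b) == 1

    def test_periodic_pair_prefers_end_gap_shift(self):
        # under end-gap-free scoring the dovetail shift (score 4) beats the
        # internal-gap alignment (score 2); the enumeration oracle agrees
        best, diffs = enumerate_alignment_diffs("ACGTACGT", "ACGTCGT")
        assert best == 4.0
        assert align_count_diffs("ACGTACGT", "ACGTCGT") in diffs

    def test_empty_sequence_is_error(self):
        with pytest.raises(ValueError):
            align_count_diffs("", "ACGT")

    def test_ambiguity_codes_match_on_intersection(self):
        assert align_count_diffs("ACGT", "ACGN") == 0  # N intersects everything
        assert align_count_diffs("ACGA", "ACGR") == 0  # R = {A,G} ∩ {A} nonempty
        assert align_count_diffs("ACGA", "ACGY") == 1  # Y = {C,T} ∩ {A} empty
        assert iupac_match("T", "Y") and not iupac_match("A", "Y")

    def test_matches_exhaustive_enumeration_on_spec_examples(self):
        for a, b in [("ACGT", "ACCT"), ("ACGTACGT", "ACGTCGT"), ("ACGT", "ACGT")]:
            best, diffs = enumerate_alignment_diffs(a, b)
            assert align_count_diffs(a, b) in diffs

    def test_matches_exhaustive_enumeration_on_random_short_strings(self):
        rng = random.Random(99)
        for _ in range(12):
            la, lb = rng.randint(3, 6), rng.randint(3, 6)
            a = "".join(rng.choice("ACGT") for _ in range(la))
            b = "".join(rng.choice("ACGT") for _ in range(lb))
            best, diffs = enumerate_alignment_diffs(a, b)
            got = align_count_diffs(a, b)
            assert got in diffs, (a, b, got, diffs)

    @given(st.text(alphabet="ACGT", min_size=1, max_size=12),
           st.text(alphabet="ACGT", min_size=1, max_size=12))
    @settings(max_examples=60, deadline=None)
    def test_symmetry(self, a, b):
        assert align_count_diffs(a, b) == align_count_diffs(b, a)

    @given(st.text(alphabet="ACGTRYN", min_size=1, max_size=30))
    @settings(max_examples=40, deadline=None)
    def test_self_distance_zero(self, a):
        assert align_count_diffs(a, a) == 0

    def test_equals_hamming_on_indel_free_generated_data(self, small_dataset):
        dataset, _ = small_dataset
        recs = dataset.records[:6]
        for i, ra in enumerate(recs):
            for rb in recs[i + 1:]:
                if ra.genus != rb.genus:
                    continue  # unrelated spacers: gap-free need not be optimal
                h = sum(1 for x, y in zip(ra.sequence, rb.sequence) if x != y)
                assert align_count_diffs(ra.sequence, rb.sequence) == h


class TestBuildMatrix:
    def test_identical_sequences_all_retained_at_zero(self):
        ds = make_dataset({f"s{i}": ("X a", "ACGT" * 50) for i in range(3)})
        m = build_matrix(ds)
        assert m.n_retained == 3
        assert all(p.bp_diff == 0 for p in m.retained_pairs())

    def test_pair_over_70bp_not_retained(self):
        rng = random.Random(1)
        seq = "".join(rng.choice("ACGT") for _ in range(700))
        mutated = list(seq)
        for pos in rng.sample(range(700), 80):
            mutated[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[pos]]
        ds = make_dataset({"a": ("X a", seq), "b": ("X b", "".join(mutated))})
        m = build_matrix(ds)
        assert m.n_retained == 0
        assert m.n_nonretained == 1

    def test_all_pairs_evaluated(self, small_matrix, small_dataset):
        dataset, _ = small_dataset
        n = len(dataset.sequenced())
        assert small_matrix.n_evaluated == n * (n - 1) // 2

    def test_pair_threshold_uses_mean_length(self):
        assert pair_threshold(700, 700) == 70
        assert pair_threshold(400, 400) == 40
        assert pair_threshold(700, 700, threshold_bp=50) == 50

    def test_taxonomic_flags_from_metadata(self, small_matrix):
        for p in small_matrix.retained_pairs():
            if p.same_species:
                assert p.same_genus


class TestSubmatrix:
    def test_full_id_set_identity(self, small_matrix):
        sub = submatrix(small_matrix, small_matrix.ids)
        assert sub.entries == small_matrix.entries

    def test_singleton_empty(self, small_matrix):
        sub = submatrix(small_matrix, [small_matrix.ids[0]])
        assert sub.n_evaluated == 0

    def test_subset_matches_brute_filter(self, small_matrix):
        ids = small_matrix.ids[:5]
        keep = set(ids[:3])
        sub = submatrix(small_matrix, keep)
        expected = {k for k in small_matrix.entries if k[0] in keep and k[1] in keep}
        assert set(sub.entries) == expected

    def test_unknown_id_error(self, small_matrix):
        with pytest.raises(KeyError):
            submatrix(small_matrix, ["nope"])


def test_matrix_tsv_roundtrip(tmp_path, small_matrix):
    p = tmp_path / "dist.tsv"
    write_matrix_tsv(small_matrix, p)
    back = read_matrix_tsv(p)
    assert back.ids == small_matrix.ids
    assert back.entries == small_matrix.entries
    assert back.nonretained == small_matrix.nonretained
    assert back.threshold_bp == small_matrix.threshold_bp
    assert back.lengths == small_matrix.lengths


def test_degenerate_overlap_censored_not_zero_distance():
    # unrelated sequences sharing a conserved core must not come out as
    # "identical": the sliver-overlap optimum is censored by the overlap rule
    rng = random.Random(5)
    core = "".join(rng.choice("ACGT") for _ in range(160))
    left1 = "".join(rng.choice("ACGT") for _ in range(250))
    left2 = "".join(rng.choice("ACGT") for _ in range(250))
    right1 = "".join(rng.choice("ACGT") for _ in range(250))
    right2 = "".join(rng.choice("ACGT") for _ in range(250))
    ds = make_dataset({"a": ("X a", left1 + core + right1), "b": ("Y b", left2 + core + right2)})
    m = build_matrix(ds)
    assert m.n_retained == 0
    assert m.n_nonretained == 1
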