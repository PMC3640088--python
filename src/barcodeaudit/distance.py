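"""Pairwise bp-difference distances with the barcode retention rule.

The distance between two barcodes is the number of nucleotide differences
under an end-gap-free global alignment: substitution columns plus internal
gap columns, with terminal overhangs (ragged amplicon ends from different
primer trims) excluded.  IUPAC ambiguity codes count as a match whenever the
two codes' base sets intersect — conservative toward intraspecific identity.

Pairs are retained only when they differ by at most ``min(threshold_bp,
floor(threshold_frac * mean pair length))`` — by default 70 bp or 10% of the
typical ~700 bp ITS amplicon — the empirical regime in which pairwise
alignments of heterogeneous barcodes stay trustworthy.  Distances beyond the
threshold are censored: the pair's identity is kept, its distance is not.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Optional, Union

from Bio import Align
from Bio.Align import substitution_matrices

from .records import Dataset

IUPAC_SETS = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("GC"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}
_CODES = "".join(IUPAC_SETS)


def iupac_match(a: str, b: str) -> bool:
    """True when the IUPAC base sets of *a* and *b* intersect."""
    return bool(IUPAC_SETS[a] & IUPAC_SETS[b])


@dataclass(frozen=True)
class AlignmentScoring:
    """Scoring for the end-gap-free global alignment behind bp differences.

    ``indel_as_single`` switches a k-base internal indel from counting k
    differences (one per gap column, the default) to counting 1.
    """

    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -5.0
    gap_extend: float = -2.0
    indel_as_single: bool = False


@lru_cache(maxsize=8)
def _make_aligner(match: float, mismatch: float, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    mat = substitution_matrices.Array(_CODES, dims=2)
    for x in _CODES:
        for y in _CODES:
            mat[x, y] = match if iupac_match(x, y) else mismatch
    aligner = Align.PairwiseAligner(mode="global")
    aligner.substitution_matrix = mat
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    # free end gaps: terminal overhangs neither scored nor counted
    aligner.end_insertion_score = 0.0
    aligner.end_deletion_score = 0.0
    return aligner


def _hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if not iupac_match(x, y))


def align_diff_stats(
    seq_a: str, seq_b: str, scoring: Optional[AlignmentScoring] = None
) -> tuple[int, float]:
    """Count nucleotide differences and report the aligned overlap fraction.

    Differences = substitution columns + internal gap columns of an optimal
    end-gap-free global alignment (match +1, mismatch −1, gap open −5,
    gap extend −2 by default); terminal overhangs are excluded.  Among
    equally scoring alignments the gap-free one is preferred when the
    sequences have equal length.

    The second return value is the fraction of the mean sequence length that
    the aligned span (first to last aligned column) covers.  End-gap-free
    alignment of two *unrelated* sequences degenerates to a tiny overlap with
    a near-zero difference count, so a difference count is only meaningful
    when the overlap is substantial; callers enforce that.
    """
    if not seq_a or not seq_b:
        raise ValueError("cannot align an empty sequence")
    scoring = scoring or AlignmentScoring()
    if seq_a == seq_b:
        return 0, 1.0
    # canonical argument order => exact symmetry even under alignment ties
    if seq_b < seq_a:
        seq_a, seq_b = seq_b, seq_a
    mean_len = (len(seq_a) + len(seq_b)) / 2.0
    aligner = _make_aligner(scoring.match, scoring.mismatch, scoring.gap_open, scoring.gap_extend)
    if len(seq_a) == len(seq_b):
        # gap-free fast path, taken only when provably optimal by score
        h = _hamming(seq_a, seq_b)
        gapfree_score = scoring.match * (len(seq_a) - h) + scoring.mismatch * h
        if aligner.score(seq_a, seq_b) == gapfree_score:
            return h, 1.0
    aln = aligner.align(seq_a, seq_b)[0]
    blocks_a, blocks_b = aln.aligned
    if len(blocks_a) == 0:  # nothing aligned at all: no usable overlap
        return 0, 0.0
    diff = 0
    for (sa, ea), (sb, _eb) in zip(blocks_a, blocks_b):
        seg_a = seq_a[sa:ea]
        seg_b = seq_b[sb:sb + (ea - sa)]
        diff += sum(1 for x, y in zip(seg_a, seg_b) if not iupac_match(x, y))
    for i in range(len(blocks_a) - 1):
        gap_a = blocks_a[i + 1][0] - blocks_a[i][1]
        gap_b = blocks_b[i + 1][0] - blocks_b[i][1]
        if scoring.indel_as_single:
            diff += (1 if gap_a > 0 else 0) + (1 if gap_b > 0 else 0)
        else:
            diff += gap_a + gap_b
    span_a = blocks_a[-1][1] - blocks_a[0][0]
    span_b = blocks_b[-1][1] - blocks_b[0][0]
    overlap = ((span_a + span_b) / 2.0) / mean_len
    return diff, overlap


def align_count_diffs(seq_a: str, seq_b: str, scoring: Optional[AlignmentScoring] = None) -> int:
    """Difference count of :func:`align_diff_stats` (overlap ignored)."""
    return align_diff_stats(seq_a, seq_b, scoring)[0]


@dataclass(frozen=True)
class PairComparison:
    """A single sequence pair with its bp difference and taxonomic context."""

    id_a: str
    id_b: str
    bp_diff: Optional[int]  # None when the pair was censored (not retained)
    retained: bool
    same_species: bool
    same_genus: bool
    same_family: bool


def pair_threshold(len_a: int, len_b: int, threshold_bp: int = 70, threshold_frac: float = 0.10) -> int:
    """Retention cap for one pair: min(fixed bp cap, fraction of mean length)."""
    return min(threshold_bp, math.floor(threshold_frac * (len_a + len_b) / 2.0))


@dataclass
class SparseDistanceMatrix:
    """Retained pairwise comparisons over a specimen set.

    Unordered pairs are stored once with ``id_a < id_b``; the diagonal is
    implicitly zero.  Censored (non-retained) pairs keep only their identity
    and taxonomic flags, never a distance.
    """

    ids: list[str]
    entries: dict[tuple[str, str], PairComparison] = field(default_factory=dict)
    nonretained: dict[tuple[str, str], PairComparison] = field(default_factory=dict)
    threshold_bp: int = 70
    threshold_frac: float = 0.10
    lengths: dict[str, int] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def n_retained(self) -> int:
        return len(self.entries)

    @property
    def n_nonretained(self) -> int:
        return len(self.nonretained)

    @property
    def n_evaluated(self) -> int:
        return len(self.entries) + len(self.nonretained)

    def get(self, id_a: str, id_b: str) -> Optional[PairComparison]:
        key = (id_a, id_b) if id_a < id_b else (id_b, id_a)
        entry = self.entries.get(key)
        return entry if entry is not None else self.nonretained.get(key)

    def retained_pairs(self) -> Iterable[PairComparison]:
        return (self.entries[k] for k in sorted(self.entries))

    def all_pairs(self) -> Iterable[PairComparison]:
        merged = {**self.entries, **self.nonretained}
        return (merged[k] for k in sorted(merged))


def build_matrix(
    dataset: Dataset,
    scoring: Optional[AlignmentScoring] = None,
    threshold_bp: int = 70,
    threshold_frac: float = 0.10,
    min_overlap_frac: float = 0.5,
) -> SparseDistanceMatrix:
    """Evaluate all unordered pairs of sequenced records and apply retention.

    A pair is retained when its difference count is within the threshold AND
    its aligned span covers at least *min_overlap_frac* of the mean pair
    length — a degenerate sliver overlap between unrelated sequences is as
    uninformative as a >70 bp distance, and is censored the same way.
    Taxonomic flags come from the record metadata, with species defined as
    the binomial after infraspecific collapse.
    """
    records = dataset.sequenced()
    if len(records) < 2:
        raise ValueError("need at least 2 sequenced records to build a distance matrix")
    records = sorted(records, key=lambda r: r.specimen_id)
    matrix = SparseDistanceMatrix(
        ids=[r.specimen_id for r in records],
        threshold_bp=threshold_bp,
        threshold_frac=threshold_frac,
        lengths={r.specimen_id: len(r.sequence) for r in records},
    )
    for i, ra in enumerate(records):
        for rb in records[i + 1:]:
            bp, overlap = align_diff_stats(ra.sequence, rb.sequence, scoring)
            cap = pair_threshold(len(ra.sequence), len(rb.sequence), threshold_bp, threshold_frac)
            retained = bp <= cap and overlap >= min_overlap_frac
            cmp = PairComparison(
                id_a=ra.specimen_id,
                id_b=rb.specimen_id,
                bp_diff=bp if retained else None,
                retained=retained,
                same_species=ra.species == rb.species and bool(ra.species),
                same_genus=ra.genus == rb.genus and bool(ra.genus),
                same_family=_same_family(ra, rb, dataset),
            )
            key = (ra.specimen_id, rb.specimen_id)
            (matrix.entries if retained else matrix.nonretained)[key] = cmp
    return matrix


def _same_family(ra, rb, dataset: Dataset) -> bool:
    fa = ra.family or dataset.taxonomy.family_of(ra.genus) or ""
    fb = rb.family or dataset.taxonomy.family_of(rb.genus) or ""
    return bool(fa) and fa == fb


def submatrix(matrix: SparseDistanceMatrix, ids: Iterable[str]) -> SparseDistanceMatrix:
    """Restrict the matrix to pairs with both endpoints in *ids*."""
    keep = set(ids)
    unknown = keep - set(matrix.ids)
    if unknown:
        raise KeyError(f"unknown specimen ids: {sorted(unknown)}")
    sub_ids = [i for i in matrix.ids if i in keep]
    return SparseDistanceMatrix(
        ids=sub_ids,
        entries={k: v for k, v in matrix.entries.items() if k[0] in keep and k[1] in keep},
        nonretained={k: v for k, v in matrix.nonretained.items() if k[0] in keep and k[1] in keep},
        threshold_bp=matrix.threshold_bp,
        threshold_frac=matrix.threshold_frac,
        lengths={i: matrix.lengths[i] for i in sub_ids if i in matrix.lengths},
    )


def write_matrix_tsv(matrix: SparseDistanceMatrix, path: Union[str, Path]) -> None:
    """Serialize as long-format delimited text (byte-stable ordering)."""
    lines = [
        f"#threshold_bp={matrix.threshold_bp}",
        f"#threshold_frac={matrix.threshold_frac}",
        "#ids=" + ",".join(matrix.ids),
        "#lengths=" + ",".join(str(matrix.lengths.get(i, "")) for i in matrix.ids),
        "id_a\tid_b\tbp_diff\tretained\tsame_species\tsame_genus\tsame_family",
    ]
    for p in matrix.all_pairs():
        bp = "" if p.bp_diff is None else str(p.bp_diff)
        lines.append(
            f"{p.id_a}\t{p.id_b}\t{bp}\t{int(p.retained)}\t"
            f"{int(p.same_species)}\t{int(p.same_genus)}\t{int(p.same_family)}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_matrix_tsv(path: Union[str, Path]) -> SparseDistanceMatrix:
    lines = Path(path).read_text().splitlines()
    meta: dict[str, str] = {}
    rows = []
    for line in lines:
        if line.startswith("#"):
            k, _, v = line[1:].partition("=")
            meta[k] = v
        elif line and not line.startswith("id_a\t"):
            rows.append(line.split("\t"))
    ids = meta.get("ids", "").split(",") if meta.get("ids") else []
    length_vals = meta.get("lengths", "").split(",") if meta.get("lengths") else []
    lengths = {i: int(v) for i, v in zip(ids, length_vals) if v}
    matrix = SparseDistanceMatrix(
        ids=ids,
        threshold_bp=int(meta.get("threshold_bp", 70)),
        threshold_frac=float(meta.get("threshold_frac", 0.10)),
        lengths=lengths,
    )
    for id_a, id_b, bp, retained, ss, sg, sf in rows:
        cmp = PairComparison(
            id_a=id_a, id_b=id_b,
            bp_diff=int(bp) if bp != "" else None,
            retained=bool(int(retained)),
            same_species=bool(int(ss)), same_genus=bool(int(sg)), same_family=bool(int(sf)),
        )
        (matrix.entries if cmp.retained else matrix.nonretained)[(id_a, id_b)] = cmp
    return matrix
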