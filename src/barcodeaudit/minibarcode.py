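"""ITS1/ITS2 mini-barcode extraction and discriminating-power evaluation.

Full-length fungal barcodes are ITS1+5.8S+ITS2; degraded herbarium DNA often
amplifies only a spacer.  This module splits each barcode into its regions —
using curated annotation coordinates when present, else by locating the
conserved 5.8S with a local alignment against a packaged consensus — and
quantifies how much discriminating power each spacer retains by Pearson
correlation between region-wise and full-length pairwise distance matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats
from Bio import Align

from .distance import AlignmentScoring, SparseDistanceMatrix, build_matrix, iupac_match
from .records import Dataset, SpecimenRecord
from .simulate import packaged_58s_consensus


@dataclass(frozen=True)
class SplitResult:
    """One specimen's region split; lossless (its1+s58+its2 == sequence) when ok."""

    specimen_id: str
    ok: bool
    its1: str = ""
    s58: str = ""
    its2: str = ""
    split_method: str = ""  # annotation | anchor
    anchor_score: Optional[float] = None
    reason: str = ""


@dataclass
class RegionSet:
    results: dict[str, SplitResult] = field(default_factory=dict)

    def successes(self) -> list[SplitResult]:
        return [r for r in self.results.values() if r.ok]

    @property
    def n_failed(self) -> int:
        return sum(1 for r in self.results.values() if not r.ok)


def _anchor_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner(mode="local")
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -2
    return aligner


def _locate_anchor(sequence: str, anchor: str, min_identity: float, min_coverage: float):
    """Best local alignment of the 5.8S anchor; returns (start, end, score, reason)."""
    aligner = _anchor_aligner()
    alignments = aligner.align(sequence, anchor)
    if len(alignments) == 0:
        return None, None, None, "no local alignment found"
    aln = alignments[0]
    blocks_t, blocks_q = aln.aligned
    matches = 0
    aligned_cols = 0
    for (ts, te), (qs, _qe) in zip(blocks_t, blocks_q):
        for i in range(te - ts):
            aligned_cols += 1
            if iupac_match(sequence[ts + i], anchor[qs + i]):
                matches += 1
    q_span = blocks_q[-1][1] - blocks_q[0][0]
    coverage = q_span / len(anchor)
    identity = matches / aligned_cols if aligned_cols else 0.0
    if coverage < min_coverage:
        return None, None, aln.score, f"anchor coverage {coverage:.2f} < {min_coverage}"
    if identity < min_identity:
        return None, None, aln.score, f"anchor identity {identity:.2f} < {min_identity}"
    # project the unaligned anchor flanks so the cut spans the whole 5.8S
    t_start = int(blocks_t[0][0]) - int(blocks_q[0][0])
    t_end = int(blocks_t[-1][1]) + (len(anchor) - int(blocks_q[-1][1]))
    t_start = max(0, t_start)
    t_end = min(len(sequence), t_end)
    return t_start, t_end, float(aln.score), ""


def split_record(
    record: SpecimenRecord,
    anchor: str,
    min_anchor_identity: float = 0.75,
    min_anchor_coverage: float = 0.8,
) -> SplitResult:
    seq = record.sequence
    if not seq:
        return SplitResult(record.specimen_id, ok=False, reason="no sequence")
    if record.region_coords is not None:
        _its1_end, s58_start, s58_end = record.region_coords
        return SplitResult(
            record.specimen_id, ok=True,
            its1=seq[:s58_start], s58=seq[s58_start:s58_end], its2=seq[s58_end:],
            split_method="annotation",
        )
    start, end, score, reason = _locate_anchor(seq, anchor, min_anchor_identity, min_anchor_coverage)
    if start is None:
        return SplitResult(record.specimen_id, ok=False, split_method="anchor",
                           anchor_score=score, reason=reason)
    if start == 0 or end == len(seq):
        return SplitResult(record.specimen_id, ok=False, split_method="anchor",
                           anchor_score=score, reason="5.8S abuts a sequence end; empty spacer")
    return SplitResult(
        record.specimen_id, ok=True,
        its1=seq[:start], s58=seq[start:end], its2=seq[end:],
        split_method="anchor", anchor_score=score,
    )


def split_regions(
    dataset: Dataset,
    anchor_58s: Optional[str] = None,
    min_anchor_identity: float = 0.75,
    min_anchor_coverage: float = 0.8,
) -> RegionSet:
    """Split every sequenced record into ITS1 / 5.8S / ITS2.

    Annotation coordinates win when present; otherwise the packaged (or
    supplied) 5.8S consensus is located by local alignment and accepted when
    identity ≥ *min_anchor_identity* over ≥ *min_anchor_coverage* of the
    anchor length.  Failures are recorded per specimen, never fatal.
    """
    anchor = (anchor_58s or packaged_58s_consensus()).upper().replace("U", "T")
    if not anchor:
        raise ValueError("anchor sequence must be non-empty")
    rs = RegionSet()
    for rec in dataset.sequenced():
        rs.results[rec.specimen_id] = split_record(rec, anchor, min_anchor_identity, min_anchor_coverage)
    return rs


@dataclass(frozen=True)
class MatrixCorrelation:
    r: float
    n_shared: int


def matrix_correlation(m1: SparseDistanceMatrix, m2: SparseDistanceMatrix) -> MatrixCorrelation:
    """Pearson r between two distance matrices over their shared retained pairs."""
    shared = sorted(set(m1.entries) & set(m2.entries))
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared retained pairs; need >= 3")
    x = np.array([m1.entries[k].bp_diff for k in shared], dtype=float)
    y = np.array([m2.entries[k].bp_diff for k in shared], dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("undefined correlation: zero variance in one distance vector")
    r = stats.pearsonr(x, y).statistic
    return MatrixCorrelation(r=float(r), n_shared=len(shared))


@dataclass
class MiniBarcodeReport:
    r_its1_full: Optional[float]
    r_its2_full: Optional[float]
    r_its1_its2: Optional[float]
    n_shared_its1_full: int
    n_shared_its2_full: int
    n_shared_its1_its2: int
    n_split_failed: int
    notes: dict[str, str] = field(default_factory=dict)


def _region_dataset(dataset: Dataset, regions: RegionSet, attr: str) -> Dataset:
    records = []
    for rec in dataset.sequenced():
        res = regions.results.get(rec.specimen_id)
        if res is None or not res.ok:
            continue
        seq = getattr(res, attr)
        if not seq:
            continue
        clone = SpecimenRecord(
            specimen_id=rec.specimen_id, taxon_name=rec.taxon_name, sequence=seq,
            genus=rec.genus, family=rec.family, order_name=rec.order_name,
        )
        records.append(clone)
    return Dataset(records=records, taxonomy=dataset.taxonomy)


def minibarcode_report(
    dataset: Dataset,
    regions: Optional[RegionSet] = None,
    scoring: Optional[AlignmentScoring] = None,
    threshold_bp: int = 70,
    threshold_frac: float = 0.10,
    full_matrix: Optional[SparseDistanceMatrix] = None,
) -> MiniBarcodeReport:
    """Correlate region-wise distance matrices with the full-length matrix.

    All three matrices use the same distance parameters; pairs retained in
    one matrix but not another are excluded pairwise (intersection).
    Undefined correlations (zero variance, too few shared pairs) are reported
    as None with the reason, mirroring e.g. a dataset of identical ITS2s.
    """
    regions = regions or split_regions(dataset)
    full = full_matrix if full_matrix is not None else build_matrix(
        dataset, scoring, threshold_bp, threshold_frac
    )
    m1 = build_matrix(_region_dataset(dataset, regions, "its1"), scoring, threshold_bp, threshold_frac)
    m2 = build_matrix(_region_dataset(dataset, regions, "its2"), scoring, threshold_bp, threshold_frac)

    values: dict[str, Optional[float]] = {}
    counts: dict[str, int] = {}
    notes: dict[str, str] = {}
    for name, (ma, mb) in {
        "r_its1_full": (m1, full),
        "r_its2_full": (m2, full),
        "r_its1_its2": (m1, m2),
    }.items():
        try:
            mc = matrix_correlation(ma, mb)
            values[name] = mc.r
            counts[name] = mc.n_shared
        except ValueError as exc:
            values[name] = None
            counts[name] = 0
            notes[name] = str(exc)
    return MiniBarcodeReport(
        r_its1_full=values["r_its1_full"],
        r_its2_full=values["r_its2_full"],
        r_its1_its2=values["r_its1_its2"],
        n_shared_its1_full=counts["r_its1_full"],
        n_shared_its2_full=counts["r_its2_full"],
        n_shared_its1_its2=counts["r_its1_its2"],
        n_split_failed=regions.n_failed,
        notes=notes,
    )
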