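"""Barcode-gap analysis and false-negative / false-positive error detection.

A *false negative* is a pair of distinct morphological species carrying
identical barcodes (0 bp difference); a *false positive* is a morphological
species whose collections carry more than one barcode (maximum within-species
difference above a cutoff).  Flagged entries are classified by taxonomic
severity — congeneric, confamilial, moderate (different family, same order)
or major (different order) — so that a reviewer can separate probable
synonyms/species complexes from outright misidentifications or mixed samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

from .distance import SparseDistanceMatrix
from .records import Dataset, TaxonomyIndex, parse_genus

SEVERITY_LEVELS = ("congeneric", "confamilial", "moderate", "major", "unknown")


@dataclass
class DivergenceProfile:
    """Within- vs between-species bp-difference histograms over retained pairs."""

    bins: np.ndarray  # 0..max bp difference
    intra_counts: np.ndarray
    inter_counts: np.ndarray

    @property
    def n_pairs(self) -> int:
        return int(self.intra_counts.sum() + self.inter_counts.sum())

    def median(self, which: str) -> float:
        counts = self.intra_counts if which == "intra" else self.inter_counts
        values = np.repeat(self.bins, counts)
        return float(np.median(values)) if values.size else float("nan")


def divergence_profile(matrix: SparseDistanceMatrix) -> DivergenceProfile:
    """Bin every retained pair into the intra- or inter-specific curve."""
    pairs = list(matrix.retained_pairs())
    if not pairs:
        raise ValueError("matrix has no retained pairs")
    max_bp = max(p.bp_diff for p in pairs)
    bins = np.arange(max_bp + 1)
    intra = np.zeros(max_bp + 1, dtype=int)
    inter = np.zeros(max_bp + 1, dtype=int)
    for p in pairs:
        (intra if p.same_species else inter)[p.bp_diff] += 1
    return DivergenceProfile(bins=bins, intra_counts=intra, inter_counts=inter)


def classify_severity(species_a: str, species_b: str, taxonomy: TaxonomyIndex) -> str:
    """Severity of confusing *species_a* with *species_b*.

    Shared rank decides: genus → congeneric, family → confamilial, order →
    moderate, nothing shared (or different orders) → major.  Genera absent
    from the taxonomy index yield "unknown".
    """
    genus_a, genus_b = parse_genus(species_a), parse_genus(species_b)
    if genus_a == genus_b:
        return "congeneric"
    if genus_a not in taxonomy or genus_b not in taxonomy:
        return "unknown"
    fam_a, fam_b = taxonomy.family_of(genus_a), taxonomy.family_of(genus_b)
    if fam_a and fam_a == fam_b:
        return "confamilial"
    ord_a, ord_b = taxonomy.order_of(genus_a), taxonomy.order_of(genus_b)
    if ord_a and ord_a == ord_b:
        return "moderate"
    return "major"


@dataclass(frozen=True)
class FalseNegativeEntry:
    species_a: str
    species_b: str
    witness: tuple[str, str]
    bp_diff: int
    severity: str


@dataclass(frozen=True)
class FalsePositiveEntry:
    species: str
    max_intra_bp: Optional[int]  # None when a within-species pair was censored
    witness: tuple[str, str]
    any_nonretained: bool


@dataclass(frozen=True)
class NearMissEntry:
    species_a: str
    species_b: str
    witness: tuple[str, str]
    bp_diff: int
    severity: str


@dataclass
class ErrorReport:
    false_negatives: list[FalseNegativeEntry] = field(default_factory=list)
    false_positives: list[FalsePositiveEntry] = field(default_factory=list)
    near_misses: list[NearMissEntry] = field(default_factory=list)

    def severity_counts(self) -> dict[str, int]:
        counts = {s: 0 for s in SEVERITY_LEVELS}
        for e in self.false_negatives:
            counts[e.severity] += 1
        return counts


def _species_of(dataset: Dataset) -> dict[str, str]:
    return {r.specimen_id: r.species for r in dataset.records}


def find_false_negatives(
    matrix: SparseDistanceMatrix,
    dataset: Dataset,
    exact_match: bool = False,
) -> list[FalseNegativeEntry]:
    """Unique unordered pairs of distinct species joined by an identical barcode.

    "Identical" means 0 bp difference under the ambiguity-tolerant alignment;
    ``exact_match=True`` additionally requires byte-identical sequences.
    Output is deduplicated to species pairs (lexicographically smallest
    witness kept) and invariant under specimen relabeling/permutation.
    """
    species = _species_of(dataset)
    seqs = {r.specimen_id: r.sequence for r in dataset.records}
    found: dict[tuple[str, str], FalseNegativeEntry] = {}
    for p in matrix.retained_pairs():
        if p.bp_diff != 0 or p.same_species:
            continue
        if exact_match and seqs.get(p.id_a) != seqs.get(p.id_b):
            continue
        sp_a, sp_b = sorted((species[p.id_a], species[p.id_b]))
        key = (sp_a, sp_b)
        if key not in found:
            found[key] = FalseNegativeEntry(
                species_a=sp_a,
                species_b=sp_b,
                witness=(p.id_a, p.id_b),
                bp_diff=0,
                severity=classify_severity(sp_a, sp_b, dataset.taxonomy),
            )
    return [found[k] for k in sorted(found)]


def find_false_positives(
    matrix: SparseDistanceMatrix,
    dataset: Dataset,
    cutoff_bp: int,
) -> list[FalsePositiveEntry]:
    """Species whose within-species barcode spread exceeds *cutoff_bp*.

    A censored (non-retained) within-species pair counts as exceeding any
    cutoff — those pairs differ by more than the retention threshold.
    """
    if cutoff_bp < 0:
        raise ValueError("cutoff_bp must be >= 0")
    species = _species_of(dataset)
    max_bp: dict[str, int] = {}
    witness_max: dict[str, tuple[str, str]] = {}
    censored_witness: dict[str, tuple[str, str]] = {}
    for p in matrix.all_pairs():
        if not p.same_species:
            continue
        sp = species[p.id_a]
        if not p.retained:
            censored_witness.setdefault(sp, (p.id_a, p.id_b))
        elif sp not in max_bp or p.bp_diff > max_bp[sp]:
            max_bp[sp] = p.bp_diff
            witness_max[sp] = (p.id_a, p.id_b)
    out = []
    for sp in sorted(set(max_bp) | set(censored_witness)):
        censored = sp in censored_witness
        if censored or max_bp[sp] > cutoff_bp:
            out.append(
                FalsePositiveEntry(
                    species=sp,
                    max_intra_bp=None if censored else max_bp[sp],
                    witness=censored_witness.get(sp) or witness_max[sp],
                    any_nonretained=censored,
                )
            )
    return out


def find_near_misses(
    matrix: SparseDistanceMatrix,
    dataset: Dataset,
    max_bp: int = 1,
    collapse_to_species_pairs: bool = False,
) -> list[NearMissEntry]:
    """Cross-species pairs at small (0 < bp ≤ max_bp) differences.

    Counts specimen pairs by default; ``collapse_to_species_pairs`` keeps one
    entry per unordered species pair.
    """
    species = _species_of(dataset)
    entries: list[NearMissEntry] = []
    seen: set[tuple[str, str]] = set()
    for p in matrix.retained_pairs():
        if p.same_species or p.bp_diff == 0 or p.bp_diff > max_bp:
            continue
        sp_a, sp_b = sorted((species[p.id_a], species[p.id_b]))
        if collapse_to_species_pairs:
            if (sp_a, sp_b) in seen:
                continue
            seen.add((sp_a, sp_b))
        entries.append(
            NearMissEntry(
                species_a=sp_a,
                species_b=sp_b,
                witness=(p.id_a, p.id_b),
                bp_diff=p.bp_diff,
                severity=classify_severity(sp_a, sp_b, dataset.taxonomy),
            )
        )
    return entries


def build_error_report(
    matrix: SparseDistanceMatrix,
    dataset: Dataset,
    fp_cutoff_bp: int = 14,
    near_miss_bp: int = 1,
) -> ErrorReport:
    """Full error report; the default false-positive cutoff corresponds to
    ~2% of a 700 bp amplicon, the divergence regime where most false
    positives disappear while false negatives persist."""
    return ErrorReport(
        false_negatives=find_false_negatives(matrix, dataset),
        false_positives=find_false_positives(matrix, dataset, fp_cutoff_bp),
        near_misses=find_near_misses(matrix, dataset, near_miss_bp),
    )


@dataclass(frozen=True)
class SweepPoint:
    cutoff: int
    lumping: int   # cross-species pairs at <= cutoff (would be merged)
    splitting: int  # within-species pairs at > cutoff (would be split)


def threshold_sweep(matrix: SparseDistanceMatrix, cutoffs: Iterable[int]) -> list[SweepPoint]:
    """Lumping/splitting error counts of a similarity cutoff, per cutoff.

    Censored within-species pairs count as splitting at every cutoff (their
    difference exceeds the retention threshold, hence any sweep cutoff).
    Lumping is non-decreasing and splitting non-increasing in the cutoff.
    """
    cutoffs = list(cutoffs)
    if cutoffs != sorted(cutoffs):
        raise ValueError("cutoffs must be sorted ascending")
    intra = [p.bp_diff for p in matrix.retained_pairs() if p.same_species]
    inter = [p.bp_diff for p in matrix.retained_pairs() if not p.same_species]
    censored_intra = sum(1 for p in matrix.nonretained.values() if p.same_species)
    points = []
    for c in cutoffs:
        lump = sum(1 for d in inter if d <= c)
        split = sum(1 for d in intra if d > c) + censored_intra
        points.append(SweepPoint(cutoff=c, lumping=lump, splitting=split))
    return points
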