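"""Contingency analysis of PCR-success factors.

Amplification success from herbarium material depends on specimen age (DNA
degradation) and on taxon (pigments, polysaccharides, spore-wall chemistry).
This module tests those associations with a Pearson chi-square test of
independence and localizes the signal cell-by-cell with Haberman
standardized adjusted residuals,

    r_ij = (O_ij − E_ij) / sqrt(E_ij (1 − row_i/n)(1 − col_j/n)),

approximately standard normal under independence.  Cell significance is
judged against a Bonferroni-corrected alpha with the number of contrasts
equal to the number of cells (a 3×2 table gives 0.05/6 ≈ 0.0083), and each
cell's share of the omnibus statistic is reported as its relative
contribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy import stats

from .records import Dataset

#: Default age strata used by the taxon-by-age stratified analysis.
DEFAULT_STRATA: dict[str, tuple[int, int]] = {
    "1980s-1990s": (1980, 1999),
    "2000s": (2000, 2009),
}


@dataclass
class ContingencyTable:
    row_labels: list[str]
    col_labels: list[str]
    observed: np.ndarray  # (r, c) integer counts

    def __post_init__(self) -> None:
        self.observed = np.asarray(self.observed, dtype=float)
        if self.observed.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("observed shape does not match labels")
        if self.observed.shape[0] < 2 or self.observed.shape[1] < 2:
            raise ValueError("contingency table needs at least 2 rows and 2 columns")
        if (self.observed < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def n(self) -> int:
        return int(self.observed.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.observed.astype(int), index=self.row_labels, columns=self.col_labels)

    def success_rates(self, positive_col: str = "positive") -> dict[str, float]:
        """Per-row success fraction, e.g. Table-1-style sequence success rates."""
        j = self.col_labels.index(positive_col)
        totals = self.observed.sum(axis=1)
        return {
            lab: float(self.observed[i, j] / totals[i]) if totals[i] else float("nan")
            for i, lab in enumerate(self.row_labels)
        }


def build_table(
    dataset: Dataset,
    row_factor: str = "decade",
    outcome: str = "pcr_positive",
    strata: Optional[dict[str, tuple[int, int]]] = None,
) -> Union[ContingencyTable, dict[str, ContingencyTable]]:
    """Tally records into a (factor × outcome) table, optionally per age stratum.

    ``row_factor`` is "decade" (floor(year/10)*10) or "genus"; ``outcome`` is
    "pcr_positive" or "sequence_positive".  Records missing the factor or
    outcome are excluded.  With *strata* (name → inclusive year range) one
    table per stratum is returned.
    """
    if strata is not None:
        out = {}
        for name, (lo, hi) in strata.items():
            sub = Dataset(
                records=[r for r in dataset.records
                         if r.collection_year is not None and lo <= r.collection_year <= hi],
                taxonomy=dataset.taxonomy,
            )
            out[name] = build_table(sub, row_factor=row_factor, outcome=outcome)
        return out

    rows: dict[str, list[int]] = {}
    for r in dataset.records:
        flag = getattr(r, outcome)
        if flag is None:
            continue
        if row_factor == "decade":
            if r.collection_year is None:
                continue
            label = f"{r.decade}s"
        elif row_factor == "genus":
            if not r.genus:
                continue
            label = r.genus
        else:
            raise ValueError("row_factor must be 'decade' or 'genus'")
        cell = rows.setdefault(label, [0, 0])
        cell[0 if flag else 1] += 1
    labels = sorted(rows)
    if len(labels) < 2:
        raise ValueError(f"fewer than 2 non-empty {row_factor} rows")
    observed = np.array([rows[lab] for lab in labels])
    return ContingencyTable(row_labels=labels, col_labels=["positive", "negative"], observed=observed)


@dataclass
class PostHocResult:
    table: ContingencyTable
    expected: np.ndarray
    chi2: float
    df: int
    p_value: float
    std_residuals: np.ndarray       # (O − E) / sqrt(E)
    adjusted_residuals: np.ndarray  # Haberman STARs
    cell_contributions: np.ndarray  # cell chi2 / omnibus chi2
    alpha: float
    alpha_corrected: float
    n_contrasts: int
    significant: np.ndarray         # |adjusted| above z(alpha_corrected/2)
    small_expected_cells: list[tuple[str, str]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, rl in enumerate(self.table.row_labels):
            for j, cl in enumerate(self.table.col_labels):
                rows.append(
                    {
                        "row": rl, "col": cl,
                        "observed": int(self.table.observed[i, j]),
                        "expected": self.expected[i, j],
                        "std_residual": self.std_residuals[i, j],
                        "adjusted_residual": self.adjusted_residuals[i, j],
                        "contribution": self.cell_contributions[i, j],
                        "significant": bool(self.significant[i, j]),
                    }
                )
        return pd.DataFrame(rows)


def chi_square_posthoc(
    table: ContingencyTable,
    alpha: float = 0.05,
    yates: bool = False,
) -> PostHocResult:
    """Pearson chi-square omnibus test with Haberman post-hoc residuals.

    No continuity correction by default (Pearson chi-square); ``yates=True``
    applies it to the omnibus statistic only.  The Bonferroni denominator is
    the number of cells (rows × columns).
    """
    O = table.observed
    n = O.sum()
    row = O.sum(axis=1)
    col = O.sum(axis=0)
    if (row == 0).any() or (col == 0).any():
        raise ValueError("zero marginal total in contingency table")
    E = np.outer(row, col) / n
    small = [
        (table.row_labels[i], table.col_labels[j])
        for i, j in zip(*np.where(E < 1e-12))
    ]
    if small:
        import warnings
        warnings.warn(f"zero expected counts in cells {small}")

    resid = O - E
    if yates:
        cell_chi2 = (np.abs(resid) - 0.5).clip(min=0) ** 2 / E
    else:
        cell_chi2 = resid ** 2 / E
    chi2 = float(cell_chi2.sum())
    r, c = O.shape
    df = (r - 1) * (c - 1)
    p_value = float(stats.chi2.sf(chi2, df))

    std_resid = resid / np.sqrt(E)
    adj_denom = np.sqrt(E * np.outer(1.0 - row / n, 1.0 - col / n))
    adjusted = resid / adj_denom
    contributions = (resid ** 2 / E) / chi2 if chi2 > 0 else np.zeros_like(E)

    n_contrasts = r * c
    alpha_corr = alpha / n_contrasts
    z_crit = stats.norm.isf(alpha_corr / 2.0)
    significant = np.abs(adjusted) > z_crit
    return PostHocResult(
        table=table, expected=E, chi2=chi2, df=df, p_value=p_value,
        std_residuals=std_resid, adjusted_residuals=adjusted,
        cell_contributions=contributions,
        alpha=alpha, alpha_corrected=alpha_corr, n_contrasts=n_contrasts,
        significant=significant, small_expected_cells=small,
    )


@dataclass
class StratifiedReport:
    """Per-stratum post-hoc results with dual-alpha significance marks."""

    results: dict[str, PostHocResult]
    narrative: pd.DataFrame

    def result(self, stratum: str) -> PostHocResult:
        return self.results[stratum]


def stratified_report(
    dataset: Dataset,
    alpha: float = 0.05,
    row_factor: str = "genus",
    outcome: str = "pcr_positive",
    strata: Optional[dict[str, tuple[int, int]]] = None,
) -> StratifiedReport:
    """Taxon-by-outcome analysis controlled for specimen age.

    One chi-square post-hoc per age stratum; the narrative table marks each
    (stratum, row, cell) at both the raw alpha ("*") and the
    Bonferroni-corrected alpha ("§"), mirroring a dual-alpha presentation.
    """
    strata = strata if strata is not None else DEFAULT_STRATA
    tables = build_table(dataset, row_factor=row_factor, outcome=outcome, strata=strata)
    results: dict[str, PostHocResult] = {}
    rows = []
    z_raw = stats.norm.isf(alpha / 2.0)
    for name in strata:
        tab = tables[name]
        res = chi_square_posthoc(tab, alpha=alpha)
        results[name] = res
        for i, lab in enumerate(tab.row_labels):
            for j, cl in enumerate(tab.col_labels):
                ar = res.adjusted_residuals[i, j]
                rows.append(
                    {
                        "stratum": name, "row": lab, "col": cl,
                        "observed": int(tab.observed[i, j]),
                        "expected": res.expected[i, j],
                        "adjusted_residual": ar,
                        "sig_raw": bool(abs(ar) > z_raw),
                        "sig_bonferroni": bool(res.significant[i, j]),
                        "marks": ("*" if abs(ar) > z_raw else "")
                                 + ("§" if res.significant[i, j] else ""),
                    }
                )
    if len(results) < 1:
        raise ValueError("no valid strata")
    return StratifiedReport(results=results, narrative=pd.DataFrame(rows))
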