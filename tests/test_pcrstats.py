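"""Contingency tables, chi-square post-hoc formulas, stratified reporting."""

import numpy as np
import pytest
from scipy import stats

import barcodeaudit as ba
from barcodeaudit.pcrstats import (
    ContingencyTable,
    build_table,
    chi_square_posthoc,
    stratified_report,
)
from barcodeaudit.records import Dataset, SpecimenRecord


def rec(sid, genus, year, pcr):
    return SpecimenRecord(sid, f"{genus} sp", genus=genus,
                          collection_year=year, pcr_positive=pcr)


class TestBuildTable:
    def test_direct_tally(self):
        ds = Dataset(records=[
            rec("a", "X", 1985, True), rec("b", "X", 1985, False),
            rec("c", "X", 2003, True), rec("d", "X", 2003, True)])
        t = build_table(ds, "decade", "pcr_positive")
        assert t.row_labels == ["1980s", "2000s"]
        assert t.observed.tolist() == [[1, 1], [2, 0]]

    def test_single_decade_errors(self):
        ds = Dataset(records=[rec("a", "X", 1985, True), rec("b", "X", 1986, False)])
        with pytest.raises(ValueError, match="fewer than 2"):
            build_table(ds, "decade", "pcr_positive")

    def test_strata_partition_totals(self):
        ds, _ = ba.generate(ba.GeneratorConfig(seed=61))
        full = build_table(ds, "genus", "pcr_positive")
        parts = build_table(ds, "genus", "pcr_positive",
                            strata={"old": (1980, 1999), "new": (2000, 2009)})
        assert full.n == parts["old"].n + parts["new"].n

    def test_missing_outcome_excluded(self):
        ds = Dataset(records=[
            rec("a", "X", 1985, True), rec("b", "X", 1995, None), rec("c", "X", 1995, False)])
        t = build_table(ds, "decade", "pcr_positive")
        assert t.n == 2


class TestChiSquarePosthoc:
    def test_exact_independence_all_zero(self):
        t = ContingencyTable(["a", "b"], ["positive", "negative"], np.array([[10, 10], [10, 10]]))
        res = chi_square_posthoc(t)
        assert res.chi2 == 0.0
        assert res.p_value == pytest.approx(1.0)
        assert np.allclose(res.adjusted_residuals, 0.0)

    def test_closed_form_worked_example(self):
        # [[30,10],[10,30]]: E = 20 everywhere, chi2 = 4*(100/20) = 20, df 1,
        # adjusted residuals +-sqrt(20)
        t = ContingencyTable(["a", "b"], ["positive", "negative"], np.array([[30, 10], [10, 30]]))
        res = chi_square_posthoc(t)
        assert res.chi2 == pytest.approx(20.0)
        assert res.df == 1
        assert np.allclose(np.abs(res.adjusted_residuals), np.sqrt(20.0))

    def test_bonferroni_denominator_is_cell_count(self):
        t = ContingencyTable(["a", "b", "c"], ["positive", "negative"],
                             np.array([[20, 10], [15, 15], [5, 25]]))
        res = chi_square_posthoc(t, alpha=0.05)
        assert res.n_contrasts == 6
        assert res.alpha_corrected == pytest.approx(0.05 / 6)

    def test_contributions_sum_to_one(self, small_dataset):
        dataset, _ = small_dataset
        t = build_table(dataset, "decade", "pcr_positive")
        res = chi_square_posthoc(t)
        assert res.cell_contributions.sum() == pytest.approx(1.0, abs=1e-12)

    def test_2x2_omnibus_equals_squared_adjusted_residual(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            O = rng.integers(1, 60, size=(2, 2))
            t = ContingencyTable(["a", "b"], ["positive", "negative"], O)
            res = chi_square_posthoc(t)
            assert np.allclose(res.adjusted_residuals ** 2, res.chi2)

    def test_matches_scipy_omnibus(self):
        rng = np.random.default_rng(2)
        O = rng.integers(5, 80, size=(3, 2))
        t = ContingencyTable(["a", "b", "c"], ["positive", "negative"], O)
        res = chi_square_posthoc(t)
        ref = stats.chi2_contingency(O, correction=False)
        assert res.chi2 == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue)
        assert np.allclose(res.expected, ref.expected_freq)

    def test_zero_marginal_errors(self):
        t = ContingencyTable(["a", "b"], ["positive", "negative"], np.array([[0, 0], [10, 5]]))
        with pytest.raises(ValueError, match="marginal"):
            chi_square_posthoc(t)

    def test_pvalue_matches_permutation_monte_carlo(self):
        # permutation oracle: permute outcomes across individuals, conditional
        # on both margins; chi2 p-value within 3 SE of the permutation p
        O = np.array([[30, 20], [18, 32], [25, 25]])
        t = ContingencyTable(["a", "b", "c"], ["positive", "negative"], O)
        res = chi_square_posthoc(t)
        rows = np.repeat(np.arange(3), O.sum(axis=1))
        outcomes = np.concatenate([np.concatenate([np.ones(int(o[0])), np.zeros(int(o[1]))])
                                   for o in O])
        rng = np.random.default_rng(3)
        n_perm = 4000
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(outcomes)
            tab = np.zeros((3, 2))
            for r in range(3):
                pos = perm[rows == r].sum()
                tab[r] = (pos, (rows == r).sum() - pos)
            E = np.outer(tab.sum(1), tab.sum(0)) / tab.sum()
            chi2 = ((tab - E) ** 2 / E).sum()
            count += chi2 >= res.chi2 - 1e-9
        p_perm = count / n_perm
        se = np.sqrt(p_perm * (1 - p_perm) / n_perm)
        assert abs(res.p_value - p_perm) < 3 * se + 0.005

    def test_strong_decade_effect_flags_oldest_decade(self):
        # generator with a steep age effect: the oldest-decade cells must come
        # out significant with the sign the simulated effect implies
        model = ba.SuccessModel(intercept=1.5, per_decade_age=-1.0)
        ds, _ = ba.generate(ba.GeneratorConfig(
            n_genera=2, species_per_genus=5, accessions_per_species=40,
            year_range=(1980, 2005), success_model=model, seed=71))
        t = build_table(ds, "decade", "pcr_positive")
        res = chi_square_posthoc(t)
        oldest = t.row_labels.index("1980s")
        pos_col = t.col_labels.index("positive")
        assert res.significant[oldest, pos_col]
        assert res.adjusted_residuals[oldest, pos_col] < 0


class TestStratifiedReport:
    def test_null_genus_effect_type_one_rate(self):
        # zero genus offsets: fraction of genus cells significant at raw alpha
        # should be near alpha over replicates
        hits = trials = 0
        for seed in range(10):
            ds, _ = ba.generate(ba.GeneratorConfig(
                n_genera=4, species_per_genus=3, accessions_per_species=12, seed=500 + seed))
            rep = stratified_report(ds)
            narr = rep.narrative
            hits += int(narr["sig_raw"].sum())
            trials += len(narr)
        rate = hits / trials
        se = np.sqrt(0.05 * 0.95 / trials)
        # adjusted residual cells within a table are correlated; allow wide band
        assert rate < 0.05 + 5 * se

    def test_negative_genus_offset_flagged_with_negative_residual(self):
        wins = 0
        for seed in range(5):
            model = ba.SuccessModel(intercept=1.0, per_decade_age=-0.2,
                                    genus_offsets=(("Genus01", -2.0),))
            ds, _ = ba.generate(ba.GeneratorConfig(
                n_genera=3, species_per_genus=4, accessions_per_species=15,
                success_model=model, seed=600 + seed))
            rep = stratified_report(ds)
            narr = rep.narrative
            sel = narr[(narr["row"] == "Genus01") & (narr["col"] == "positive")]
            if ((sel["adjusted_residual"] < 0) & sel["sig_raw"]).any():
                wins += 1
        assert wins >= 4

    def test_single_stratum_degenerates_to_posthoc(self):
        ds, _ = ba.generate(ba.GeneratorConfig(seed=81))
        rep = stratified_report(ds, strata={"all": (1900, 2100)})
        direct = chi_square_posthoc(build_table(ds, "genus", "pcr_positive"))
        assert rep.result("all").chi2 == pytest.approx(direct.chi2)


def test_rescue_success_rates_from_counts():
    # per-genus mini-barcode rescue: sequencing successes out of 30 samples
    t = ContingencyTable(
        ["Cortinarius", "Mycena", "Russula"], ["positive", "negative"],
        np.array([[24, 6], [4, 26], [27, 3]]),
    )
    rates = t.success_rates()
    assert rates["Cortinarius"] == pytest.approx(0.80)
    assert rates["Russula"] == pytest.approx(0.90)
    assert rates["Mycena"] == pytest.approx(4 / 30)
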