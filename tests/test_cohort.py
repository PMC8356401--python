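"""Cohort summaries, subgroup rules, and the supporting statistics."""

import numpy as np
import pytest
from scipy import stats

import strokestop as ss
from strokestop.cohort import (
    ContingencyTable,
    DegenerateTableError,
    EmptyInputError,
    EmptySelectionError,
    InsufficientDataError,
    effective_index,
)
from strokestop.model import Cohort, PatientRecord, PlaqueEchogenicity, StenosisGrade
from strokestop.model import StenosisCategory


def brute_force_chi2(counts):
    """Independent oracle: expected counts E = row*col/N, summed Pearson terms."""
    arr = np.asarray(counts, dtype=float)
    n = arr.sum()
    stat = 0.0
    for i in range(arr.shape[0]):
        for j in range(arr.shape[1]):
            expected = arr[i].sum() * arr[:, j].sum() / n
            stat += (arr[i, j] - expected) ** 2 / expected
    df = (arr.shape[0] - 1) * (arr.shape[1] - 1)
    return stat, df, float(stats.chi2.sf(stat, df))


def make_table(counts):
    arr = np.asarray(counts)
    return ContingencyTable(
        counts=tuple(tuple(int(x) for x in row) for row in arr),
        row_labels=tuple(f"r{i}" for i in range(arr.shape[0])),
        column_labels=tuple(f"c{j}" for j in range(arr.shape[1])),
    )


class TestChiSquare:
    def test_perfect_independence(self):
        stat, df, p = ss.chi_square_independence(make_table([[10, 10], [10, 10]]))
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert df == 1
        assert p == pytest.approx(1.0)

    def test_published_echolucent_comparison(self):
        # symptomatic vs asymptomatic stenosis-severity counts, echolucent plaque;
        # the source reports p = 0.025 for this comparison, which does not match
        # the Pearson statistic on the printed counts — the computed value is
        # asserted here and the discrepancy is documented, not reconciled.
        stat, df, p = ss.chi_square_independence(ss.table2_contingency("echolucent"))
        assert stat == pytest.approx(8.4536, abs=1e-3)
        assert df == 2
        assert p == pytest.approx(0.0146, abs=1e-3)

    def test_degenerate_margin_rejected(self):
        with pytest.raises(DegenerateTableError):
            ss.chi_square_independence(make_table([[1, 0], [3, 0]]))

    def test_matches_brute_force_on_random_tables(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            shape = rng.choice([(2, 2), (2, 3), (3, 3)])
            counts = rng.integers(0, 21, size=tuple(shape))
            if (counts.sum(0) == 0).any() or (counts.sum(1) == 0).any():
                continue
            got = ss.chi_square_independence(make_table(counts))
            want = brute_force_chi2(counts)
            assert got[0] == pytest.approx(want[0], rel=1e-12, abs=1e-12)
            assert got[1] == want[1]
            assert got[2] == pytest.approx(want[2], rel=1e-9)

    def test_table_validation(self):
        with pytest.raises(ValueError):
            make_table([[1, 2]])  # fewer than 2 rows
        with pytest.raises(ValueError):
            make_table([[1, -2], [3, 4]])


class TestAnova:
    def test_identical_groups_give_zero_f(self):
        f, p = ss.one_way_anova([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert f == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_two_group_f_equals_t_squared(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(0, 1, 12), rng.normal(0.5, 1, 15)
        f, p_f = ss.one_way_anova([a, b])
        t, p_t = stats.ttest_ind(a, b, equal_var=True)
        assert f == pytest.approx(t**2, rel=1e-10)
        assert p_f == pytest.approx(p_t, rel=1e-10)

    def test_large_shift_detected_in_most_replicates(self):
        # simulation oracle: 3-SD mean shift at n=30/group
        rng = np.random.default_rng(11)
        hits = sum(
            ss.one_way_anova([rng.normal(0, 1, 30), rng.normal(3, 1, 30)])[1] < 0.05
            for _ in range(200)
        )
        assert hits / 200 >= 0.99

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            ss.one_way_anova([[1.0, 2.0]])
        with pytest.raises(InsufficientDataError):
            ss.one_way_anova([[1.0], [2.0, 3.0]])
        with pytest.raises(InsufficientDataError):
            ss.one_way_anova([[2.0, 2.0], [2.0, 2.0]])


class TestTukey:
    def test_identical_groups_nothing_flagged(self):
        g = [1.0, 2.0, 3.0, 4.0]
        comps = ss.tukey_hsd([g, g, g])
        assert len(comps) == 3
        assert not any(c.significant for c in comps)

    def test_far_shifted_group_flags_exactly_its_pairs(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 1, 25)
        b = rng.normal(0, 1, 25)
        c = rng.normal(5, 1, 25)  # 5-SD shift
        comps = ss.tukey_hsd([a, b, c])
        flagged = {(x.group_a, x.group_b) for x in comps if x.significant}
        assert flagged == {(0, 2), (1, 2)}

    def test_flags_symmetric_under_group_reordering(self):
        rng = np.random.default_rng(4)
        groups = [rng.normal(m, 1, 20) for m in (0, 0, 4)]
        direct = {(c.group_a, c.group_b): c.significant for c in ss.tukey_hsd(groups)}
        swapped = {
            (c.group_a, c.group_b): c.significant for c in ss.tukey_hsd(groups[::-1])
        }
        assert direct[(0, 2)] == swapped[(0, 2)]
        assert direct[(0, 1)] == swapped[(1, 2)]


class TestPearson:
    def test_perfect_linear(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert ss.pearson_correlation(x, [2 * v + 1 for v in x])[0] == pytest.approx(1.0)
        assert ss.pearson_correlation(x, [-v for v in x])[0] == pytest.approx(-1.0)

    def test_independent_samples_near_zero(self):
        rng = np.random.default_rng(8)
        hits = sum(
            abs(ss.pearson_correlation(rng.normal(size=1000), rng.normal(size=1000))[0]) < 0.1
            for _ in range(100)
        )
        assert hits >= 99

    def test_degenerate_inputs(self):
        with pytest.raises(InsufficientDataError):
            ss.pearson_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            ss.pearson_correlation([1.0, 2.0], [1.0, 2.0, 3.0])


def _rec(pid, index=None, plaque=None, pct=None, lp=None, sdvr=None, group=None):
    return PatientRecord(
        patient_id=pid,
        group=group,
        sdvr=sdvr,
        lp_pla2=lp,
        plaque=PlaqueEchogenicity.parse(plaque) if plaque else None,
        stenosis=(
            StenosisGrade(
                category=StenosisCategory.GE70 if pct >= 70 else StenosisCategory.S50_69,
                percent=pct,
            )
            if pct is not None
            else None
        ),
        printed_index=index,
    )


class TestSummarize:
    def test_fixture_band_counts_and_range(self, table3):
        s = ss.summarize_cohort(table3)
        assert s.n_by_band == {"low": 6, "medium": 16, "high": 48}
        assert s.lp_pla2_min == pytest.approx(252.7)
        assert s.lp_pla2_max == pytest.approx(328.6)
        assert s.n_total == 70
        assert s.skipped == []
        assert sum(s.n_by_band.values()) == 70

    def test_band_counts_invariant_to_record_order(self, table3):
        reordered = Cohort(records=list(table3.records[::-1]), provenance="reversed")
        assert ss.summarize_cohort(reordered).n_by_band == ss.summarize_cohort(table3).n_by_band

    def test_histogram_bins_are_half_open(self):
        cohort = Cohort(
            records=[_rec("a", index=70.0, lp=280.0), _rec("b", index=69.999, lp=280.0)]
        )
        s = ss.summarize_cohort(cohort, bin_width=10.0)
        counts = s.index_histogram["counts"]
        edges = s.index_histogram["bin_edges"]
        assert edges[:2] == [0.0, 10.0]
        assert counts[6] == 1  # [60, 70)
        assert counts[7] == 1  # [70, 80)
        assert sum(s.n_by_band.values()) == 2

    def test_single_record_cohort(self):
        s = ss.summarize_cohort(Cohort(records=[_rec("a", index=58.0, lp=252.9)]))
        assert s.n_by_band == {"low": 1, "medium": 0, "high": 0}

    def test_unscoreable_records_reported_skipped(self):
        cohort = Cohort(records=[_rec("a", index=58.0, lp=250.0), _rec("ctl", lp=220.0)])
        s = ss.summarize_cohort(cohort)
        assert s.skipped == ["ctl"]

    def test_empty_cohort_rejected(self):
        with pytest.raises(EmptyInputError):
            ss.summarize_cohort(Cohort(records=[]))

    def test_computed_index_preferred_over_printed(self):
        rec = _rec("a", index=999.0, plaque="echogenic", lp=285.0, sdvr=3.0)
        assert effective_index(rec) == pytest.approx(57.0)


class TestSubgroupMinIndex:
    def test_fixture_echolucent_rule(self, table3):
        assert ss.subgroup_min_index(table3, "echolucent", 70, 285) == pytest.approx(123)

    def test_fixture_heterogeneous_rule(self, table3):
        assert ss.subgroup_min_index(table3, "heterogeneous", 80, 285) == pytest.approx(127)

    def test_filters_are_strict(self, table3):
        # row with stenosis exactly 70 must not qualify under stenosis > 70
        loose = ss.subgroup_min_index(table3, "echolucent", 69.9, 285)
        assert loose <= ss.subgroup_min_index(table3, "echolucent", 70, 285)

    def test_impossible_filter_raises(self, table3):
        with pytest.raises(EmptySelectionError):
            ss.subgroup_min_index(table3, "echolucent", 70, 1e6)


def test_fixture_printed_index_round_trip(table3):
    # loader + formula wiring: implied SDVR from the printed index feeds the
    # formula back to the printed index
    for rec in table3:
        sdvr = ss.implied_sdvr(rec.printed_index, rec.lp_pla2, rec.plaque)
        back = ss.stroke_stop_index(sdvr, rec.lp_pla2, rec.plaque)
        assert back == pytest.approx(rec.printed_index, rel=1e-9)
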