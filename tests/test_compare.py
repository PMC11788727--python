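"""Before/after comparison pipeline and the significance tests."""

import warnings

import numpy as np
import pytest
from scipy import stats

from westgardqc import (
    ComparisonConfig,
    ComparisonRow,
    ComparisonTable,
    FailureCounts,
    aggregate_totals,
    association_tests,
    compare_counts,
    load_table1_fixture,
    run_comparison,
    table_from_fixture,
)
from westgardqc.errors import ConfigurationError, QCWarning, ValidationError
from westgardqc.qc_io import ChartSeries

from conftest import fisher_two_sided_exact, make_chart


def fc(t, w, r):
    return FailureCounts(t, w, r)


class TestCompareCounts:
    @pytest.mark.parametrize(
        "before,after,expected",
        [
            ((0, 0, 0), (0, 0, 0), False),     # group 1
            ((3, 2, 1), (8, 1, 7), True),      # group 7
            ((2, 2, 0), (2, 0, 2), True),      # group 17: severity composition shifts
        ],
    )
    def test_any_component_criterion(self, before, after, expected):
        assert compare_counts(fc(*before), fc(*after)) is expected


class TestAggregation:
    def test_fixture_totals(self):
        rows = table_from_fixture(load_table1_fixture()).rows
        tb, ta = aggregate_totals(rows)
        assert (tb.total, tb.warning, tb.rejection) == (26, 21, 5)
        assert (ta.total, ta.warning, ta.rejection) == (36, 12, 24)

    def test_permutation_invariance(self, rng):
        rows = list(table_from_fixture(load_table1_fixture()).rows)
        shuffled = [rows[i] for i in rng.permutation(len(rows))]
        assert aggregate_totals(rows) == aggregate_totals(shuffled)

    def test_single_row_identity(self):
        row = ComparisonRow(1, "c", fc(3, 2, 1), fc(1, 1, 0), True)
        assert aggregate_totals([row]) == (row.before, row.after)

    def test_empty_rows_rejected(self):
        with pytest.raises(ValidationError):
            aggregate_totals([])

    def test_computed_flag_reported_alongside_published_label(self):
        # the any-component criterion flags 12 rows; the published labels say 11
        table = table_from_fixture(load_table1_fixture())
        assert sum(r.differs for r in table.rows) == 12
        assert sum(r.paper_label for r in table.rows) == 11
        (disagreement,) = [r for r in table.rows if r.differs != r.paper_label]
        assert disagreement.group_no == 17


def two_lot_chart(values_a, values_b, chart_id="a:L1"):
    a = make_chart(values_a, chart_id=chart_id, lot_id="old")
    b = make_chart(values_b, chart_id=chart_id, lot_id="new", start_index=len(values_a))
    return ChartSeries.from_observations(chart_id, a.observations + b.observations)


class TestRunComparison:
    def test_identical_limits_give_no_differences(self, rng):
        """When the outgoing lot is an exact rescaling of the incoming lot,
        the pooled CV equals the incoming lot's CV, so both schemes yield
        identical limits and every row's counts agree."""
        charts = []
        for k in range(4):
            xb = rng.normal(100, 3, 25)
            charts.append(two_lot_chart(1.3 * xb, xb, chart_id=f"a{k}:L1"))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", QCWarning)
            table = run_comparison(charts, config=ComparisonConfig(establishment_runs=25))
        assert all(not r.differs for r in table.rows)

    def test_single_lot_chart_is_configuration_error(self):
        chart = make_chart(list(range(1, 25)), lot_id="only")
        with pytest.raises(ConfigurationError, match="a:L1"):
            run_comparison([chart])

    def test_inflated_crossover_sd_misses_shifts(self, rng):
        """A 2.5-SD shift after the establishment window: actual limits see
        more rejection failures than 1.5x-inflated cross-over limits in
        nearly all replicates (small-scale directional check)."""
        wins = 0
        reps = 20
        for rep in range(reps):
            r = np.random.default_rng(500 + rep)
            charts = []
            for k in range(6):
                xa = r.normal(100, 3, 20)
                xb = np.concatenate([r.normal(100, 3, 20), r.normal(100 + 2.5 * 3, 3, 10)])
                charts.append(two_lot_chart(xa, xb, chart_id=f"a{k}:L1"))
            table = run_comparison(
                charts, config=ComparisonConfig(crossover_inflation=1.5)
            )
            wins += table.totals_after.rejection > table.totals_before.rejection
        assert wins >= int(0.9 * reps)


class TestAssociationTests:
    def test_fixture_severity_table_is_significant(self):
        table = table_from_fixture(load_table1_fixture())
        sev, paired = association_tests(table)
        assert sev.test_name == "chi_square"  # all expected counts >= 5 here
        assert sev.odds_ratio == pytest.approx(8.4)
        assert sev.significant and sev.p_value < 0.05
        assert paired.test_name == "paired_t" and not paired.degenerate

    def test_no_association_when_conditions_identical(self):
        rows = [ComparisonRow(i, f"c{i}", fc(2, 1, 1), fc(2, 1, 1), False) for i in range(1, 11)]
        sev, paired = association_tests(ComparisonTable.from_rows(rows))
        assert sev.odds_ratio == pytest.approx(1.0)
        assert sev.p_value == pytest.approx(1.0)
        assert paired.p_value == pytest.approx(1.0) and paired.degenerate

    def test_balanced_chi_square_is_zero(self):
        rows = [ComparisonRow(i, f"c{i}", fc(2, 1, 1), fc(2, 1, 1), False) for i in range(1, 11)]
        table = ComparisonTable.from_rows(rows)  # [[10,10],[10,10]]
        sev = association_tests(table)[0]
        assert sev.test_name == "chi_square"
        assert sev.statistic == pytest.approx(0.0)
        assert sev.p_value == pytest.approx(1.0)

    def test_zero_margin_is_degenerate(self):
        rows = [ComparisonRow(1, "c", fc(2, 2, 0), fc(3, 3, 0), True)]
        sev = association_tests(ComparisonTable.from_rows(rows))[0]
        assert sev.degenerate and sev.p_value == 1.0 and not sev.significant

    def test_fisher_branch_for_sparse_tables(self):
        rows = [ComparisonRow(1, "c", fc(3, 2, 1), fc(4, 1, 3), True)]
        sev = association_tests(ComparisonTable.from_rows(rows))[0]
        assert sev.test_name == "fisher_exact"
        expected = fisher_two_sided_exact(2, 1, 1, 3)
        assert sev.p_value == pytest.approx(expected, rel=1e-12)


class TestFisherOracle:
    def test_library_matches_exact_enumeration(self, rng):
        """scipy's two-sided Fisher p equals exact rational hypergeometric
        enumeration on random 2x2 tables with margins <= 30."""
        for _ in range(200):
            a, b, c, d = (int(v) for v in rng.integers(0, 16, size=4))
            if min(a + b, c + d, a + c, b + d) == 0:
                continue
            _, p = stats.fisher_exact([[a, b], [c, d]])
            assert p == pytest.approx(fisher_two_sided_exact(a, b, c, d), rel=1e-11, abs=1e-14)
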