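"""Before/after comparison of failure counts under the two limit schemes.

For every chart the pipeline derives control limits twice —

* "before": cross-over pooled CV of the two lots, applied around a target
  mean (by default the incoming lot's provisional mean);
* "after": the incoming lot's own established mean and SD —

evaluates the Westgard rules on the incoming lot's series under each
limit set, tallies warning/rejection failures, flags per-chart
differences, sums column totals, and runs the study's significance tests:
a 2x2 test on the warning/rejection composition of the totals (chi-square
with continuity correction when expected counts allow, Fisher exact
otherwise) and a paired t-test on per-chart total failures.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, ValidationError
from .limits import (
    compute_lot_summary,
    crossover_cv,
    derive_limits_actual,
    derive_limits_crossover,
)
from .qc_io import ChartSeries, Table1Row
from .rules import FailureCounts, RuleConfig, count_failures, evaluate_rules, zscore_series

__all__ = [
    "ComparisonConfig",
    "ComparisonRow",
    "ComparisonTable",
    "AssociationResult",
    "compare_counts",
    "aggregate_totals",
    "run_comparison",
    "table_from_fixture",
    "association_tests",
]


@dataclass(frozen=True)
class ComparisonConfig:
    """Pipeline knobs.

    establishment_runs
        Runs of the incoming lot used to establish its provisional mean
        (cross-over scheme) and actual mean/SD; the conventional 20 by
        default.  Rules are then evaluated over the whole incoming-lot
        series under both limit sets.
    crossover_method
        ``df_weighted_rms`` or ``arithmetic_mean`` CV pooling.
    target_mean
        Center used with the cross-over SD: ``new_lot_provisional``,
        ``historical`` (outgoing lot mean), or an explicit number.
    crossover_inflation
        Extra multiplier lambda on the cross-over applied SD; models how
        badly a pooled transitional SD can overstate the incoming lot's
        true imprecision (1.0 = no inflation).
    """

    establishment_runs: int = 20
    crossover_method: str = "df_weighted_rms"
    target_mean: object = "new_lot_provisional"
    crossover_inflation: float = 1.0
    rule_config: RuleConfig = field(default_factory=RuleConfig)

    def __post_init__(self) -> None:
        if self.establishment_runs < 2:
            raise ValidationError("establishment_runs must be >= 2")
        if self.crossover_inflation <= 0:
            raise ValidationError("crossover_inflation must be > 0")


@dataclass(frozen=True)
class ComparisonRow:
    group_no: int
    chart_id: str
    before: FailureCounts
    after: FailureCounts
    differs: bool
    paper_label: Optional[bool] = None


@dataclass(frozen=True)
class ComparisonTable:
    rows: tuple
    totals_before: FailureCounts
    totals_after: FailureCounts

    @classmethod
    def from_rows(cls, rows: Sequence[ComparisonRow]) -> "ComparisonTable":
        tb, ta = aggregate_totals(rows)
        return cls(rows=tuple(rows), totals_before=tb, totals_after=ta)

    def to_frame(self) -> pd.DataFrame:
        recs = [
            {
                "group_no": r.group_no,
                "chart_id": r.chart_id,
                "before_total": r.before.total,
                "before_warning": r.before.warning,
                "before_rejection": r.before.rejection,
                "after_total": r.after.total,
                "after_warning": r.after.warning,
                "after_rejection": r.after.rejection,
                "differs": r.differs,
                "paper_label": (
                    "" if r.paper_label is None else ("Yes" if r.paper_label else "No")
                ),
            }
            for r in self.rows
        ]
        return pd.DataFrame(recs)


@dataclass(frozen=True)
class AssociationResult:
    """One significance test at alpha = 0.05."""

    test_name: str  # "chi_square" | "fisher_exact" | "paired_t"
    statistic: float
    p_value: float
    significant: bool
    odds_ratio: Optional[float] = None
    degenerate: bool = False


def compare_counts(before: FailureCounts, after: FailureCounts) -> bool:
    """True iff any of (total, warning, rejection) differ between conditions."""
    return (
        before.total != after.total
        or before.warning != after.warning
        or before.rejection != after.rejection
    )


def aggregate_totals(rows: Sequence[ComparisonRow]) -> tuple:
    """Componentwise column totals (before, after) over comparison rows."""
    if not rows:
        raise ValidationError("cannot aggregate an empty set of rows")
    tb = FailureCounts.zero()
    ta = FailureCounts.zero()
    for r in rows:
        tb = tb + r.before
        ta = ta + r.after
    return tb, ta


def _resolve_lots(series: ChartSeries, lot_assignment: Optional[Mapping]) -> tuple:
    """(historical lot, monitored/incoming lot) for one chart."""
    if lot_assignment is not None and series.chart_id in lot_assignment:
        hist, new = lot_assignment[series.chart_id]
    else:
        lots = series.lot_ids()
        if len(lots) != 2:
            raise ConfigurationError(
                f"chart {series.chart_id!r}: expected exactly two lots, found {lots}"
            )
        hist, new = lots
    present = set(series.lot_ids())
    for lot in (hist, new):
        if lot not in present:
            raise ConfigurationError(f"chart {series.chart_id!r}: lot {lot!r} has no data")
    return hist, new


def _head(series: ChartSeries, n: int) -> ChartSeries:
    return ChartSeries(series.chart_id, series.observations[: max(n, 2)])


def run_comparison(
    charts: Sequence[ChartSeries],
    lot_assignment: Optional[Mapping] = None,
    config: Optional[ComparisonConfig] = None,
) -> ComparisonTable:
    """Evaluate every chart under both limit schemes and assemble the table.

    ``lot_assignment`` maps chart_id -> (historical_lot_id, new_lot_id);
    when omitted, the two lots are taken in order of first appearance on
    the chart (outgoing first).  Each chart must carry both lots.
    """
    if config is None:
        config = ComparisonConfig()
    rows = []
    for group_no, series in enumerate(charts, start=1):
        hist_lot, new_lot = _resolve_lots(series, lot_assignment)
        hist = series.restrict_to_lot(hist_lot)
        new = series.restrict_to_lot(new_lot)

        hist_summary = compute_lot_summary(hist)
        est_summary = compute_lot_summary(_head(new, config.establishment_runs))

        est = crossover_cv(hist_summary, est_summary, method=config.crossover_method)
        if config.target_mean == "new_lot_provisional":
            target = est_summary.mean
        elif config.target_mean == "historical":
            target = hist_summary.mean
        else:
            target = float(config.target_mean)  # type: ignore[arg-type]
        before_limits = derive_limits_crossover(est, target)
        if config.crossover_inflation != 1.0:
            before_limits = replace(
                before_limits, sd_applied=before_limits.sd_applied * config.crossover_inflation
            )
        after_limits = derive_limits_actual(est_summary)

        before = count_failures(
            evaluate_rules(zscore_series(new, before_limits), config.rule_config)
        )
        after = count_failures(
            evaluate_rules(zscore_series(new, after_limits), config.rule_config)
        )
        rows.append(
            ComparisonRow(
                group_no=group_no,
                chart_id=series.chart_id,
                before=before,
                after=after,
                differs=compare_counts(before, after),
            )
        )
    return ComparisonTable.from_rows(rows)


def table_from_fixture(rows: Sequence[Table1Row]) -> ComparisonTable:
    """Pass-through mode: build the comparison table from already-counted
    failures (the packaged reference table), skipping rule evaluation."""
    out = [
        ComparisonRow(
            group_no=r.group_no,
            chart_id=f"group{r.group_no:02d}",
            before=r.before,
            after=r.after,
            differs=compare_counts(r.before, r.after),
            paper_label=r.paper_difference_label,
        )
        for r in rows
    ]
    return ComparisonTable.from_rows(out)


def _severity_table(table: ComparisonTable) -> np.ndarray:
    return np.array(
        [
            [table.totals_before.warning, table.totals_before.rejection],
            [table.totals_after.warning, table.totals_after.rejection],
        ],
        dtype=float,
    )


def association_tests(table: ComparisonTable) -> list:
    """The study's significance tests on the assembled comparison table.

    (a) 2x2 test on the warning/rejection composition of the column totals
    — chi-square with Yates continuity correction when all expected counts
    are >= 5, otherwise a two-sided Fisher exact test; the sample odds
    ratio is reported alongside.  (b) Two-sided paired t-test on per-chart
    total failures (the same charts are measured under both conditions).
    Degenerate inputs (a zero margin, or no variation in the paired
    differences) return p = 1 with the degeneracy flag set.
    """
    results = []
    obs = _severity_table(table)
    a, b = obs[0]
    c, d = obs[1]
    oratio = float("inf") if b * c == 0 else float((a * d) / (b * c))
    if obs.sum(axis=0).min() == 0 or obs.sum(axis=1).min() == 0:
        results.append(
            AssociationResult("fisher_exact", float("nan"), 1.0, False, oratio, degenerate=True)
        )
    else:
        expected = stats.contingency.expected_freq(obs)
        if (expected >= 5).all():
            chi2, p, _, _ = stats.chi2_contingency(obs, correction=True)
            results.append(
                AssociationResult("chi_square", float(chi2), float(p), bool(p < 0.05), oratio)
            )
        else:
            stat, p = stats.fisher_exact(obs, alternative="two-sided")
            results.append(
                AssociationResult("fisher_exact", float(stat), float(p), bool(p < 0.05), oratio)
            )

    before_totals = np.array([r.before.total for r in table.rows], dtype=float)
    after_totals = np.array([r.after.total for r in table.rows], dtype=float)
    diffs = after_totals - before_totals
    if np.allclose(diffs, diffs[0]) and (diffs[0] == 0 or len(diffs) < 2):
        results.append(AssociationResult("paired_t", float("nan"), 1.0, False, degenerate=True))
    else:
        t, p = stats.ttest_rel(after_totals, before_totals)
        if np.isnan(p):  # constant nonzero differences: zero variance
            results.append(AssociationResult("paired_t", float("nan"), 1.0, False, degenerate=True))
        else:
            results.append(AssociationResult("paired_t", float(t), float(p), bool(p < 0.05)))
    return results
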