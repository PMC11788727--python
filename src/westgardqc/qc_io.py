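"""Domain data model and I/O for control measurement series.

A control measurement is one value of one QC material lot on one chart
(analyte x control level).  Charts are interchanged as plain CSV with the
five columns ``analyte_id, control_level, lot_id, run_index, value``
(comma-separated, UTF-8, header required, decimal point ``.``).

``run_index`` is an abstract run ordering, not a timestamp: laboratories
run controls at varying daily frequency, so calendar semantics (the
"20-day" establishment convention) are expressed in runs.

The module also ships the reference failure-count table used by the
comparison pipeline: 18 chart groups with (total, warning, rejection)
failure triples under the cross-over-CV scheme and under actual per-lot
mean/SD, plus the published Yes/No difference label.  The underlying raw
measurements were never published, so this table is shipped as data and
validated for integrity at load time rather than re-derived.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import FixtureIntegrityError, FormatError, ValidationError
from .rules import FailureCounts

__all__ = [
    "CSV_COLUMNS",
    "ControlObservation",
    "ChartSeries",
    "Table1Row",
    "read_control_csv",
    "write_control_csv",
    "load_table1_fixture",
]

CSV_COLUMNS = ("analyte_id", "control_level", "lot_id", "run_index", "value")


@dataclass(frozen=True)
class ControlObservation:
    """One control measurement: a value for (analyte, level, lot) at a run index."""

    analyte_id: str
    control_level: str
    lot_id: str
    run_index: int
    value: float

    def __post_init__(self) -> None:
        if self.run_index < 0 or int(self.run_index) != self.run_index:
            raise ValidationError(f"run_index must be a non-negative integer, got {self.run_index!r}")
        if not math.isfinite(self.value):
            raise ValidationError(f"value must be finite, got {self.value!r}")
        object.__setattr__(self, "run_index", int(self.run_index))
        object.__setattr__(self, "value", float(self.value))


@dataclass(frozen=True)
class ChartSeries:
    """All observations of one chart (one analyte at one control level),
    ordered by run_index with no duplicate indices."""

    chart_id: str
    observations: tuple

    def __post_init__(self) -> None:
        obs = tuple(self.observations)
        object.__setattr__(self, "observations", obs)
        idx = [o.run_index for o in obs]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValidationError(
                f"chart {self.chart_id!r}: observations must be strictly increasing in run_index"
            )

    @classmethod
    def from_observations(cls, chart_id: str, observations: Sequence[ControlObservation]) -> "ChartSeries":
        """Build a chart, sorting by run_index and rejecting duplicates."""
        obs = sorted(observations, key=lambda o: o.run_index)
        seen: set = set()
        for o in obs:
            if o.run_index in seen:
                raise ValidationError(f"chart {chart_id!r}: duplicate run_index {o.run_index}")
            seen.add(o.run_index)
        return cls(chart_id=chart_id, observations=tuple(obs))

    def __len__(self) -> int:
        return len(self.observations)

    def values(self) -> np.ndarray:
        return np.array([o.value for o in self.observations], dtype=float)

    def run_indices(self) -> np.ndarray:
        return np.array([o.run_index for o in self.observations], dtype=int)

    def lot_ids(self) -> list:
        """Distinct lot ids in order of first appearance (run order)."""
        out: list = []
        for o in self.observations:
            if o.lot_id not in out:
                out.append(o.lot_id)
        return out

    def restrict_to_lot(self, lot_id: str) -> "ChartSeries":
        obs = tuple(o for o in self.observations if o.lot_id == lot_id)
        return ChartSeries(chart_id=self.chart_id, observations=obs)


@dataclass(frozen=True)
class Table1Row:
    """One chart group of the reference comparison table.

    ``before`` is the tally under cross-over-CV-derived limits, ``after``
    under actual per-lot mean/SD limits; ``paper_difference_label`` is the
    published Yes/No flag, retained verbatim (it is not recomputed here).
    """

    group_no: int
    before: FailureCounts
    after: FailureCounts
    paper_difference_label: bool


def _chart_id(analyte_id: str, control_level: str) -> str:
    return f"{analyte_id}:{control_level}"


def read_control_csv(path) -> list:
    """Read a control-measurement CSV into one ChartSeries per
    (analyte_id, control_level) pair, each sorted by run_index.

    Raises
    ------
    FormatError
        If a required column is absent.
    ValidationError
        On a non-numeric value or a duplicate run_index, naming the
        offending data row.
    """
    # round_trip parsing: written values must re-read bit-identically
    df = pd.read_csv(
        path,
        dtype={"analyte_id": str, "control_level": str, "lot_id": str},
        float_precision="round_trip",
    )
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")

    charts: list = []
    for (analyte, level), grp in df.groupby(["analyte_id", "control_level"], sort=True):
        obs = []
        for row in grp.itertuples():
            # row.Index is the 0-based data-row position in the file
            try:
                value = float(row.value)
                run_index = int(row.run_index)
            except (TypeError, ValueError) as exc:
                raise ValidationError(f"{path}: row {row.Index + 2}: {exc}") from exc
            try:
                obs.append(
                    ControlObservation(
                        analyte_id=str(analyte),
                        control_level=str(level),
                        lot_id=str(row.lot_id),
                        run_index=run_index,
                        value=value,
                    )
                )
            except ValidationError as exc:
                raise ValidationError(f"{path}: row {row.Index + 2}: {exc}") from exc
        try:
            charts.append(ChartSeries.from_observations(_chart_id(analyte, level), obs))
        except ValidationError as exc:
            raise ValidationError(f"{path}: {exc}") from exc
    return charts


def write_control_csv(series: Sequence[ChartSeries], path) -> None:
    """Write charts back to the five-column CSV; round-trips through
    :func:`read_control_csv` with identical observations."""
    rows = [
        {
            "analyte_id": o.analyte_id,
            "control_level": o.control_level,
            "lot_id": o.lot_id,
            "run_index": o.run_index,
            "value": o.value,
        }
        for s in series
        for o in s.observations
    ]
    pd.DataFrame(rows, columns=list(CSV_COLUMNS)).to_csv(path, index=False)


_FIXTURE_COLUMNS = (
    "group_no",
    "before_total",
    "before_warning",
    "before_rejection",
    "after_total",
    "after_warning",
    "after_rejection",
    "paper_label",
)


def load_table1_fixture() -> list:
    """Load the packaged 18-group reference failure-count table.

    The table is checked for shape and internal consistency (18 rows,
    group numbers 1..18, per-row additivity of both tallies); any mismatch
    raises :class:`FixtureIntegrityError`.
    """
    with resources.files("westgardqc.data").joinpath("table1.csv").open("r", encoding="utf-8") as fh:
        df = pd.read_csv(fh)
    if tuple(df.columns) != _FIXTURE_COLUMNS:
        raise FixtureIntegrityError(f"unexpected fixture columns: {list(df.columns)}")
    if len(df) != 18 or list(df["group_no"]) != list(range(1, 19)):
        raise FixtureIntegrityError("fixture must contain groups 1..18 exactly once, in order")
    if not set(df["paper_label"]) <= {"Yes", "No"}:
        raise FixtureIntegrityError("paper_label must be Yes or No")
    rows: list = []
    for r in df.itertuples():
        try:
            before = FailureCounts(int(r.before_total), int(r.before_warning), int(r.before_rejection))
            after = FailureCounts(int(r.after_total), int(r.after_warning), int(r.after_rejection))
        except ValidationError as exc:
            raise FixtureIntegrityError(f"group {r.group_no}: {exc}") from exc
        rows.append(
            Table1Row(
                group_no=int(r.group_no),
                before=before,
                after=after,
                paper_difference_label=(r.paper_label == "Yes"),
            )
        )
    return rows
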