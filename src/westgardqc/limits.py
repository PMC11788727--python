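"""Per-lot summary statistics and control-limit derivation.

Two limit schemes are supported, matching the two phases of a control-lot
changeover:

* **cross-over CV** — during the overlap period, the CVs of the outgoing
  and incoming lots are pooled into a single transitional CV, which is
  converted to an applied SD against a target mean (by default the new
  lot's provisional mean).  The pooled CV is, by default, the
  degrees-of-freedom-weighted root-mean-square

      CV_pooled = sqrt(((n_a-1) CV_a^2 + (n_b-1) CV_b^2) / (n_a + n_b - 2))

  which reduces to the CV of the pooled within-lot variance when the two
  lot means are equal; a plain arithmetic mean of the two CVs is available
  for sensitivity analysis.

* **actual** — once enough data for the new lot has accumulated (the
  conventional target is 20 runs), its own mean and sample SD define the
  limits directly.

All SDs are sample SDs (n-1 denominator); CV = 100 * s / x̄ in percent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import (
    DegenerateLimitsError,
    InsufficientDataError,
    QCWarning,
    UndefinedCVError,
    ValidationError,
)

__all__ = [
    "ESTABLISHMENT_RUNS",
    "LotSummary",
    "CrossoverEstimate",
    "ControlLimits",
    "compute_lot_summary",
    "crossover_cv",
    "derive_limits_crossover",
    "derive_limits_actual",
]

#: conventional number of runs over which lot-specific limits are established
ESTABLISHMENT_RUNS = 20


@dataclass(frozen=True)
class LotSummary:
    """n, mean, sample SD and CV (%) of one lot's observations on one chart."""

    lot_id: str
    n: int
    mean: float
    sd: float
    cv: float  # percent


@dataclass(frozen=True)
class CrossoverEstimate:
    """Pooled transitional CV (%) from two lot summaries."""

    cv_pooled: float
    source_lots: tuple
    method_tag: str


@dataclass(frozen=True)
class ControlLimits:
    """Center line m and applied SD defining the ±1/±2/±3 SD limit lines."""

    center: float
    sd_applied: float
    scheme: str  # "crossover_cv" | "actual"

    def __post_init__(self) -> None:
        if self.sd_applied <= 0:
            raise DegenerateLimitsError("sd_applied must be > 0")
        if self.scheme not in ("crossover_cv", "actual"):
            raise ValidationError(f"unknown scheme {self.scheme!r}")

    def lines(self, k: float) -> tuple:
        """The (lower, upper) limit lines at ±k SD."""
        return (self.center - k * self.sd_applied, self.center + k * self.sd_applied)


def compute_lot_summary(series, lot_id: Optional[str] = None) -> LotSummary:
    """Summarise one lot's observations on a chart.

    Parameters
    ----------
    series : ChartSeries
        Either already restricted to a single lot, or a mixed-lot chart
        together with an explicit ``lot_id`` to select.
    lot_id : str, optional
        Lot to summarise; required when the chart holds more than one lot.

    Emits a :class:`QCWarning` when fewer than 20 runs are available — the
    conventional minimum for establishing lot-specific limits — and raises
    :class:`InsufficientDataError` below n = 2.
    """
    if lot_id is not None:
        series = series.restrict_to_lot(lot_id)
    lots = series.lot_ids()
    if len(lots) > 1:
        raise ValidationError(
            f"chart {series.chart_id!r} mixes lots {lots}; pass lot_id to select one"
        )
    if len(series) < 2:
        raise InsufficientDataError(
            f"chart {series.chart_id!r}: need >= 2 observations for an SD, got {len(series)}"
        )
    if len(series) < ESTABLISHMENT_RUNS:
        warnings.warn(
            f"chart {series.chart_id!r}, lot {lots[0]!r}: only {len(series)} runs; "
            f"{ESTABLISHMENT_RUNS} are conventionally required to establish limits",
            QCWarning,
            stacklevel=2,
        )
    x = series.values()
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    if mean == 0.0:
        raise UndefinedCVError(f"chart {series.chart_id!r}: mean is 0, CV undefined")
    return LotSummary(lot_id=lots[0], n=len(series), mean=mean, sd=sd, cv=100.0 * sd / abs(mean))


def crossover_cv(
    lot_a: LotSummary, lot_b: LotSummary, method: str = "df_weighted_rms"
) -> CrossoverEstimate:
    """Pool the CVs of two control lots into a transitional cross-over CV.

    ``df_weighted_rms`` (default) weights each squared CV by its degrees of
    freedom n-1; ``arithmetic_mean`` averages the two CVs directly.  Either
    way the result lies between the two input CVs and the operation is
    symmetric in its arguments.
    """
    for lot in (lot_a, lot_b):
        if lot.n < 2:
            raise InsufficientDataError(f"lot {lot.lot_id!r}: n >= 2 required, got {lot.n}")
    if method == "df_weighted_rms":
        df_a, df_b = lot_a.n - 1, lot_b.n - 1
        pooled = float(np.sqrt((df_a * lot_a.cv**2 + df_b * lot_b.cv**2) / (df_a + df_b)))
    elif method == "arithmetic_mean":
        pooled = (lot_a.cv + lot_b.cv) / 2.0
    else:
        raise ValidationError(f"unknown crossover method {method!r}")
    return CrossoverEstimate(cv_pooled=pooled, source_lots=(lot_a, lot_b), method_tag=method)


def derive_limits_crossover(est: CrossoverEstimate, target_mean: float) -> ControlLimits:
    """Convert a pooled CV into control limits around a target mean:
    s_applied = CV_pooled * |target_mean| / 100."""
    if target_mean == 0:
        raise ValidationError("target_mean must be nonzero")
    if est.cv_pooled <= 0:
        raise DegenerateLimitsError("pooled CV is 0: limits would have zero width")
    return ControlLimits(
        center=float(target_mean),
        sd_applied=est.cv_pooled * abs(target_mean) / 100.0,
        scheme="crossover_cv",
    )


def derive_limits_actual(summary: LotSummary) -> ControlLimits:
    """Use the lot's own established mean and SD as the control limits."""
    if summary.sd <= 0:
        raise DegenerateLimitsError(
            f"lot {summary.lot_id!r}: sd = {summary.sd} gives zero-width limits"
        )
    return ControlLimits(center=summary.mean, sd_applied=summary.sd, scheme="actual")
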