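"""Westgard multirule engine.

Control observations are first standardised against a set of control limits
(z_i = (x_i - m) / s_applied) and the classic six-rule Westgard scheme is
evaluated on the resulting z-series:

====== ======================================================== ==========
rule   definition (strict inequalities)                         severity
====== ======================================================== ==========
1_2s   a single point with |z| > 2                              warning
1_3s   a single point with |z| > 3                              rejection
2_2s   two consecutive points on the same side with |z| > 2     rejection
R_4s   two consecutive points, one > +2 and one < -2            rejection
4_1s   four consecutive points on the same side with |z| > 1    rejection
10_x   ten consecutive points strictly on one side of the mean  rejection
====== ======================================================== ==========

Rules are applied to a single ordered series (one control level on one
chart); across-material variants are out of scope.  A hit is reported at
every index where a rule's window completes — windows are not reset after a
rejection — and the counting policy collapses multiple hits at one index
into a single failure so that total = warning + rejection always holds.

A point with z exactly equal to a threshold (e.g. z == 2.0) does not fire:
all comparisons are strict, which makes the engine deterministic on data
that lands exactly on a limit line.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .errors import DegenerateLimitsError, ValidationError

__all__ = [
    "RULE_ARITY",
    "DEFAULT_SEVERITY",
    "FailureCounts",
    "RuleConfig",
    "RuleHit",
    "ZSeries",
    "zscore_series",
    "evaluate_rules",
    "count_failures",
]

#: window length of each rule
RULE_ARITY: Mapping[str, int] = {
    "1_2s": 1,
    "1_3s": 1,
    "2_2s": 2,
    "R_4s": 2,
    "4_1s": 4,
    "10_x": 10,
}

#: the warning/rejection dichotomy: 1_2s warns, every other rule rejects the run
DEFAULT_SEVERITY: Mapping[str, str] = {
    "1_2s": "warning",
    "1_3s": "rejection",
    "2_2s": "rejection",
    "R_4s": "rejection",
    "4_1s": "rejection",
    "10_x": "rejection",
}


@dataclass(frozen=True)
class FailureCounts:
    """Per-chart failure tally; the additivity total = warning + rejection is enforced."""

    total: int
    warning: int
    rejection: int

    def __post_init__(self) -> None:
        for name in ("total", "warning", "rejection"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValidationError(f"{name} must be a non-negative integer, got {v!r}")
        if self.total != self.warning + self.rejection:
            raise ValidationError(
                f"total ({self.total}) != warning ({self.warning}) + rejection ({self.rejection})"
            )

    def __add__(self, other: "FailureCounts") -> "FailureCounts":
        return FailureCounts(
            self.total + other.total,
            self.warning + other.warning,
            self.rejection + other.rejection,
        )

    @classmethod
    def zero(cls) -> "FailureCounts":
        return cls(0, 0, 0)


@dataclass(frozen=True)
class RuleConfig:
    """Which rules are enabled and how each one is classified.

    The default enables the full six-rule set with 1_2s as the warning rule.
    """

    enabled_rules: frozenset = frozenset(RULE_ARITY)
    severity: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_SEVERITY))

    def __post_init__(self) -> None:
        object.__setattr__(self, "enabled_rules", frozenset(self.enabled_rules))
        unknown = self.enabled_rules - set(RULE_ARITY)
        if unknown:
            raise ValidationError(f"unknown rules: {sorted(unknown)}")
        missing = self.enabled_rules - set(self.severity)
        if missing:
            raise ValidationError(f"no severity assigned for rules: {sorted(missing)}")
        bad = {r: s for r, s in self.severity.items() if s not in ("warning", "rejection")}
        if bad:
            raise ValidationError(f"severity must be 'warning' or 'rejection': {bad}")


@dataclass(frozen=True)
class RuleHit:
    """One completed rule window.

    ``trigger_index`` is the index at which the window completes;
    ``window`` is the inclusive (start, end) index range, with
    end == trigger_index and length equal to the rule's arity.
    """

    rule: str
    trigger_index: int
    window: tuple
    severity: str

    def __post_init__(self) -> None:
        if self.window[1] != self.trigger_index:
            raise ValidationError("window must end at trigger_index")
        if self.window[1] - self.window[0] + 1 != RULE_ARITY[self.rule]:
            raise ValidationError(f"window length does not match arity of {self.rule}")


@dataclass(frozen=True)
class ZSeries:
    """Standardised chart: z_i = (x_i - center) / s_applied, order preserved."""

    chart_id: str
    z: tuple
    limits: "ControlLimits"  # noqa: F821 - forward ref to limits.ControlLimits

    def __post_init__(self) -> None:
        object.__setattr__(self, "z", tuple(float(v) for v in self.z))


def zscore_series(series, limits) -> ZSeries:
    """Standardise a chart's observed values against control limits.

    Parameters
    ----------
    series : ChartSeries
        Ordered control observations for one chart.
    limits : ControlLimits
        Center m and applied SD; must be non-degenerate (sd_applied > 0).
    """
    if limits.sd_applied <= 0:
        raise DegenerateLimitsError("sd_applied must be > 0 to standardise")
    z = (np.asarray(series.values(), dtype=float) - limits.center) / limits.sd_applied
    return ZSeries(chart_id=series.chart_id, z=tuple(z), limits=limits)


def _hit(rule: str, i: int, severity: Mapping[str, str]) -> RuleHit:
    k = RULE_ARITY[rule]
    return RuleHit(rule=rule, trigger_index=i, window=(i - k + 1, i), severity=severity[rule])


def evaluate_rules(zs: ZSeries, config: RuleConfig | None = None) -> list:
    """Evaluate the enabled Westgard rules over a z-series.

    Returns every rule hit, ordered by trigger index (ties broken by rule
    name order in :data:`RULE_ARITY`).  Consecutive-point rules use running
    counters, so the scan is a single O(n) pass.
    """
    if config is None:
        config = RuleConfig()
    z = np.asarray(zs.z, dtype=float)
    if z.size == 0:
        raise ValidationError("cannot evaluate rules on an empty series")
    en = config.enabled_rules
    sev = config.severity
    hits: list = []

    # running counts of consecutive points satisfying each one-sided predicate
    run_gt1 = run_lt1 = 0       # |z| > 1, same side
    run_gt2 = run_lt2 = 0       # |z| > 2, same side
    run_pos = run_neg = 0       # strictly above / below the mean
    prev = None
    for i, zi in enumerate(z):
        run_gt1 = run_gt1 + 1 if zi > 1 else 0
        run_lt1 = run_lt1 + 1 if zi < -1 else 0
        run_gt2 = run_gt2 + 1 if zi > 2 else 0
        run_lt2 = run_lt2 + 1 if zi < -2 else 0
        run_pos = run_pos + 1 if zi > 0 else 0
        run_neg = run_neg + 1 if zi < 0 else 0

        if "1_2s" in en and abs(zi) > 2:
            hits.append(_hit("1_2s", i, sev))
        if "1_3s" in en and abs(zi) > 3:
            hits.append(_hit("1_3s", i, sev))
        if "2_2s" in en and (run_gt2 >= 2 or run_lt2 >= 2):
            hits.append(_hit("2_2s", i, sev))
        if (
            "R_4s" in en
            and prev is not None
            and ((prev > 2 and zi < -2) or (prev < -2 and zi > 2))
        ):
            hits.append(_hit("R_4s", i, sev))
        if "4_1s" in en and (run_gt1 >= 4 or run_lt1 >= 4):
            hits.append(_hit("4_1s", i, sev))
        if "10_x" in en and (run_pos >= 10 or run_neg >= 10):
            hits.append(_hit("10_x", i, sev))
        prev = zi

    order = list(RULE_ARITY)
    hits.sort(key=lambda h: (h.trigger_index, order.index(h.rule)))
    return hits


def count_failures(hits: Iterable[RuleHit], policy: str = "exclusive_by_point") -> FailureCounts:
    """Tally rule hits into (total, warning, rejection) failure counts.

    The default ``exclusive_by_point`` policy lets each trigger index
    contribute at most one failure: a rejection if any rejection rule
    completes there, otherwise a warning.  This keeps the tally additive
    (total = warning + rejection) even when several rules fire at once,
    e.g. 1_2s and 2_2s completing at the same point.
    """
    if policy != "exclusive_by_point":
        raise ValidationError(f"unknown counting policy: {policy!r}")
    by_index: dict = {}
    for h in hits:
        cur = by_index.get(h.trigger_index)
        if cur != "rejection":
            by_index[h.trigger_index] = h.severity if cur is None or h.severity == "rejection" else cur
    warning = sum(1 for s in by_index.values() if s == "warning")
    rejection = sum(1 for s in by_index.values() if s == "rejection")
    return FailureCounts(total=warning + rejection, warning=warning, rejection=rejection)
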