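"""Seeded simulator for two-lot control measurement series.

Control materials are modelled with the standard Gaussian QC assumption:
lot observations are i.i.d. normal around a lot mean with a lot CV, with
optional contamination —

* a systematic **shift** of ``shift_sd`` true SDs from a given within-lot
  run onward (an abrupt bias, e.g. a calibration change),
* a linear **drift** of ``drift_per_run`` true SDs per run,
* scale-contaminated **outliers**: each point is, with probability
  ``outlier_prob``, drawn with its noise SD inflated by ``outlier_scale``.

Generated value:

    x_i = mu + s_true * (eps_i + shift*1[i >= shift_start] + drift*i),
    s_true = cv * mu / 100

Each chart carries two lots (the outgoing lot A, then the incoming lot B)
on one continuous run axis, with the changeover at the end of lot A.  An
optional ``decimals`` parameter rounds reported values to emulate
instruments with coarse result reporting; it is off by default.

Reproducibility: one master seed; each (chart, lot) gets an independent
child stream via ``np.random.default_rng([seed, chart_key, lot_ordinal])``,
so charts are pairwise distinct but bitwise reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

from .errors import ValidationError
from .qc_io import ChartSeries, ControlObservation

__all__ = [
    "LotSpec",
    "SimulationConfig",
    "SimulatedStudy",
    "simulate_lot",
    "simulate_study",
    "paperlike_configs",
]


@dataclass(frozen=True)
class LotSpec:
    """Target mean (analyte units), CV (%) and number of runs for one lot."""

    mean: float
    cv: float
    n: int

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValidationError(f"cv must be >= 0, got {self.cv}")
        if self.n < 1:
            raise ValidationError(f"n must be >= 1, got {self.n}")

    @property
    def sd_true(self) -> float:
        return self.cv * abs(self.mean) / 100.0


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters for one simulated two-lot chart.

    Contamination (shift/drift/outliers) is applied at within-lot run
    indices, identically parameterised for whichever lot is simulated;
    ``shift_start_index`` past a lot's length leaves that lot untouched.
    """

    analyte_id: str = "analyte"
    control_level: str = "L1"
    lot_a: LotSpec = field(default_factory=lambda: LotSpec(100.0, 3.0, 20))
    lot_b: LotSpec = field(default_factory=lambda: LotSpec(100.0, 3.0, 30))
    shift_sd: float = 0.0
    shift_start_index: int = 0
    drift_per_run: float = 0.0
    outlier_prob: float = 0.0
    outlier_scale: float = 5.0
    decimals: Optional[int] = None
    seed: int = 0
    chart_index: int = 0  # key for the per-chart child RNG stream

    def __post_init__(self) -> None:
        if not 0.0 <= self.outlier_prob < 1.0:
            raise ValidationError(f"outlier_prob must be in [0, 1), got {self.outlier_prob}")
        if self.outlier_prob > 0 and self.outlier_scale <= 1.0:
            raise ValidationError(f"outlier_scale must be > 1, got {self.outlier_scale}")
        if self.shift_start_index < 0:
            raise ValidationError("shift_start_index must be >= 0")

    @property
    def chart_id(self) -> str:
        return f"{self.analyte_id}:{self.control_level}"


@dataclass(frozen=True)
class SimulatedStudy:
    """Simulated charts plus per-chart ground truth of parameters and
    injected events (shift location/magnitude, outlier run indices)."""

    charts: tuple
    truth: dict


_LOT_ORDINAL = {"a": 0, "b": 1}


def _simulate_values(config: SimulationConfig, lot: str):
    spec: LotSpec = getattr(config, f"lot_{lot}")
    rng = np.random.default_rng([config.seed, config.chart_index, _LOT_ORDINAL[lot]])
    n = spec.n
    eps = rng.standard_normal(n)
    outlier_idx = np.array([], dtype=int)
    if config.outlier_prob > 0:
        mask = rng.random(n) < config.outlier_prob
        eps[mask] *= config.outlier_scale
        outlier_idx = np.flatnonzero(mask)
    i = np.arange(n)
    systematic = config.shift_sd * (i >= config.shift_start_index) + config.drift_per_run * i
    x = spec.mean + spec.sd_true * (eps + systematic)
    if config.decimals is not None:
        x = np.round(x, config.decimals)
    return x, outlier_idx


def simulate_lot(config: SimulationConfig, lot: str) -> ChartSeries:
    """Simulate one lot of a chart.

    ``lot`` selects ``"a"`` (outgoing; run indices start at 0) or ``"b"``
    (incoming; run indices continue after lot A, marking the changeover).
    The same config and lot always reproduce the identical series.
    """
    if lot not in _LOT_ORDINAL:
        raise ValidationError(f"lot must be 'a' or 'b', got {lot!r}")
    x, _ = _simulate_values(config, lot)
    offset = 0 if lot == "a" else config.lot_a.n
    lot_id = f"lot_{lot.upper()}"
    obs = [
        ControlObservation(
            analyte_id=config.analyte_id,
            control_level=config.control_level,
            lot_id=lot_id,
            run_index=offset + i,
            value=float(v),
        )
        for i, v in enumerate(x)
    ]
    return ChartSeries.from_observations(config.chart_id, obs)


def _merge(chart_id: str, a: ChartSeries, b: ChartSeries) -> ChartSeries:
    return ChartSeries.from_observations(chart_id, a.observations + b.observations)


def simulate_study(configs: Sequence[SimulationConfig]) -> SimulatedStudy:
    """Simulate one two-lot chart per config and record ground truth."""
    if not configs:
        raise ValidationError("at least one SimulationConfig is required")
    charts = []
    truth: dict = {}
    for cfg in configs:
        series = _merge(cfg.chart_id, simulate_lot(cfg, "a"), simulate_lot(cfg, "b"))
        charts.append(series)
        events = []
        for lot in ("a", "b"):
            spec: LotSpec = getattr(cfg, f"lot_{lot}")
            offset = 0 if lot == "a" else cfg.lot_a.n
            if cfg.shift_sd != 0.0 and cfg.shift_start_index < spec.n:
                events.append(
                    {
                        "kind": "shift",
                        "lot": f"lot_{lot.upper()}",
                        "run_index": offset + cfg.shift_start_index,
                        "magnitude_sd": cfg.shift_sd,
                    }
                )
            if cfg.drift_per_run != 0.0:
                events.append(
                    {
                        "kind": "drift",
                        "lot": f"lot_{lot.upper()}",
                        "run_index": offset,
                        "per_run_sd": cfg.drift_per_run,
                    }
                )
            _, out_idx = _simulate_values(cfg, lot)
            events.extend(
                {"kind": "outlier", "lot": f"lot_{lot.upper()}", "run_index": int(offset + j)}
                for j in out_idx
            )
        truth[cfg.chart_id] = {"config": asdict(cfg), "events": events}
    return SimulatedStudy(charts=tuple(charts), truth=truth)


#: chart groups (1-based) that receive a shift in the "paperlike" preset —
#: 11 of 18 charts change, 7 stay comparable, mirroring the study design
_PAPERLIKE_SHIFTED = frozenset({2, 3, 6, 7, 8, 9, 11, 14, 16, 17, 18})


def paperlike_configs(seed: int) -> list:
    """The 18-chart study preset.

    Each chart: 20 clean runs of the outgoing lot, then 30 runs of the
    incoming lot whose last 10 runs carry a 2.5-SD systematic shift on 11
    of the 18 charts.  Lot means and CVs vary across charts (analyte means
    spread over ~10-500 units, CVs 2-5 %; lot A is slightly offset from
    lot B and somewhat noisier, as an aged outgoing lot typically is).
    Deterministic in ``seed``.
    """
    rng = np.random.default_rng([seed, 0xC0FFEE])
    configs = []
    for g in range(1, 19):
        mean_b = float(np.exp(rng.uniform(np.log(10.0), np.log(500.0))))
        cv_b = float(rng.uniform(2.0, 5.0))
        mean_a = mean_b * float(1.0 + rng.uniform(-0.02, 0.02))
        cv_a = cv_b * float(rng.uniform(1.0, 1.4))
        shifted = g in _PAPERLIKE_SHIFTED
        configs.append(
            SimulationConfig(
                analyte_id=f"group{g:02d}",
                control_level="L1",
                lot_a=LotSpec(mean_a, cv_a, 20),
                lot_b=LotSpec(mean_b, cv_b, 30),
                shift_sd=2.5 if shifted else 0.0,
                shift_start_index=20,
                seed=seed,
                chart_index=g,
            )
        )
    return configs
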