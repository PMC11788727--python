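"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the package's own algorithms:
``brute_force_hits`` re-checks every rule window from scratch at every
index, and ``fisher_two_sided_exact`` sums exact rational hypergeometric
probabilities via ``math.comb``.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np
import pytest

from westgardqc import ChartSeries, ControlLimits, ControlObservation, ZSeries
from westgardqc.rules import RULE_ARITY

ALL_RULES = frozenset(RULE_ARITY)


def brute_force_hits(z, enabled=ALL_RULES):
    """Naive Westgard scan: for each index, re-examine the full window of
    each rule.  Returns the set of (rule, trigger_index) pairs."""
    z = list(z)
    hits = set()
    for i, zi in enumerate(z):
        if "1_2s" in enabled and abs(zi) > 2:
            hits.add(("1_2s", i))
        if "1_3s" in enabled and abs(zi) > 3:
            hits.add(("1_3s", i))
        if i >= 1:
            w = z[i - 1 : i + 1]
            if "2_2s" in enabled and (all(v > 2 for v in w) or all(v < -2 for v in w)):
                hits.add(("2_2s", i))
            if "R_4s" in enabled and (
                (w[0] > 2 and w[1] < -2) or (w[0] < -2 and w[1] > 2)
            ):
                hits.add(("R_4s", i))
        if i >= 3:
            w = z[i - 3 : i + 1]
            if "4_1s" in enabled and (all(v > 1 for v in w) or all(v < -1 for v in w)):
                hits.add(("4_1s", i))
        if i >= 9:
            w = z[i - 9 : i + 1]
            if "10_x" in enabled and (all(v > 0 for v in w) or all(v < 0 for v in w)):
                hits.add(("10_x", i))
    return hits


def fisher_two_sided_exact(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p by exact hypergeometric enumeration.

    Sums, over all tables with the observed margins, the probabilities no
    larger than the observed table's, using exact rational arithmetic.
    """
    n1, K, M = a + b, a + c, a + b + c + d
    denom = comb(M, n1)
    pmf = {
        k: Fraction(comb(K, k) * comb(M - K, n1 - k), denom)
        for k in range(max(0, n1 - (M - K)), min(n1, K) + 1)
    }
    p_obs = pmf[a]
    return float(sum(p for p in pmf.values() if p <= p_obs))


UNIT_LIMITS = ControlLimits(center=0.0, sd_applied=1.0, scheme="actual")


def zseries(z, chart_id: str = "t") -> ZSeries:
    """A z-series against unit limits, for direct rule-engine input."""
    return ZSeries(chart_id=chart_id, z=tuple(float(v) for v in z), limits=UNIT_LIMITS)


def make_chart(values, chart_id="a:L1", lot_id="lotX", start_index=0) -> ChartSeries:
    analyte, level = chart_id.split(":")
    obs = [
        ControlObservation(analyte, level, lot_id, start_index + i, float(v))
        for i, v in enumerate(values)
    ]
    return ChartSeries.from_observations(chart_id, obs)


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)
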