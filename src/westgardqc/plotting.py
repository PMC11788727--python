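"""Levey-Jennings chart rendering (file output only, no GUI backend)."""

from __future__ import annotations

from typing import Iterable, Optional

from matplotlib.backends.backend_agg import FigureCanvasAgg
from matplotlib.backends.backend_svg import FigureCanvasSVG
from matplotlib.figure import Figure

from .errors import ValidationError
from .limits import ControlLimits
from .qc_io import ChartSeries
from .rules import RuleHit

__all__ = ["plot_levey_jennings"]

_LINE_STYLES = {1: (":", "#999999"), 2: ("--", "#e0a800"), 3: ("-", "#c0392b")}


def plot_levey_jennings(
    series: ChartSeries,
    limits: ControlLimits,
    hits: Optional[Iterable[RuleHit]] = None,
    path=None,
    fmt: str = "png",
) -> Figure:
    """Plot a chart's points against the center line and ±1/2/3 SD lines.

    Points at indices where any rule completed are highlighted (filled red
    for rejection, open orange for warning).  When ``path`` is given, the
    figure is written there in ``fmt`` ('png' or 'svg').
    """
    if fmt not in ("png", "svg"):
        raise ValidationError(f"unsupported plot format {fmt!r}")
    fig = Figure(figsize=(8, 4))
    (FigureCanvasSVG if fmt == "svg" else FigureCanvasAgg)(fig)
    ax = fig.add_subplot(111)

    x = series.run_indices()
    y = series.values()
    ax.plot(x, y, marker="o", ms=4, lw=1, color="#2c3e50", zorder=3)
    ax.axhline(limits.center, color="#2c3e50", lw=1.2)
    for k, (ls, color) in _LINE_STYLES.items():
        lo, hi = limits.lines(k)
        ax.axhline(lo, ls=ls, color=color, lw=0.9)
        ax.axhline(hi, ls=ls, color=color, lw=0.9)

    if hits:
        sev_at = {}
        for h in hits:
            if sev_at.get(h.trigger_index) != "rejection":
                sev_at[h.trigger_index] = h.severity
        pos = {int(r): i for i, r in enumerate(x)}
        for scheme, marker in (("warning", dict(mfc="none", mec="#e67e22")),
                               ("rejection", dict(mfc="#c0392b", mec="#c0392b"))):
            idx = [pos[i] for i, s in sev_at.items() if s == scheme and i in pos]
            if idx:
                ax.plot(x[idx], y[idx], "o", ms=9, lw=0, zorder=4, **marker)

    ax.set_xlabel("run index")
    ax.set_ylabel("control value")
    ax.set_title(f"{series.chart_id} — {limits.scheme} limits")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, format=fmt, dpi=120)
    return fig
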