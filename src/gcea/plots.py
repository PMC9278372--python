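"""The three figure types of the sectoral analysis.

* isoquant — log-log scatter of every intervention on the
  cost-effectiveness plane (health gain rightward, cost upward) with
  diagonal lines of constant ACER one order of magnitude apart;
* expansion — the optimized expansion path as cumulative health vs.
  cumulative cost, each segment's slope being its ICER;
* platform stack — total health gain and per-capita annual cost of the
  per-platform benefit packages.

With ``fixed_style`` set, identical inputs produce byte-identical SVG
output (hash salt pinned, no timestamp metadata).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402

from .league import BandScheme
from .models import (
    BenefitPackage,
    ExpansionPath,
    InterventionScenario,
    Platform,
    ValidationError,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PlotSpec:
    """Output options shared by the plot operations."""

    out: str = "figure.svg"
    fmt: str = "svg"
    fixed_style: bool = True
    title: Optional[str] = None


def _save(fig, spec: PlotSpec) -> Path:
    out = Path(spec.out)
    out.parent.mkdir(parents=True, exist_ok=True)
    kwargs = {}
    if spec.fixed_style and spec.fmt == "svg":
        plt.rcParams["svg.hashsalt"] = "gcea"
        kwargs["metadata"] = {"Date": None}
    fig.savefig(out, format=spec.fmt, **kwargs)
    plt.close(fig)
    return out


def plot_isoquant(
    scenarios: Sequence[InterventionScenario],
    scheme: Optional[BandScheme] = None,
    spec: Optional[PlotSpec] = None,
) -> Path:
    """Isoquant graph: each scenario at (hly, cost) on log-log axes, with
    constant-ACER diagonals at the band edges.  Scenarios with zero cost or
    zero health gain cannot be shown on log axes and are dropped with a
    warning."""
    scheme = scheme or BandScheme.with_sub_dollar()
    spec = spec or PlotSpec(out="isoquant.svg")
    plotted = [s for s in scenarios if s.cost_pv > 0 and s.hly > 0]
    dropped = len(scenarios) - len(plotted)
    if dropped:
        logger.warning(
            "isoquant: dropped %d scenario(s) with zero cost or hly", dropped
        )
    if not plotted:
        raise ValidationError("no scenario is plottable on log-log axes")

    fig, ax = plt.subplots(figsize=(7, 5.5))
    programmes = sorted({s.programme for s in plotted})
    cmap = plt.get_cmap("tab20")
    for i, prog in enumerate(programmes):
        xs = [s.hly for s in plotted if s.programme == prog]
        ys = [s.cost_pv for s in plotted if s.programme == prog]
        ax.scatter(
            xs, ys, s=14, color=cmap(i % 20), label=prog, zorder=3
        )
    h_lo = min(s.hly for s in plotted)
    h_hi = max(s.hly for s in plotted)
    for edge in scheme.edges:
        ax.plot(
            [h_lo, h_hi],
            [edge * h_lo, edge * h_hi],
            color="0.6",
            lw=0.8,
            zorder=1,
        )
        ax.annotate(
            f"${edge:g}/HLY",
            xy=(h_hi, edge * h_hi),
            fontsize=7,
            color="0.4",
        )
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel("healthy life years gained (vs. null)")
    ax.set_ylabel("present-value cost (I$)")
    ax.set_title(spec.title or "Cost-effectiveness isoquant plot")
    if len(programmes) <= 12:
        ax.legend(fontsize=6, ncol=2)
    return _save(fig, spec)


def plot_expansion(
    path: ExpansionPath, spec: Optional[PlotSpec] = None
) -> Path:
    """Cumulative health (x) vs. cumulative cost (y) of the expansion path,
    from the null outward; each segment's slope equals its ICER."""
    spec = spec or PlotSpec(out="expansion.svg")
    if not path.steps:
        raise ValidationError("cannot plot an empty expansion path")
    xs = [0.0] + [s.cum_hly for s in path.steps]
    ys = [0.0] + [s.cum_cost for s in path.steps]
    fig, ax = plt.subplots(figsize=(7, 5))
    ax.plot(xs, ys, marker="o", ms=3, lw=1.2, color="tab:blue")
    ax.set_xlabel("cumulative healthy life years gained")
    ax.set_ylabel("cumulative present-value cost (I$)")
    ax.set_title(spec.title or "Optimized expansion path")
    return _save(fig, spec)


def plot_platform_stack(
    packages: Mapping[Platform, BenefitPackage],
    spec: Optional[PlotSpec] = None,
) -> Path:
    """Per-platform package summaries: total health gain and per-capita
    annual cost, side by side."""
    spec = spec or PlotSpec(out="platforms.svg")
    if not packages:
        raise ValidationError("need at least one platform package")
    platforms = [p for p in Platform if p in packages]
    hlys = [packages[p].total_hly for p in platforms]
    costs = [packages[p].per_capita_annual_cost for p in platforms]
    labels = [p.value.replace("_", " ") for p in platforms]

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4.5))
    ax1.bar(labels, hlys, color="tab:green")
    ax1.set_ylabel("total healthy life years gained")
    ax1.tick_params(axis="x", labelrotation=30)
    ax2.bar(labels, costs, color="tab:orange")
    ax2.set_ylabel("per-capita annual cost (I$/person/year)")
    ax2.tick_params(axis="x", labelrotation=30)
    fig.suptitle(spec.title or "Benefit packages by delivery platform")
    fig.tight_layout()
    return _save(fig, spec)
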