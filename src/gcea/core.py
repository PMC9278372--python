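"""Discounting and cost-effectiveness ratio arithmetic.

The analysis convention is differential discounting: costs discounted at
3% per year, health benefits at 0%, over a 100-year horizon, with payments
falling at the start of each year (the t = 0 term undiscounted).  Both
rates are configurable through :class:`DiscountSpec`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np

from .models import (
    NULL_POINT,
    CostEffectPoint,
    GceaError,
    MutualExclusivityError,
    ProgrammeCluster,
    StreamSeries,
    UndefinedRatioError,
    ValidationError,
)


class DominanceSignal(GceaError):
    """Raised when an incremental ratio is requested for a move that gains
    no health: the caller must treat the target as dominated or tied."""


@dataclass(frozen=True)
class DiscountSpec:
    """Differential discounting convention.

    Parameters
    ----------
    cost_rate
        Annual discount rate applied to costs (default 0.03).
    health_rate
        Annual discount rate applied to health benefits (default 0.0, the
        headline presentation; 3% variants exist elsewhere in the series).
    horizon
        Analytic horizon in years (default 100).
    """

    cost_rate: float = 0.03
    health_rate: float = 0.0
    horizon: int = 100

    def __post_init__(self) -> None:
        for name, rate in (("cost_rate", self.cost_rate),
                           ("health_rate", self.health_rate)):
            if not 0.0 <= rate < 1.0:
                raise ValidationError(f"{name} must be in [0, 1)")
        if self.horizon < 1:
            raise ValidationError("horizon must be >= 1 year")

    def cost_annuity_factor(self) -> float:
        return annuity_factor(self.cost_rate, self.horizon)


def annuity_factor(rate: float, horizon: int) -> float:
    """Sum of start-of-year discount factors over ``horizon`` years:
    Σ_{t=0}^{H−1} (1+r)^{−t}; equals ``horizon`` when ``rate`` is 0."""
    if rate < 0:
        raise ValidationError("discount rate must be >= 0")
    if rate == 0:
        return float(horizon)
    return (1.0 - (1.0 + rate) ** (-horizon)) / rate * (1.0 + rate)


def present_value(
    stream: Union[StreamSeries, Sequence[float]], rate: float
) -> float:
    """Present value of a yearly stream with start-of-year payments:
    PV = Σ_t x_t / (1+r)^t for t = 0 … len−1."""
    if rate < 0:
        raise ValidationError("discount rate must be >= 0")
    values = np.asarray(
        stream.values if isinstance(stream, StreamSeries) else stream,
        dtype=float,
    )
    t = np.arange(values.size)
    return float(np.sum(values / (1.0 + rate) ** t))


def acer(point: CostEffectPoint) -> float:
    """Average cost-effectiveness ratio vs. the null: cost / hly.

    Undefined (raises) when the scenario gains no health — such a scenario
    cannot be ranked.
    """
    if point.hly <= 0:
        raise UndefinedRatioError(
            "ACER undefined for zero health gain; the scenario cannot be"
            " ranked on the cost-effectiveness plane"
        )
    return point.cost / point.hly


@dataclass(frozen=True)
class Icer:
    """An incremental cost-effectiveness ratio. ``cost_saving`` is True when
    the move gains health while reducing cost; such a move is unambiguously
    worthwhile and must not be ranked by its (negative) ratio."""

    value: float
    cost_saving: bool = False


def icer(from_point: CostEffectPoint, to_point: CostEffectPoint) -> Icer:
    """Incremental ratio of moving from one package point to a larger one:
    (Δcost / Δhly). Raises :class:`DominanceSignal` when the move gains no
    health."""
    d_hly = to_point.hly - from_point.hly
    d_cost = to_point.cost - from_point.cost
    if d_hly <= 0:
        raise DominanceSignal(
            "the target point gains no health over the source; treat it as"
            " dominated or tied instead of computing a ratio"
        )
    return Icer(d_cost / d_hly, cost_saving=d_cost < 0)


@dataclass(frozen=True)
class OverlapParams:
    """Parametric within-programme overlap model used when no explicit
    combination data exist.

    ``beta`` is the benefit-overlap proportion (later additions within a
    programme yield smaller incremental health, since part of the burden is
    already averted); ``gamma`` is the cost-synergy proportion (economies of
    scale shrink later additions' costs).  The k-th scenario of a programme,
    in ascending ACER order, contributes hly·(1−β)^(k−1) and cost·(1−γ)^(k−1).
    Defaults are the fully additive limit.
    """

    beta: float = 0.0
    gamma: float = 0.0

    def __post_init__(self) -> None:
        for name, p in (("beta", self.beta), ("gamma", self.gamma)):
            if not 0.0 <= p < 1.0:
                raise ValidationError(f"{name} must be in [0, 1)")


def _acer_order_key(scenario) -> tuple:
    ratio = scenario.cost_pv / scenario.hly if scenario.hly > 0 else np.inf
    return (ratio, scenario.id)


def combine_within_programme(
    selected: Iterable[str],
    cluster: ProgrammeCluster,
    params: Optional[OverlapParams] = None,
    include_fixed: bool = True,
) -> CostEffectPoint:
    """Joint (cost, hly) of co-implementing a set of one programme's
    scenarios.

    Explicit combination data for the exact selected subset override the
    parametric model.  Otherwise scenarios are ordered by ascending ACER and
    the sequential overlap model of :class:`OverlapParams` is applied.  The
    programme's fixed support cost enters once whenever the selection is
    non-empty.
    """
    params = params or OverlapParams()
    ids = frozenset(selected)
    if not ids:
        return NULL_POINT
    unknown = ids - cluster.ids
    if unknown:
        raise ValidationError(
            f"ids {sorted(unknown)} are not scenarios of programme"
            f" {cluster.programme!r}"
        )
    members = [s for s in cluster.scenarios if s.id in ids]
    groups: dict[str, str] = {}
    for s in members:
        if s.exclusivity_group:
            if s.exclusivity_group in groups:
                raise MutualExclusivityError(
                    f"scenarios {groups[s.exclusivity_group]!r} and {s.id!r}"
                    f" share exclusivity_group {s.exclusivity_group!r}"
                )
            groups[s.exclusivity_group] = s.id

    fixed = cluster.fixed_support_cost if include_fixed else 0.0
    joint = cluster.combinations.get(ids)
    if joint is not None:
        return CostEffectPoint(joint[0] + fixed, joint[1])

    members.sort(key=_acer_order_key)
    cost = fixed
    hly = 0.0
    for k, s in enumerate(members):
        cost += s.cost_pv * (1.0 - params.gamma) ** k
        hly += s.hly * (1.0 - params.beta) ** k
    return CostEffectPoint(cost, hly)


def combine_across_programmes(
    points: Iterable[CostEffectPoint],
) -> CostEffectPoint:
    """Component-wise sum: costs and benefits are additive across distinct
    disease programmes. The empty package is the null."""
    total = NULL_POINT
    for p in points:
        total = total + p
    return total


def evaluate_selection(
    clusters: Mapping[str, ProgrammeCluster],
    selected: Iterable[str],
    params: Optional[OverlapParams] = None,
    include_fixed: bool = True,
) -> CostEffectPoint:
    """Package point of an arbitrary cross-programme scenario selection:
    within-programme combination rules per programme, additive across."""
    ids = frozenset(selected)
    by_programme: dict[str, set] = {}
    id_to_programme = {
        s.id: c.programme for c in clusters.values() for s in c.scenarios
    }
    for sid in ids:
        if sid not in id_to_programme:
            raise ValidationError(f"unknown scenario id {sid!r}")
        by_programme.setdefault(id_to_programme[sid], set()).add(sid)
    return combine_across_programmes(
        combine_within_programme(
            sel, clusters[prog], params=params, include_fixed=include_fixed
        )
        for prog, sel in by_programme.items()
    )
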