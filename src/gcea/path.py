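"""Expansion-path construction: greedy adoption of the next most
cost-effective move away from the null, with dominance handling, coverage
upgrades, extended-dominance cleanup and budget truncation.

Starting from the null package, each round evaluates every available
scenario as an addition to the current package (within-programme
combination rules for same-programme additions, additivity across
programmes, a higher coverage rung replacing a lower one) and adopts the
candidate with the lowest incremental cost-effectiveness ratio.  In the
additive limit (no benefit overlap, no cost synergy, no fixed programme
costs) the cumulative points of the resulting path trace the lower convex
hull of every feasible package point — the efficiency frontier.

Two dominance policies are supported.  Under ``dominance="label"`` (the
default) scenarios dominated by the adopted candidate at some step are
recorded with their would-be ICER but stay available, which is what makes
the frontier guarantee hold.  Under ``dominance="exclude"`` they are
permanently barred from the package — the stricter league-table reading in
which an intervention with less health gain at higher cost than the one
being added can never enter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .core import DiscountSpec, OverlapParams, evaluate_selection
from .models import (
    NULL_POINT,
    BenefitPackage,
    CostEffectPoint,
    EmptyPathError,
    ExclusionReason,
    Exclusion,
    ExpansionPath,
    ExpansionStep,
    InterventionScenario,
    ProgrammeCluster,
    ValidationError,
    all_scenarios,
    validate_dataset,
)

_REL_TOL = 1e-12


@dataclass(frozen=True)
class PathConfig:
    """Knobs of the path builder.

    ``dominance`` selects the dominance policy ("label" or "exclude", see
    module docstring).  Ties in the incremental ratio within
    ``tie_epsilon`` (relative) are broken by ascending scenario id for
    bitwise reproducibility.  ``budget_per_capita`` (I$/person/year,
    equivalent-annual-cost convention) with ``region_population`` truncates
    the path; ``allow_partial`` pro-rates the first unaffordable step
    linearly instead of dropping it.
    """

    extended_dominance: bool = True
    dominance: str = "label"
    tie_epsilon: float = 1e-9
    budget_per_capita: Optional[float] = None
    region_population: Optional[float] = None
    allow_partial: bool = False
    overlap: OverlapParams = field(default_factory=OverlapParams)
    include_fixed: bool = True

    def __post_init__(self) -> None:
        if self.tie_epsilon < 0:
            raise ValidationError("tie_epsilon must be >= 0")
        if self.dominance not in ("label", "exclude"):
            raise ValidationError("dominance must be 'label' or 'exclude'")
        if self.budget_per_capita is not None and self.region_population is None:
            raise ValidationError(
                "region_population is required when budget_per_capita is set"
            )


@dataclass
class _Candidate:
    scenario_id: str
    point: CostEffectPoint
    delta_cost: float
    delta_hly: float
    ratio: float
    replaces: Optional[str]


class _Builder:
    def __init__(
        self, clusters: Sequence[ProgrammeCluster], config: PathConfig
    ) -> None:
        validate_dataset(clusters)
        self.config = config
        self.clusters = {c.programme: c for c in clusters}
        self.scenarios: dict[str, InterventionScenario] = {
            s.id: s for s in all_scenarios(clusters)
        }
        if not any(s.hly > 0 for s in self.scenarios.values()):
            raise EmptyPathError(
                "no scenario gains any health; an expansion path cannot"
                " leave the null"
            )
        self.order: list[str] = []  # surviving adoption order
        self.available: set[str] = set(self.scenarios)
        self.excluded: dict[str, Exclusion] = {}
        self.dominated_at: dict[str, float] = {}  # label mode bookkeeping

    # -- package evaluation -------------------------------------------------

    def _evaluate(self, selection) -> CostEffectPoint:
        return evaluate_selection(
            self.clusters,
            selection,
            params=self.config.overlap,
            include_fixed=self.config.include_fixed,
        )

    def _replay(self) -> list[ExpansionStep]:
        """Recompute steps (deltas, ICERs, cumulative points) for the
        current adoption order, deriving coverage replacements."""
        steps: list[ExpansionStep] = []
        sel: set[str] = set()
        prev = NULL_POINT
        for sid in self.order:
            s = self.scenarios[sid]
            replaced = self._group_mate(sel, s)
            if replaced is not None:
                sel.discard(replaced)
            sel.add(sid)
            pt = self._evaluate(sel)
            d_cost = pt.cost - prev.cost
            d_hly = pt.hly - prev.hly
            ratio = d_cost / d_hly if d_hly > 0 else math.inf
            steps.append(
                ExpansionStep(
                    scenario_id=sid,
                    delta_cost=d_cost,
                    delta_hly=d_hly,
                    icer=ratio,
                    cum_cost=pt.cost,
                    cum_hly=pt.hly,
                    selection=frozenset(sel),
                    replaces=replaced,
                )
            )
            prev = pt
        return steps

    def _group_mate(self, selection, scenario) -> Optional[str]:
        if not scenario.exclusivity_group:
            return None
        for sid in selection:
            other = self.scenarios[sid]
            if (
                other.exclusivity_group == scenario.exclusivity_group
                and sid != scenario.id
            ):
                return sid
        return None

    # -- greedy loop --------------------------------------------------------

    def _candidates(self, selection, current) -> list[_Candidate]:
        out = []
        for sid in sorted(self.available):
            s = self.scenarios[sid]
            replaced = self._group_mate(selection, s)
            new_sel = set(selection)
            if replaced is not None:
                new_sel.discard(replaced)
            new_sel.add(sid)
            pt = self._evaluate(new_sel)
            d_cost = pt.cost - current.cost
            d_hly = pt.hly - current.hly
            if d_hly <= 0:
                continue  # not adoptable from here (lower rung or no gain)
            out.append(
                _Candidate(sid, pt, d_cost, d_hly, d_cost / d_hly, replaced)
            )
        return out

    def _pick(self, cands: list[_Candidate]) -> _Candidate:
        savers = [c for c in cands if c.delta_cost < 0]
        if savers:
            # Cost-saving moves are unambiguously optimal; take the largest
            # health gain first rather than ranking by (negative) ratio.
            return max(savers, key=lambda c: (c.delta_hly, c.scenario_id))
        best = min(cands, key=lambda c: (c.ratio, c.scenario_id))
        eps = self.config.tie_epsilon
        tied = [
            c
            for c in cands
            if c.ratio - best.ratio <= eps * max(1.0, abs(best.ratio))
        ]
        return min(tied, key=lambda c: c.scenario_id)

    def _mark_dominated(
        self, cands: list[_Candidate], adopted: _Candidate
    ) -> None:
        for c in cands:
            if c.scenario_id == adopted.scenario_id:
                continue
            le_hly = c.delta_hly <= adopted.delta_hly
            ge_cost = c.delta_cost >= adopted.delta_cost
            strict = c.delta_hly < adopted.delta_hly or c.delta_cost > adopted.delta_cost
            if le_hly and ge_cost and strict:
                if self.config.dominance == "exclude":
                    self.available.discard(c.scenario_id)
                    self.excluded[c.scenario_id] = Exclusion(
                        ExclusionReason.STRICTLY_DOMINATED,
                        would_be_icer=c.ratio,
                    )
                else:
                    self.dominated_at.setdefault(c.scenario_id, c.ratio)

    def _extended_dominance_cleanup(self) -> None:
        """Re-splice the path until ICERs are non-decreasing, relabelling the
        removed steps. Cost-saving steps sort before any ratio."""
        while True:
            steps = self._replay()
            victim = None
            prev_icer = -math.inf
            prev_idx = None
            for i in range(len(steps)):
                if steps[i].delta_hly <= 0:
                    victim = i  # no longer adds health after a removal
                    break
                if steps[i].delta_cost < 0:
                    continue  # cost-saving step: exempt from ratio ordering
                if steps[i].icer < prev_icer * (1.0 - _REL_TOL) - _REL_TOL:
                    victim = prev_idx
                    break
                prev_icer, prev_idx = steps[i].icer, i
            if victim is None:
                return
            sid = self.order.pop(victim)
            self.excluded[sid] = Exclusion(
                ExclusionReason.EXTENDED_DOMINATED,
                would_be_icer=steps[victim].icer,
            )

    def build(self) -> ExpansionPath:
        while True:
            steps = self._replay()
            if steps:
                last = steps[-1]
                current = CostEffectPoint(last.cum_cost, last.cum_hly)
                selection = set(last.selection)
            else:
                current, selection = NULL_POINT, set()
            cands = self._candidates(selection, current)
            if not cands:
                break
            chosen = self._pick(cands)
            self._mark_dominated(cands, chosen)
            self.available.discard(chosen.scenario_id)
            self.order.append(chosen.scenario_id)
            if self.config.extended_dominance:
                self._extended_dominance_cleanup()
        steps = tuple(self._replay())
        self._classify_leftovers(steps)
        return ExpansionPath(steps=steps, excluded=dict(self.excluded))

    def _classify_leftovers(self, steps) -> None:
        on_path = {s.scenario_id for s in steps}
        final = steps[-1].selection if steps else frozenset()
        final_groups = {
            self.scenarios[sid].exclusivity_group
            for sid in final
            if self.scenarios[sid].exclusivity_group
        }
        for sid in sorted(self.available):
            if sid in on_path:
                continue
            s = self.scenarios[sid]
            if s.exclusivity_group and s.exclusivity_group in final_groups:
                self.excluded[sid] = Exclusion(
                    ExclusionReason.SUPERSEDED_COVERAGE,
                    would_be_icer=self.dominated_at.get(sid),
                )
            else:
                self.excluded[sid] = Exclusion(
                    ExclusionReason.STRICTLY_DOMINATED,
                    would_be_icer=self.dominated_at.get(sid),
                )


def build_expansion_path(
    clusters: Sequence[ProgrammeCluster],
    config: Optional[PathConfig] = None,
) -> ExpansionPath:
    """Construct the optimized expansion path over a set of programme
    clusters.  See the module docstring for the algorithm and the dominance
    policies."""
    return _Builder(clusters, config or PathConfig()).build()


def per_capita_annual_cost(
    point,
    population: float,
    spec: Optional[DiscountSpec] = None,
    convention: str = "equivalent_annual",
    final_year_cost: Optional[float] = None,
) -> float:
    """Long-run annual cost per person of a package point.

    The default ``equivalent_annual`` convention converts the present-value
    cost into the level yearly payment with the same present value (PV
    divided by the annuity factor of the cost rate over the horizon), then
    divides by the population.  The ``steady_state`` alternative divides a
    supplied final-year undiscounted cost by the population.
    """
    if population <= 0:
        raise ValidationError("population must be > 0")
    spec = spec or DiscountSpec()
    cost = point.cost if isinstance(point, CostEffectPoint) else float(point)
    if convention == "equivalent_annual":
        return cost / spec.cost_annuity_factor() / population
    if convention == "steady_state":
        if final_year_cost is None:
            raise ValidationError(
                "steady_state convention needs final_year_cost"
            )
        return final_year_cost / population
    raise ValidationError(f"unknown per-capita convention {convention!r}")


def apply_budget_constraint(
    path: ExpansionPath,
    config: PathConfig,
    spec: Optional[DiscountSpec] = None,
) -> BenefitPackage:
    """Truncate an expansion path at a per-capita annual budget.

    Walks the path in order and returns the largest prefix whose
    equivalent-annual per-capita cost stays within the budget.  With
    ``allow_partial`` the first unaffordable step is adopted pro-rata
    (cost and health scaled linearly).  A budget below the first step
    yields the empty package.
    """
    if config.budget_per_capita is None or config.region_population is None:
        raise ValidationError(
            "apply_budget_constraint needs budget_per_capita and"
            " region_population in the config"
        )
    spec = spec or DiscountSpec()
    pop = config.region_population
    af = spec.cost_annuity_factor()
    budget_pv = config.budget_per_capita * af * pop

    idx = 0
    for i, step in enumerate(path.steps, start=1):
        if step.cum_cost <= budget_pv * (1 + _REL_TOL):
            idx = i
        else:
            break

    if idx == 0:
        sel: frozenset = frozenset()
        cost, hly = 0.0, 0.0
    else:
        last = path.steps[idx - 1]
        sel, cost, hly = last.selection, last.cum_cost, last.cum_hly

    if config.allow_partial and idx < len(path.steps):
        nxt = path.steps[idx]
        if nxt.delta_cost > 0:
            frac = (budget_pv - cost) / nxt.delta_cost
            frac = min(max(frac, 0.0), 1.0)
            if frac > 0:
                cost += frac * nxt.delta_cost
                hly += frac * nxt.delta_hly
                sel = sel | {nxt.scenario_id}

    return BenefitPackage(
        scenario_ids=frozenset(sel),
        total_cost=cost,
        total_hly=hly,
        per_capita_annual_cost=per_capita_annual_cost(cost, pop, spec),
        region_population=pop,
    )


def path_frame(path: ExpansionPath):
    """Expansion path as a tidy DataFrame: one row per adopted step, then
    one row per excluded scenario (status column carries the reason)."""
    import pandas as pd

    rows = []
    for rank, s in enumerate(path.steps, start=1):
        rows.append(
            {
                "rank": rank,
                "scenario_id": s.scenario_id,
                "delta_cost": s.delta_cost,
                "delta_hly": s.delta_hly,
                "icer": s.icer,
                "cum_cost": s.cum_cost,
                "cum_hly": s.cum_hly,
                "status": "adopted",
            }
        )
    for sid in sorted(path.excluded):
        exc = path.excluded[sid]
        rows.append(
            {
                "rank": None,
                "scenario_id": sid,
                "delta_cost": None,
                "delta_hly": None,
                "icer": exc.would_be_icer,
                "cum_cost": None,
                "cum_hly": None,
                "status": exc.reason.value,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "rank",
            "scenario_id",
            "delta_cost",
            "delta_hly",
            "icer",
            "cum_cost",
            "cum_hly",
            "status",
        ],
    )
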