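"""Synthetic intervention datasets and the exhaustive-enumeration frontier
oracle.

The generator emulates the statistical structure the sectoral analysis
assumes: cost-effectiveness ratios spanning several orders of magnitude
(drawn log-uniformly so that every band is populated), lognormal costs,
programme clusters with a shared fixed support cost, and coverage ladders
whose rungs are totals at each coverage level with strictly diminishing
incremental health gain (so higher rungs carry higher ACERs).  It does not
model disease natural history — cost/HLY endpoints are drawn directly.

The oracle enumerates every feasible selection (at most one member per
exclusivity group), evaluates each under the package combination rules,
and returns the efficiency frontier — the lower convex hull of the cloud
of feasible package points — for cross-checking the greedy expansion path.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterator, Optional, Sequence

import numpy as np

from .core import OverlapParams, evaluate_selection
from .models import (
    CostEffectPoint,
    InterventionScenario,
    OracleSizeError,
    Platform,
    ProgrammeCluster,
    ValidationError,
    all_scenarios,
)

_PLATFORMS = tuple(Platform)


@dataclass(frozen=True)
class SynthConfig:
    """Shape of a synthetic intervention dataset.

    ``scenarios_per_programme`` bounds the number of base interventions per
    programme (inclusive); a base intervention becomes a 2-3 rung coverage
    ladder with probability ``coverage_ladder_prob``, each rung a separate
    scenario.  ``acer_log10_range`` is the support of log10(ACER) — the
    default spans roughly I$0.3 to I$30000 per HLY, matching the published
    spread.  ``cost_lognormal_params`` are (mu, sigma) of log scenario
    cost in I$; the default median of I$10^8 is chosen so that, against
    the default region population of 10^8, a full package costs tens of
    international dollars per person per year, the scale of real sectoral
    packages.  ``benefit_overlap`` (beta) and ``cost_synergy`` (gamma)
    parameterize within-programme combination; ``fixed_support_cost_fraction``
    sets each programme's fixed support cost as a fraction of its mean
    scenario cost.
    """

    n_programmes: int = 20
    scenarios_per_programme: tuple[int, int] = (2, 8)
    acer_log10_range: tuple[float, float] = (-0.5, 4.5)
    cost_lognormal_params: tuple[float, float] = (math.log(1e8), 1.5)
    benefit_overlap: float = 0.2
    cost_synergy: float = 0.1
    fixed_support_cost_fraction: float = 0.1
    coverage_ladder_prob: float = 0.3
    region_population: float = 1e8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_programmes < 1:
            raise ValidationError("n_programmes must be >= 1")
        lo, hi = self.scenarios_per_programme
        if not 1 <= lo <= hi:
            raise ValidationError("scenarios_per_programme must be 1 <= lo <= hi")
        if not self.acer_log10_range[0] < self.acer_log10_range[1]:
            raise ValidationError("acer_log10_range must be non-degenerate")
        for name in ("benefit_overlap", "cost_synergy",
                     "fixed_support_cost_fraction", "coverage_ladder_prob"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValidationError(f"{name} must be in [0, 1)")
        if self.region_population <= 0:
            raise ValidationError("region_population must be > 0")

    @property
    def overlap(self) -> OverlapParams:
        return OverlapParams(beta=self.benefit_overlap, gamma=self.cost_synergy)


def generate(config: SynthConfig) -> tuple[list[ProgrammeCluster], dict]:
    """Draw a synthetic dataset; deterministic given ``config.seed``.

    Returns the programme clusters and a truth record holding every
    scenario's true ACER, the ladder structure and the overlap parameters,
    for parameter-recovery tests.
    """
    rng = np.random.default_rng(config.seed)
    lo10, hi10 = config.acer_log10_range
    mu, sigma = config.cost_lognormal_params

    clusters: list[ProgrammeCluster] = []
    truth_scenarios: dict[str, dict] = {}
    ladders: dict[str, list[str]] = {}

    for p in range(config.n_programmes):
        prog = f"prog{p:03d}"
        n_base = int(
            rng.integers(
                config.scenarios_per_programme[0],
                config.scenarios_per_programme[1] + 1,
            )
        )
        scenarios: list[InterventionScenario] = []
        for b in range(n_base):
            platform = _PLATFORMS[rng.integers(0, len(_PLATFORMS))]
            acer1 = 10.0 ** rng.uniform(lo10, hi10)
            cost1 = float(rng.lognormal(mu, sigma))
            hly1 = cost1 / acer1
            is_ladder = rng.random() < config.coverage_ladder_prob
            n_rungs = int(rng.integers(2, 4)) if is_ladder else 1
            group = f"{prog}-g{b:02d}" if n_rungs > 1 else None

            cost, hly = cost1, hly1
            d_hly, ricer = hly1, acer1
            rung_ids: list[str] = []
            for r in range(n_rungs):
                if r > 0:
                    # diminishing marginal health, escalating incremental cost
                    d_hly = d_hly * rng.uniform(0.3, 0.8)
                    ricer = ricer * rng.uniform(1.5, 4.0)
                    hly = hly + d_hly
                    cost = cost + ricer * d_hly
                sid = f"{prog}-i{b:02d}{'abc'[r]}"
                scenarios.append(
                    InterventionScenario(
                        id=sid,
                        name=f"intervention {b} of {prog}"
                        + (f" (coverage rung {r + 1})" if group else ""),
                        programme=prog,
                        platform=platform,
                        cost_pv=cost,
                        hly=hly,
                        exclusivity_group=group,
                    )
                )
                truth_scenarios[sid] = {
                    "acer": cost / hly,
                    "group": group,
                    "rung": r + 1 if group else None,
                }
                rung_ids.append(sid)
            if group:
                ladders[group] = rung_ids

        mean_cost = float(np.mean([s.cost_pv for s in scenarios]))
        clusters.append(
            ProgrammeCluster(
                programme=prog,
                scenarios=tuple(scenarios),
                fixed_support_cost=config.fixed_support_cost_fraction
                * mean_cost,
            )
        )

    truth = {
        "seed": config.seed,
        "beta": config.benefit_overlap,
        "gamma": config.cost_synergy,
        "region_population": config.region_population,
        "scenarios": truth_scenarios,
        "ladders": ladders,
    }
    return clusters, truth


# ---------------------------------------------------------------------------
# exhaustive oracle
# ---------------------------------------------------------------------------


def enumerate_feasible(
    clusters: Sequence[ProgrammeCluster],
    params: Optional[OverlapParams] = None,
    include_fixed: bool = True,
) -> Iterator[tuple[frozenset, CostEffectPoint]]:
    """Yield every feasible (selection, package point), honouring
    exclusivity groups and the programme combination rules."""
    scenarios = all_scenarios(clusters)
    groups: dict[str, list[str]] = {}
    singles: list[str] = []
    for s in scenarios:
        if s.exclusivity_group:
            groups.setdefault(s.exclusivity_group, []).append(s.id)
        else:
            singles.append(s.id)
    cluster_map = {c.programme: c for c in clusters}
    choice_sets = [[None, *members] for members in groups.values()]
    choice_sets.extend([[None, sid] for sid in singles])
    for combo in itertools.product(*choice_sets):
        sel = frozenset(sid for sid in combo if sid is not None)
        yield sel, evaluate_selection(
            cluster_map, sel, params=params, include_fixed=include_fixed
        )


def _check_size(clusters, limit) -> None:
    n = len(all_scenarios(clusters))
    if n > limit:
        raise OracleSizeError(
            f"{n} scenarios exceed the enumeration limit of {limit}"
        )


def pareto_frontier(
    clusters: Sequence[ProgrammeCluster],
    limit: int = 12,
    params: Optional[OverlapParams] = None,
    include_fixed: bool = True,
) -> list[CostEffectPoint]:
    """Pareto-efficient feasible points (no other feasible point with at
    least as much health at no more cost, one strict), sorted by cost."""
    _check_size(clusters, limit)
    pts = sorted(
        {
            (pt.cost, pt.hly)
            for _, pt in enumerate_feasible(
                clusters, params=params, include_fixed=include_fixed
            )
        },
        key=lambda t: (t[0], -t[1]),
    )
    out: list[CostEffectPoint] = []
    best_hly = -math.inf
    for cost, hly in pts:
        if hly > best_hly:
            out.append(CostEffectPoint(cost, hly))
            best_hly = hly
    return out


def oracle_frontier(
    clusters: Sequence[ProgrammeCluster],
    limit: int = 12,
    params: Optional[OverlapParams] = None,
    include_fixed: bool = True,
) -> list[CostEffectPoint]:
    """Efficiency frontier by brute force: the lower convex hull of every
    feasible package point, starting at the null, sorted by cost.

    This is exactly the set of cumulative points an optimized expansion
    path can visit in the additive limit, and is the independent oracle the
    path construction is tested against.
    """
    efficient = pareto_frontier(
        clusters, limit=limit, params=params, include_fixed=include_fixed
    )
    # monotone-chain lower hull on (hly, cost); efficient points are already
    # sorted by cost and, being efficient, by hly too
    hull: list[CostEffectPoint] = []
    for p in efficient:
        while len(hull) >= 2:
            a, b = hull[-2], hull[-1]
            cross = (b.hly - a.hly) * (p.cost - a.cost) - (
                p.hly - a.hly
            ) * (b.cost - a.cost)
            if cross <= 0:  # b on or above chord a->p: not a hull vertex
                hull.pop()
            else:
                break
        hull.append(p)
    return hull
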