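"""Domain types for generalized cost-effectiveness analysis (GCEA).

The unit conventions follow sector-wide GCEA practice: costs are
present values in 2010 international dollars (I$) discounted at the cost
rate over a 100-year horizon, and health benefits are undiscounted healthy
life years (HLY) gained relative to the null scenario — the counterfactual
in which no intervention is delivered, located at (cost, hly) = (0, 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Optional, Sequence


class GceaError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(GceaError):
    """A domain object violates one of its invariants."""


class SchemaError(GceaError):
    """An input table does not match the documented column schema."""


class UndefinedRatioError(GceaError):
    """A cost-effectiveness ratio was requested for zero health gain."""


class MutualExclusivityError(ValidationError):
    """Two scenarios sharing an exclusivity group were selected together."""


class EmptyPathError(GceaError):
    """No scenario with positive health gain is available to start a path."""


class OracleSizeError(GceaError):
    """The exhaustive-enumeration oracle was asked for too many scenarios."""


class Platform(str, Enum):
    """Service-delivery platform through which an intervention reaches people.

    ``population``, ``community`` and ``first_level_clinical`` together make
    up primary healthcare (PHC); ``referral`` is its complement.
    """

    POPULATION = "population"
    COMMUNITY = "community"
    FIRST_LEVEL_CLINICAL = "first_level_clinical"
    REFERRAL = "referral"


PHC_PLATFORMS = frozenset(
    {Platform.POPULATION, Platform.COMMUNITY, Platform.FIRST_LEVEL_CLINICAL}
)


@dataclass(frozen=True)
class InterventionScenario:
    """One intervention scenario: a single intervention, one coverage level
    of an intervention analysed at several coverage levels, or a small bundle.

    Parameters
    ----------
    id
        Short unique token, stable across runs (used for tie-breaking).
    name
        Free-text label.
    programme
        Disease/risk-factor programme the scenario belongs to.
    platform
        Most common delivery platform.
    cost_pv
        Present-value cost vs. the null, I$ ≥ 0.
    hly
        Healthy life years gained vs. the null, undiscounted, ≥ 0.
    exclusivity_group
        Optional token shared by mutually exclusive scenarios (a coverage
        ladder or overlapping bundle); at most one member can be adopted.
    population_in_need
        Optional count of persons the scenario targets.
    """

    id: str
    name: str
    programme: str
    platform: Platform
    cost_pv: float
    hly: float
    exclusivity_group: Optional[str] = None
    population_in_need: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("scenario id must be a non-empty token")
        if self.cost_pv < 0:
            raise ValidationError(f"scenario {self.id!r}: cost_pv must be >= 0")
        if self.hly < 0:
            raise ValidationError(f"scenario {self.id!r}: hly must be >= 0")
        if self.cost_pv == 0 and self.hly == 0:
            raise ValidationError(
                f"scenario {self.id!r} is identical to the null (zero cost and"
                " zero health benefit) and cannot be analysed"
            )
        if self.population_in_need is not None and self.population_in_need <= 0:
            raise ValidationError(
                f"scenario {self.id!r}: population_in_need must be > 0"
            )

    @property
    def point(self) -> "CostEffectPoint":
        return CostEffectPoint(self.cost_pv, self.hly)


@dataclass(frozen=True)
class CostEffectPoint:
    """A (cost, health) point on the cost-effectiveness plane.

    The null scenario is the origin ``CostEffectPoint(0.0, 0.0)``.
    """

    cost: float
    hly: float

    def __add__(self, other: "CostEffectPoint") -> "CostEffectPoint":
        return CostEffectPoint(self.cost + other.cost, self.hly + other.hly)


NULL_POINT = CostEffectPoint(0.0, 0.0)


@dataclass(frozen=True)
class ProgrammeCluster:
    """All scenarios of one disease programme plus its shared support cost.

    ``fixed_support_cost`` is the present value of programme support
    (management, surveillance, training infrastructure) incurred once per
    programme as soon as any of its scenarios is delivered.

    ``combinations`` optionally gives joint (cost_pv, hly) values for
    specific subsets of scenario ids that are co-implemented; when a subset
    has an entry, the joint values override the parametric overlap model.
    """

    programme: str
    scenarios: tuple[InterventionScenario, ...]
    fixed_support_cost: float = 0.0
    combinations: Mapping[frozenset, tuple[float, float]] = field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        if self.fixed_support_cost < 0:
            raise ValidationError(
                f"programme {self.programme!r}: fixed_support_cost must be >= 0"
            )
        ids = {s.id for s in self.scenarios}
        if len(ids) != len(self.scenarios):
            raise ValidationError(
                f"programme {self.programme!r}: duplicate scenario ids"
            )
        for s in self.scenarios:
            if s.programme != self.programme:
                raise ValidationError(
                    f"scenario {s.id!r} belongs to programme {s.programme!r},"
                    f" not {self.programme!r}"
                )
        for subset, (cost, hly) in self.combinations.items():
            unknown = set(subset) - ids
            if unknown:
                raise ValidationError(
                    f"programme {self.programme!r}: combination key references"
                    f" unknown scenario ids {sorted(unknown)}"
                )
            members = [s for s in self.scenarios if s.id in subset]
            if hly > sum(m.hly for m in members) + 1e-9:
                raise ValidationError(
                    f"programme {self.programme!r}: combination"
                    f" {sorted(subset)} has joint hly above the sum of its"
                    " members (benefit overlap requires subadditivity)"
                )
            if cost < 0 or hly < 0:
                raise ValidationError(
                    f"programme {self.programme!r}: combination"
                    f" {sorted(subset)} has negative cost or hly"
                )

    def scenario(self, scenario_id: str) -> InterventionScenario:
        for s in self.scenarios:
            if s.id == scenario_id:
                return s
        raise KeyError(scenario_id)

    @property
    def ids(self) -> frozenset:
        return frozenset(s.id for s in self.scenarios)


class ExclusionReason(str, Enum):
    STRICTLY_DOMINATED = "strictly_dominated"
    EXTENDED_DOMINATED = "extended_dominated"
    SUPERSEDED_COVERAGE = "superseded_coverage"


@dataclass(frozen=True)
class Exclusion:
    """Why a scenario is off the optimized path, with the ICER it would
    have had at the step where it was last considered (useful for flagging
    near-ties that remain real-world candidates)."""

    reason: ExclusionReason
    would_be_icer: Optional[float] = None


@dataclass(frozen=True)
class ExpansionStep:
    """One adopted move along the expansion path.

    ``selection`` is the full scenario set of the package after this step;
    ``replaces`` names the lower coverage rung this step upgraded, if any.
    """

    scenario_id: str
    delta_cost: float
    delta_hly: float
    icer: float
    cum_cost: float
    cum_hly: float
    selection: frozenset = frozenset()
    replaces: Optional[str] = None


@dataclass(frozen=True)
class ExpansionPath:
    """Ordered adopted steps plus the map of excluded scenarios.

    Every input scenario appears exactly once: either as a step's
    ``scenario_id`` or as a key of ``excluded``.
    """

    steps: tuple[ExpansionStep, ...]
    excluded: Mapping[str, Exclusion] = field(default_factory=dict)

    @property
    def points(self) -> list[CostEffectPoint]:
        """Cumulative package points, starting from the null."""
        pts = [NULL_POINT]
        pts.extend(CostEffectPoint(s.cum_cost, s.cum_hly) for s in self.steps)
        return pts

    @property
    def final_selection(self) -> frozenset:
        return self.steps[-1].selection if self.steps else frozenset()


@dataclass(frozen=True)
class Band:
    """One order-of-magnitude cost-effectiveness band [lower, upper)."""

    lower: float
    upper: float
    label: str

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValidationError("band lower bound must be below upper bound")

    def __contains__(self, acer: float) -> bool:
        return self.lower <= acer < self.upper


@dataclass(frozen=True)
class LeagueEntry:
    scenario_id: str
    name: str
    acer: float


@dataclass(frozen=True)
class LeagueTable:
    """Platform → band label → entries sorted ascending by ACER."""

    entries: Mapping[Platform, Mapping[str, tuple[LeagueEntry, ...]]]

    def platform_entries(self, platform: Platform) -> list[LeagueEntry]:
        out: list[LeagueEntry] = []
        for band_entries in self.entries.get(platform, {}).values():
            out.extend(band_entries)
        return out

    def all_entries(self) -> list[tuple[Platform, str, LeagueEntry]]:
        out = []
        for platform, bands in self.entries.items():
            for label, band_entries in bands.items():
                for e in band_entries:
                    out.append((platform, label, e))
        return out


@dataclass(frozen=True)
class BenefitPackage:
    """A selected scenario set with its totals and per-capita annual cost."""

    scenario_ids: frozenset
    total_cost: float
    total_hly: float
    per_capita_annual_cost: float
    region_population: float

    def __post_init__(self) -> None:
        if self.region_population <= 0:
            raise ValidationError("region_population must be > 0")
        if self.per_capita_annual_cost < 0:
            raise ValidationError("per_capita_annual_cost must be >= 0")


@dataclass(frozen=True)
class StreamSeries:
    """A yearly amount stream over the analytic horizon (default 100 years
    beginning in 2010)."""

    values: tuple[float, ...]
    start_year: int = 2010

    def __post_init__(self) -> None:
        if len(self.values) == 0:
            raise ValidationError("stream must contain at least one year")

    def __len__(self) -> int:
        return len(self.values)


def validate_dataset(clusters: Sequence[ProgrammeCluster]) -> None:
    """Cross-cluster invariants: global id uniqueness and exclusivity groups
    shared by at least two scenarios."""
    seen: dict[str, str] = {}
    groups: dict[str, list[str]] = {}
    for cluster in clusters:
        for s in cluster.scenarios:
            if s.id in seen:
                raise ValidationError(
                    f"duplicate scenario id {s.id!r} (programmes"
                    f" {seen[s.id]!r} and {cluster.programme!r})"
                )
            seen[s.id] = cluster.programme
            if s.exclusivity_group:
                groups.setdefault(s.exclusivity_group, []).append(s.id)
    for group, members in groups.items():
        if len(members) < 2:
            raise ValidationError(
                f"exclusivity_group {group!r} has a single member"
                f" ({members[0]!r}); groups must tie together >= 2 scenarios"
            )


def all_scenarios(
    clusters: Sequence[ProgrammeCluster],
) -> list[InterventionScenario]:
    return [s for c in clusters for s in c.scenarios]


def is_finite_nonneg(x: float) -> bool:
    return math.isfinite(x) and x >= 0
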