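"""League tables: order-of-magnitude banding of average cost-effectiveness
ratios, stratified by delivery platform, with coverage-overlap
de-duplication and per-platform package costing.

Unlike the optimized expansion path, a league table does not exclude
dominated interventions — it lists everything that falls into each
order-of-magnitude cost-effectiveness band, so that near-ties remain
visible to decision-makers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from .core import DiscountSpec, OverlapParams, evaluate_selection
from .models import (
    Band,
    BenefitPackage,
    LeagueEntry,
    LeagueTable,
    Platform,
    ProgrammeCluster,
    ValidationError,
    validate_dataset,
)
from .path import per_capita_annual_cost


@dataclass(frozen=True)
class BandScheme:
    """Cost-effectiveness bands, one order of magnitude wide.

    ``edges`` are the interior band boundaries (each 10x the previous);
    the scheme tiles [0, inf) with ``len(edges) + 1`` half-open intervals
    [edge_k, edge_{k+1}), values below the first edge falling in the lowest
    band.  Default labels mirror the published table headers.
    """

    edges: tuple[float, ...] = (10.0, 100.0, 1000.0)
    labels: tuple[str, ...] = ("<$10", "$10-$100", "$101-$1000", "$1001+")

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.edges) + 1:
            raise ValidationError("need exactly one label per band")
        for lo, hi in zip(self.edges, self.edges[1:]):
            if not lo < hi:
                raise ValidationError("band edges must be strictly ascending")
            if abs(hi / lo - 10.0) > 1e-9:
                raise ValidationError(
                    "each band edge must be 10x the previous (order of"
                    " magnitude bands)"
                )

    @classmethod
    def with_sub_dollar(cls) -> "BandScheme":
        """Variant with the extra under-$1 band of the isoquant figure."""
        return cls(
            edges=(1.0, 10.0, 100.0, 1000.0),
            labels=("<$1", "$1-$10", "$10-$100", "$101-$1000", "$1001+"),
        )

    @property
    def bands(self) -> tuple[Band, ...]:
        bounds = (0.0,) + self.edges + (float("inf"),)
        return tuple(
            Band(lo, hi, label)
            for lo, hi, label in zip(bounds, bounds[1:], self.labels)
        )


def assign_band(acer: float, scheme: Optional[BandScheme] = None) -> Band:
    """Band of an (unrounded) ACER under half-open [lower, upper) intervals.

    Negative ratios are not banded: a cost-saving entry belongs in a
    separate listing, not on the ratio scale.
    """
    scheme = scheme or BandScheme()
    if acer < 0:
        raise ValidationError(
            "negative ACER cannot be banded; list cost-saving entries"
            " separately"
        )
    for band in scheme.bands:
        if acer in band:
            return band
    return scheme.bands[-1]  # +inf guard; unreachable for finite acer


def build_league_table(
    clusters: Sequence[ProgrammeCluster],
    scheme: Optional[BandScheme] = None,
    include_fixed: bool = True,
) -> LeagueTable:
    """Build the platform x band league table from programme clusters.

    Overlaps from coverage ladders / overlapping bundles are eliminated by
    keeping, per exclusivity group on a platform, the member with the
    lowest ACER.  Programme support is still needed for every discrete
    programme delivering on a platform, so each programme's fixed support
    cost is split equally over its surviving scenarios on that platform and
    added to their costs before the ACER is computed.  Entries are sorted
    ascending by (ACER, id) within each band.  Scenarios with zero health
    gain have no defined ratio and are omitted.
    """
    scheme = scheme or BandScheme()
    validate_dataset(clusters)

    by_platform: dict[Platform, list] = {}
    for cluster in clusters:
        for s in cluster.scenarios:
            if s.hly <= 0:
                continue
            by_platform.setdefault(s.platform, []).append((cluster, s))

    entries: dict[Platform, dict[str, tuple[LeagueEntry, ...]]] = {}
    for platform in Platform:
        pairs = by_platform.get(platform)
        if not pairs:
            continue
        # de-duplicate coverage ladders: lowest raw ACER per group survives
        best_in_group: dict[str, tuple] = {}
        survivors = []
        for cluster, s in pairs:
            if s.exclusivity_group is None:
                survivors.append((cluster, s))
                continue
            key = s.exclusivity_group
            raw = s.cost_pv / s.hly
            incumbent = best_in_group.get(key)
            if incumbent is None or (raw, s.id) < incumbent[0]:
                best_in_group[key] = ((raw, s.id), (cluster, s))
        survivors.extend(v[1] for v in best_in_group.values())

        per_programme: dict[str, int] = {}
        for cluster, s in survivors:
            per_programme[cluster.programme] = (
                per_programme.get(cluster.programme, 0) + 1
            )

        banded: dict[str, list[LeagueEntry]] = {}
        for cluster, s in survivors:
            share = (
                cluster.fixed_support_cost / per_programme[cluster.programme]
                if include_fixed
                else 0.0
            )
            ratio = (s.cost_pv + share) / s.hly
            band = assign_band(ratio, scheme)
            banded.setdefault(band.label, []).append(
                LeagueEntry(s.id, s.name, ratio)
            )
        entries[platform] = {
            band.label: tuple(
                sorted(banded[band.label], key=lambda e: (e.acer, e.scenario_id))
            )
            for band in scheme.bands
            if band.label in banded
        }
    return LeagueTable(entries=entries)


def package_summary(
    scenario_ids,
    clusters: Sequence[ProgrammeCluster],
    population: float,
    spec: Optional[DiscountSpec] = None,
    params: Optional[OverlapParams] = None,
    include_fixed: bool = True,
) -> BenefitPackage:
    """Totals and per-capita annual cost of a scenario selection, combined
    under the programme combination rules (additive across programmes)."""
    if population <= 0:
        raise ValidationError("population must be > 0")
    spec = spec or DiscountSpec()
    ids = frozenset(scenario_ids)
    point = evaluate_selection(
        {c.programme: c for c in clusters},
        ids,
        params=params,
        include_fixed=include_fixed,
    )
    return BenefitPackage(
        scenario_ids=ids,
        total_cost=point.cost,
        total_hly=point.hly,
        per_capita_annual_cost=per_capita_annual_cost(point, population, spec),
        region_population=population,
    )


def platform_packages(
    table: LeagueTable,
    clusters: Sequence[ProgrammeCluster],
    population: float,
    spec: Optional[DiscountSpec] = None,
    params: Optional[OverlapParams] = None,
) -> Mapping[Platform, BenefitPackage]:
    """One benefit package per delivery platform, built from the league
    table's (de-duplicated) entries."""
    out = {}
    for platform in table.entries:
        ids = [e.scenario_id for e in table.platform_entries(platform)]
        if ids:
            out[platform] = package_summary(
                ids, clusters, population, spec=spec, params=params
            )
    return out
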