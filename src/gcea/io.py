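"""CSV readers and writers, plus the packaged Eastern sub-Saharan Africa
league-table reference data.

Interchange schemas
-------------------
interventions CSV
    ``id,name,programme,platform,exclusivity_group,cost_pv,hly,
    population_in_need`` with an optional ``fixed_support_cost`` column
    (programme-level present value, repeated on each of the programme's
    rows; defaults to 0 when absent).
combinations CSV
    ``programme,member_ids,cost_pv,hly`` where ``member_ids`` is the
    semicolon-joined, sorted list of scenario ids the joint values apply to.
league-table CSV
    ``platform,band_label,scenario_id,name,acer``.
"""

from __future__ import annotations

import math
from importlib import resources
from typing import Optional, Sequence

import pandas as pd

from .models import (
    InterventionScenario,
    LeagueEntry,
    LeagueTable,
    Platform,
    ProgrammeCluster,
    SchemaError,
    ValidationError,
    validate_dataset,
)

_REQUIRED = [
    "id",
    "name",
    "programme",
    "platform",
    "exclusivity_group",
    "cost_pv",
    "hly",
    "population_in_need",
]

_FIXTURE = "table1_essa.csv"


def _opt(value) -> Optional[str]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    s = str(value).strip()
    return s or None


def load_interventions(
    path,
    combinations_path=None,
) -> list[ProgrammeCluster]:
    """Read an interventions CSV (and optional combinations CSV) into
    programme clusters, preserving row order within each programme for
    deterministic downstream tie-breaking."""
    frame = pd.read_csv(path, dtype={"id": str, "programme": str})
    missing = [c for c in _REQUIRED if c not in frame.columns]
    if missing:
        raise SchemaError(
            f"interventions file is missing column(s): {', '.join(missing)}"
        )

    scenarios_by_programme: dict[str, list[InterventionScenario]] = {}
    fixed_by_programme: dict[str, float] = {}
    order: list[str] = []
    for row_number, row in enumerate(frame.itertuples(index=False), start=1):
        try:
            platform = Platform(str(row.platform))
        except ValueError as err:
            raise ValidationError(
                f"row {row_number}: unknown platform {row.platform!r}"
            ) from err
        pin = _opt(row.population_in_need)
        try:
            scenario = InterventionScenario(
                id=str(row.id),
                name=str(row.name),
                programme=str(row.programme),
                platform=platform,
                cost_pv=float(row.cost_pv),
                hly=float(row.hly),
                exclusivity_group=_opt(row.exclusivity_group),
                population_in_need=float(pin) if pin is not None else None,
            )
        except ValidationError as err:
            raise ValidationError(f"row {row_number}: {err}") from err
        prog = scenario.programme
        if prog not in scenarios_by_programme:
            order.append(prog)
        scenarios_by_programme.setdefault(prog, []).append(scenario)
        if "fixed_support_cost" in frame.columns:
            fixed = getattr(row, "fixed_support_cost")
            if _opt(fixed) is not None:
                fixed_by_programme[prog] = float(fixed)

    combos: dict[str, dict[frozenset, tuple[float, float]]] = {}
    if combinations_path is not None:
        cframe = pd.read_csv(combinations_path, dtype=str)
        cmissing = [
            c
            for c in ("programme", "member_ids", "cost_pv", "hly")
            if c not in cframe.columns
        ]
        if cmissing:
            raise SchemaError(
                f"combinations file is missing column(s): {', '.join(cmissing)}"
            )
        for row in cframe.itertuples(index=False):
            members = frozenset(str(row.member_ids).split(";"))
            combos.setdefault(str(row.programme), {})[members] = (
                float(row.cost_pv),
                float(row.hly),
            )

    clusters = [
        ProgrammeCluster(
            programme=prog,
            scenarios=tuple(scenarios_by_programme[prog]),
            fixed_support_cost=fixed_by_programme.get(prog, 0.0),
            combinations=combos.get(prog, {}),
        )
        for prog in order
    ]
    validate_dataset(clusters)
    return clusters


def write_interventions(
    clusters: Sequence[ProgrammeCluster],
    path,
    combinations_path=None,
) -> None:
    """Write clusters back to the interventions (and optional combinations)
    CSV schema; ``load_interventions`` on the output reproduces the input."""
    rows = []
    for cluster in clusters:
        for s in cluster.scenarios:
            rows.append(
                {
                    "id": s.id,
                    "name": s.name,
                    "programme": s.programme,
                    "platform": s.platform.value,
                    "exclusivity_group": s.exclusivity_group,
                    "cost_pv": s.cost_pv,
                    "hly": s.hly,
                    "population_in_need": s.population_in_need,
                    "fixed_support_cost": cluster.fixed_support_cost,
                }
            )
    pd.DataFrame(rows, columns=_REQUIRED + ["fixed_support_cost"]).to_csv(
        path, index=False
    )
    if combinations_path is not None:
        crows = [
            {
                "programme": cluster.programme,
                "member_ids": ";".join(sorted(subset)),
                "cost_pv": cost,
                "hly": hly,
            }
            for cluster in clusters
            for subset, (cost, hly) in cluster.combinations.items()
        ]
        pd.DataFrame(
            crows, columns=["programme", "member_ids", "cost_pv", "hly"]
        ).to_csv(combinations_path, index=False)


def write_league_table(table: LeagueTable, path) -> None:
    """Write a league table as CSV (platform, band_label, scenario_id,
    name, acer), preserving the table's ordering."""
    rows = [
        {
            "platform": platform.value,
            "band_label": label,
            "scenario_id": entry.scenario_id,
            "name": entry.name,
            "acer": entry.acer,
        }
        for platform, label, entry in table.all_entries()
    ]
    pd.DataFrame(
        rows, columns=["platform", "band_label", "scenario_id", "name", "acer"]
    ).to_csv(path, index=False)


def load_league_table(path) -> LeagueTable:
    """Read a league-table CSV, keeping rows under the band they are
    recorded in (``band_source=as_printed`` semantics: reference tables are
    not re-banded on load)."""
    frame = pd.read_csv(path, dtype={"scenario_id": str})
    missing = [
        c
        for c in ("platform", "band_label", "scenario_id", "name", "acer")
        if c not in frame.columns
    ]
    if missing:
        raise SchemaError(
            f"league-table file is missing column(s): {', '.join(missing)}"
        )
    entries: dict[Platform, dict[str, list[LeagueEntry]]] = {}
    for row in frame.itertuples(index=False):
        platform = Platform(str(row.platform))
        entries.setdefault(platform, {}).setdefault(
            str(row.band_label), []
        ).append(LeagueEntry(str(row.scenario_id), str(row.name), float(row.acer)))
    return LeagueTable(
        entries={
            platform: {label: tuple(v) for label, v in bands.items()}
            for platform, bands in entries.items()
        }
    )


def load_table1_fixture() -> LeagueTable:
    """The published Eastern sub-Saharan Africa league table (platform x
    order-of-magnitude band, average cost-effectiveness ratios as printed).

    This is hand-transcribed reference data: ACERs are stored exactly as
    printed (e.g. $0.3) and each row sits in the band the source placed it
    in, which is not re-derived.
    """
    with resources.as_file(
        resources.files("gcea").joinpath("data").joinpath(_FIXTURE)
    ) as p:
        return load_league_table(p)
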