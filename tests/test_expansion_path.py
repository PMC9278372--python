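"""Expansion-path construction: greedy adoption, dominance policies,
coverage upgrades, frontier equivalence and budget truncation."""

import math

import numpy as np
import pytest

from gcea import (
    DiscountSpec,
    EmptyPathError,
    ExclusionReason,
    OverlapParams,
    PathConfig,
    SynthConfig,
    ValidationError,
    apply_budget_constraint,
    build_expansion_path,
    generate,
    oracle_frontier,
    pareto_frontier,
    per_capita_annual_cost,
)

from conftest import make_cluster, make_scenario


def _points(path):
    return np.array([(p.hly, p.cost) for p in path.points])


def _additive_config(seed, n_programmes=3, spp=(1, 3)):
    return SynthConfig(
        n_programmes=n_programmes,
        scenarios_per_programme=spp,
        benefit_overlap=0.0,
        cost_synergy=0.0,
        fixed_support_cost_fraction=0.0,
        seed=seed,
    )


def _small_additive_seeds(count, max_scenarios=12):
    """First `count` seeds whose additive instance is small enough for the
    exhaustive oracle."""
    from gcea import all_scenarios

    seeds, seed = [], 0
    while len(seeds) < count:
        clusters, _ = generate(_additive_config(seed))
        if len(all_scenarios(clusters)) <= max_scenarios:
            seeds.append(seed)
        seed += 1
    return seeds


class TestGreedyConstruction:
    def test_single_scenario_path(self):
        clusters = [make_cluster("a", [make_scenario("x", 100, 10, "a")])]
        path = build_expansion_path(clusters)
        assert len(path.steps) == 1
        step = path.steps[0]
        assert step.icer == 10.0
        assert (step.cum_cost, step.cum_hly) == (100.0, 10.0)
        assert not path.excluded

    def test_no_health_gain_anywhere_raises(self):
        clusters = [make_cluster("a", [make_scenario("x", 10, 0, "a")])]
        with pytest.raises(EmptyPathError):
            build_expansion_path(clusters)

    def test_exclude_policy_bars_dominated_scenario(self, abc_clusters):
        """Under the strict league reading, C (less health, more cost than
        the adopted A) can never enter the package."""
        path = build_expansion_path(
            abc_clusters, PathConfig(dominance="exclude")
        )
        assert [s.scenario_id for s in path.steps] == ["A", "B"]
        # additive package point after B is (300, 25): ICER = 200/15
        assert path.steps[1].icer == pytest.approx(200 / 15)
        exc = path.excluded["C"]
        assert exc.reason is ExclusionReason.STRICTLY_DOMINATED
        assert exc.would_be_icer == pytest.approx(150 / 8)

    def test_label_policy_keeps_dominated_scenario_adoptable(self, abc_clusters):
        """Under the frontier reading, C is dominated at step one but is
        still the best value-for-money addition once A and B are in."""
        path = build_expansion_path(abc_clusters, PathConfig(dominance="label"))
        assert [s.scenario_id for s in path.steps] == ["A", "B", "C"]
        assert [s.icer for s in path.steps] == pytest.approx(
            [10.0, 200 / 15, 150 / 8]
        )
        assert not path.excluded

    def test_icer_ties_broken_by_ascending_id(self):
        clusters = [
            make_cluster("a", [make_scenario("m", 100, 10, "a")]),
            make_cluster("b", [make_scenario("k", 200, 20, "b")]),
        ]
        path = build_expansion_path(clusters)
        assert [s.scenario_id for s in path.steps] == ["k", "m"]

    def test_cost_saving_candidates_adopted_before_ratio_ranking(self):
        # co-implementing y with x saves money (joint cost 90 < 100 + 50)
        # while adding health, so once x is in, the y addition is
        # cost-saving and must be taken before the expensive z even though
        # its (negative) ratio would sort last
        cluster_a = make_cluster(
            "a",
            [make_scenario("x", 100, 10, "a"), make_scenario("y", 50, 2, "a")],
            combinations={frozenset({"x", "y"}): (90.0, 12.0)},
        )
        cluster_b = make_cluster("b", [make_scenario("z", 1000, 1, "b")])
        path = build_expansion_path([cluster_a, cluster_b])
        assert [s.scenario_id for s in path.steps] == ["x", "y", "z"]
        y_step = path.steps[1]
        assert y_step.delta_cost == pytest.approx(-10.0)
        assert y_step.icer == pytest.approx(-5.0)
        # the cost-saving step does not invalidate its predecessor
        assert "x" not in path.excluded

    def test_skipped_lower_rung_marked_superseded(self):
        clusters = [
            make_cluster(
                "a",
                [
                    make_scenario("r1", 10, 1, "a", group="g"),
                    make_scenario("r2", 11, 5, "a", group="g"),
                ],
            )
        ]
        path = build_expansion_path(clusters)
        assert [s.scenario_id for s in path.steps] == ["r2"]
        assert (
            path.excluded["r1"].reason is ExclusionReason.SUPERSEDED_COVERAGE
        )

    def test_upgraded_rung_keeps_its_lower_budget_step(self):
        """A lower coverage rung that was efficient at a smaller budget
        remains a path vertex after the upgrade; the upgrade step records
        what it replaced."""
        clusters = [
            make_cluster(
                "a",
                [
                    make_scenario("r1", 1, 1, "a", group="g"),
                    make_scenario("r3", 11, 3, "a", group="g"),
                ],
            )
        ]
        path = build_expansion_path(clusters)
        assert [s.scenario_id for s in path.steps] == ["r1", "r3"]
        assert path.steps[1].replaces == "r1"
        assert path.steps[1].selection == frozenset({"r3"})
        assert path.steps[1].icer == pytest.approx(10 / 2)


class TestPathInvariants:
    @pytest.mark.parametrize("seed", range(25))
    def test_every_scenario_accounted_for_exactly_once(self, seed):
        clusters, _ = generate(
            SynthConfig(n_programmes=4, scenarios_per_programme=(1, 4), seed=seed)
        )
        config = PathConfig(
            dominance="exclude" if seed % 2 else "label",
            overlap=OverlapParams(0.2, 0.1),
        )
        path = build_expansion_path(clusters, config)
        on_path = {s.scenario_id for s in path.steps}
        excluded = set(path.excluded)
        all_ids = {s.id for c in clusters for s in c.scenarios}
        assert on_path | excluded == all_ids
        assert not on_path & excluded

    @pytest.mark.parametrize("seed", range(25))
    def test_icers_nondecreasing_and_sums_consistent(self, seed):
        clusters, _ = generate(
            SynthConfig(n_programmes=5, scenarios_per_programme=(1, 5), seed=seed)
        )
        path = build_expansion_path(
            clusters, PathConfig(overlap=OverlapParams(0.2, 0.1))
        )
        icers = [s.icer for s in path.steps if s.delta_cost >= 0]
        assert all(b >= a * (1 - 1e-9) - 1e-9 for a, b in zip(icers, icers[1:]))
        cost = hly = 0.0
        for s in path.steps:
            cost += s.delta_cost
            hly += s.delta_hly
            assert s.cum_cost == pytest.approx(cost, rel=1e-9, abs=1e-6)
            assert s.cum_hly == pytest.approx(hly, rel=1e-9, abs=1e-9)
            assert s.delta_hly > 0
            assert s.icer == pytest.approx(
                s.delta_cost / s.delta_hly, rel=1e-12
            )

    @pytest.mark.parametrize("seed", _small_additive_seeds(40))
    def test_path_points_trace_the_brute_force_frontier(self, seed):
        """In the additive limit the greedy path's cumulative points are
        exactly the lower convex hull of every feasible package point."""
        clusters, _ = generate(_additive_config(seed))
        path = build_expansion_path(clusters)
        hull = np.array(
            [(p.hly, p.cost) for p in oracle_frontier(clusters, limit=12)]
        )
        pts = _points(path)
        assert pts.shape == hull.shape
        assert np.allclose(pts, hull, rtol=1e-9, atol=1e-9)

    @pytest.mark.parametrize("seed", _small_additive_seeds(10))
    def test_path_points_are_pareto_efficient(self, seed):
        clusters, _ = generate(_additive_config(seed))
        path = build_expansion_path(clusters)
        frontier = np.array(
            [(p.hly, p.cost) for p in pareto_frontier(clusters, limit=12)]
        )
        for p in path.points:
            matches = np.all(
                np.isclose(frontier, (p.hly, p.cost), rtol=1e-9, atol=1e-9),
                axis=1,
            )
            assert matches.any()

    def test_adding_dominated_scenario_leaves_steps_unchanged(self):
        base = [
            make_cluster("a", [make_scenario("A", 100, 10, "a")]),
            make_cluster("b", [make_scenario("B", 200, 15, "b")]),
        ]
        config = PathConfig(dominance="exclude")
        before = build_expansion_path(base, config)
        extra = base + [
            make_cluster("c", [make_scenario("D", 500, 1, "c")])
        ]
        after = build_expansion_path(extra, config)
        assert [s.scenario_id for s in after.steps] == [
            s.scenario_id for s in before.steps
        ]
        assert set(after.excluded) == {"D"}


class TestBudgetConstraint:
    @pytest.fixture
    def three_step_path(self):
        # additive ACER order a, b, c; cumulative costs 100, 250, 600 so
        # with rate 0 over 100 years and one person the cumulative
        # per-capita annual costs are 1.0, 2.5, 6.0
        clusters = [
            make_cluster("pa", [make_scenario("a", 100, 100, "pa")]),
            make_cluster("pb", [make_scenario("b", 150, 100, "pb")]),
            make_cluster("pc", [make_scenario("c", 350, 100, "pc")]),
        ]
        return build_expansion_path(clusters)

    def _config(self, budget, allow_partial=False):
        return PathConfig(
            budget_per_capita=budget,
            region_population=1.0,
            allow_partial=allow_partial,
        )

    @pytest.fixture
    def zero_rate(self):
        return DiscountSpec(cost_rate=0.0)

    def test_unbounded_budget_returns_full_path(self, three_step_path, zero_rate):
        pkg = apply_budget_constraint(
            three_step_path, self._config(math.inf), zero_rate
        )
        assert pkg.scenario_ids == {"a", "b", "c"}
        assert pkg.total_cost == 600.0

    def test_zero_budget_returns_empty_package(self, three_step_path, zero_rate):
        pkg = apply_budget_constraint(
            three_step_path, self._config(0.0), zero_rate
        )
        assert pkg.scenario_ids == frozenset()
        assert (pkg.total_cost, pkg.total_hly) == (0.0, 0.0)

    def test_prefix_rule_keeps_largest_affordable_prefix(
        self, three_step_path, zero_rate
    ):
        pkg = apply_budget_constraint(
            three_step_path, self._config(3.0), zero_rate
        )
        assert pkg.scenario_ids == {"a", "b"}
        assert pkg.per_capita_annual_cost == pytest.approx(2.5)

    def test_partial_adoption_pro_rates_the_next_step(
        self, three_step_path, zero_rate
    ):
        pkg = apply_budget_constraint(
            three_step_path, self._config(3.0, allow_partial=True), zero_rate
        )
        assert pkg.scenario_ids == {"a", "b", "c"}
        assert pkg.per_capita_annual_cost == pytest.approx(3.0)
        # 50/350 of step c's health comes with the affordable slice
        assert pkg.total_hly == pytest.approx(200 + 100 * (50 / 350))

    def test_budget_monotonicity(self, three_step_path, zero_rate):
        previous = frozenset()
        for budget in (0.0, 0.5, 1.0, 2.0, 2.5, 4.0, 6.0, 10.0):
            pkg = apply_budget_constraint(
                three_step_path, self._config(budget), zero_rate
            )
            assert previous <= pkg.scenario_ids
            previous = pkg.scenario_ids


class TestPerCapitaCost:
    def test_zero_cost_is_zero(self):
        assert per_capita_annual_cost(0.0, 1e6) == 0.0

    def test_zero_rate_divides_by_horizon_and_population(self):
        spec = DiscountSpec(cost_rate=0.0, horizon=100)
        assert per_capita_annual_cost(1000.0, 10.0, spec) == pytest.approx(1.0)

    def test_inverse_construction_recovers_headline_cost(self):
        spec = DiscountSpec()
        population = 6.5e8
        pv = spec.cost_annuity_factor() * 19.80 * population
        assert per_capita_annual_cost(pv, population, spec) == pytest.approx(
            19.80, rel=1e-12
        )

    def test_nonpositive_population_rejected(self):
        with pytest.raises(ValidationError):
            per_capita_annual_cost(100.0, 0.0)

    def test_steady_state_convention_needs_final_year_cost(self):
        with pytest.raises(ValidationError):
            per_capita_annual_cost(100.0, 10.0, convention="steady_state")
        assert (
            per_capita_annual_cost(
                100.0, 10.0, convention="steady_state", final_year_cost=50.0
            )
            == 5.0
        )
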