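# Methods

## The model

`gcea` implements generalized cost-effectiveness analysis (GCEA) for
sector-wide health benefit package design. Every intervention scenario is
evaluated against the same counterfactual, the *null scenario* — no
intervention delivered, located at the origin of the cost-effectiveness
plane — rather than against current practice. This common reference point
is what makes ratios comparable across disease programmes and lets
packages be assembled across the whole sector.

Each scenario carries a present-value cost `C` (2010 international
dollars) and a health gain `E` in healthy life years (HLY, analogous to an
averted DALY), both accumulated over a 100-year horizon. Discounting is
differential: costs at 3% per year, health at 0% (both configurable via
`DiscountSpec`). Payments fall at the start of each year, so the `t = 0`
term is undiscounted; the present value of a stream is
`PV = Σ_t x_t (1+r)^(−t)` and the annuity factor of a level stream is
`(1 − (1+r)^(−H))/r · (1+r)`. The start-of-year convention is a package
choice — either timing convention is defensible, but one must be fixed for
reproducibility.

Two ratios drive everything:

* **ACER** `= C/E`, the average cost-effectiveness ratio of a scenario vs.
  the null. Undefined when `E = 0`; such scenarios cannot be ranked and
  are rejected from ratio-based operations.
* **ICER** `= ΔC/ΔE`, the incremental ratio of moving from one package to
  a larger one. A move with `ΔE ≤ 0` has no meaningful ratio and signals
  dominance instead; a move with `ΔC < 0` and `ΔE > 0` is *cost-saving*
  and is flagged rather than ranked — a negative ratio would sort
  nonsensically among positive ones.

## Combining interventions

Costs and benefits are assumed additive **across** disease programmes.
**Within** a programme, co-implemented scenarios interact: part of the
burden is already averted (benefit overlap) and delivery shares
infrastructure (economies of scale). When a dataset carries explicit joint
values for a subset of a programme's scenarios, those override everything
else. Otherwise a two-parameter sequential model is applied in ascending
ACER order: the k-th scenario contributes `E_k (1−β)^(k−1)` health and
`C_k (1−γ)^(k−1)` cost, with β the benefit-overlap and γ the cost-synergy
proportion (defaults 0: fully additive). No empirical estimates of β and γ
exist for this setting; nonzero values are placeholders for sensitivity
analysis, not calibrated quantities.

Each programme also carries a *fixed support cost* (management,
surveillance, training) treated as a present-value lump that enters once
as soon as any of the programme's scenarios is selected — support is
needed per discrete programme even inside a platform-restricted package.
Treating it as a PV lump rather than an annual flow is a modelling choice;
the two differ only by the annuity factor, which the `DiscountSpec`
exposes.

## The expansion path

The optimized package is built greedily from the null: at each round every
available scenario is evaluated as an addition to the current package
(same-programme additions through the combination rules, additivity across
programmes, a higher coverage rung replacing its lower rung), and the
candidate with the lowest ICER against the current point is adopted.
Cost-saving candidates are adopted before any ratio comparison, largest
health gain first. After each adoption an extended-dominance cleanup
re-splices the path until the ICER sequence is non-decreasing, removing
steps that a later, better move renders inefficient.

Dominance comes in two policies:

* `dominance="label"` (default): scenarios with less health gain at higher
  cost than the adopted candidate are recorded with their would-be ICER
  but remain adoptable later. In the additive limit (β = γ = 0, zero
  fixed costs) this policy provably traces the **lower convex hull** of
  every feasible package point — the efficiency frontier — which is the
  operational meaning of "mathematically optimized" here, and is what the
  brute-force oracle tests enforce.
* `dominance="exclude"`: a scenario dominated at any step is permanently
  barred from the package. This is the stricter league-table reading in
  which dominated interventions can never enter; it produces sparser
  packages but can forgo feasible frontier points, because under
  additivity a scenario dominated early is still a worthwhile late
  addition.

Near-ties (relative ICER difference below `tie_epsilon`, default 1e−9) are
broken by ascending scenario id for bitwise reproducibility. Excluded
scenarios keep their would-be ICER in the output so that near-tie
interventions — which in a real-world package would remain perfectly valid
choices — stay visible to report consumers.

A coverage rung upgraded to a higher rung **keeps its step on the path**:
the lower rung is the efficient package at the lower budget, and removing
its vertex would break frontier equivalence (rungs (1,1) → (11,3) leave
(1,1) on the hull). The upgrade step records what it replaced;
`superseded_coverage` marks ladder members that never made it onto the
path at all. Every input scenario ends up exactly once in steps or in the
excluded map.

Numerical details: ICER-monotonicity violations are detected with a 1e−12
relative tolerance; the cleanup compares each step against its most recent
non-cost-saving predecessor, because a cost-saving step (possible only
with explicit joint data or strong cost synergy) carries no rank
information and must not evict the efficient step before it. Each removal
strictly shortens the path, so the cleanup terminates.

## Budgets and per-capita costs

`apply_budget_constraint` walks the path outward and keeps the largest
prefix whose per-capita annual cost fits the budget; optionally the first
unaffordable step is pro-rated linearly. A larger budget can only enlarge
the package (set inclusion), which the tests assert.

The default per-capita convention is **equivalent annual cost**: the
present-value package cost divided by the annuity factor of the cost rate
over the horizon, then by the regional population — the level yearly
payment with the same present value, a reasonable reading of a "long run"
per-capita price. A `steady_state` alternative divides a supplied
final-year undiscounted cost by the population instead; the two coincide
for level cost streams.

## League tables

League tables deliberately do not exclude dominated interventions; they
band every rankable scenario by order of magnitude of its ACER, stratified
by delivery platform (population, community, first-level clinical — 
jointly primary healthcare — and referral, defined as everything outside
the PHC set). Bands are half-open decades `[edge, 10·edge)` on the
*unrounded* ratio, values below the lowest edge landing in the lowest
band; exactly 10 therefore belongs to the $10–$100 band and exactly 100 to
the $101–$1000 band. The packaged reference table stores each printed row
under the band it was printed in — reference data are not re-banded, even
where the source's own placement of boundary values is inconsistent.

Coverage overlaps are removed per exclusivity group by keeping the member
with the lowest raw ACER. Each programme's fixed support cost is then
split equally over its surviving scenarios on the platform and added to
their costs before the final ACER is computed — an apportionment rule the
source leaves open; equal splitting is the simplest deterministic choice
and keeps the platform total exact. Within bands, entries sort by (ACER,
id), a total and deterministic order.

## The synthetic generator

The generator emulates the *statistical shape* of a sectoral intervention
set: ACERs drawn log-uniformly over `[10^−0.5, 10^4.5]` I$/HLY so every
order-of-magnitude band is populated; lognormal costs (median I$10^8,
σ = 1.5, chosen so a full package against the default population of 10^8
costs tens of I$ per person per year — the scale of real sectoral
packages); health gains derived as cost/ACER; 20 programmes of 2–8 base
interventions; 30% of interventions expanded into 2–3 rung coverage
ladders whose rungs are totals-at-coverage with strictly diminishing
incremental health and escalating incremental ratios; and per-programme
fixed support costs at 10% of mean scenario cost. A truth record carries
every true ACER and the ladder structure for parameter-recovery checks.

What it does **not** emulate: disease natural history, intervention effect
sizes, demographic projection, comorbidity correlations, or empirically
estimated overlap between real interventions. Passing tests therefore
demonstrate the correctness of the ranking, dominance, banding and
costing machinery on data with the right shape — not the validity of any
real-world cost or effect estimate.

The exhaustive oracle enumerates every feasible selection (at most one
member per exclusivity group; capped at 12 scenarios ≈ 4096 subsets),
evaluates each under the same combination rules, and returns the lower
convex hull of the resulting cloud (`oracle_frontier`) or the Pareto set
(`pareto_frontier`). Frontier-equivalence tests run on fully additive
instances, because nonzero fixed support costs make the feasible set
non-convex and the one-scenario-at-a-time path provably cannot trace a
hull that jumps over the fixed-cost cliff; under fixed costs and overlap
the structural invariants (monotone ICERs, complete accounting) are
verified instead, across both dominance policies.

## Problem sizes

The test suite and the acceptance script use 100 additive instances of at
most 12 scenarios for frontier equivalence, 1000 fuzzed instances
(2–6 programmes, overlap, synergy, fixed costs, ladders) for the
structural invariants, and a default-size dataset (~10^2 scenarios; the
band-coverage check uses ~10^4) for parameter recovery — sizes at which
the exhaustive oracle is exact and the whole suite runs in seconds.

## Known limitations

* The greedy path is optimal only in the additive limit; with strong
  non-convexities (fixed costs, explicit joint data) it remains a
  well-defined, monotone, fully-accounted heuristic, matching how the
  method is actually used.
* Equity, financial risk protection and other package-selection criteria
  are out of scope, as is any disease-specific impact modelling.
* β and γ defaults are placeholders; no data in this setting pins them
  down.
* No uncertainty propagation: ratios are point estimates, and no
  probabilistic league tables or acceptability curves are produced.
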