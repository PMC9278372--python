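# gcea — generalized cost-effectiveness analysis for benefit package design

`gcea` is a Python library (with a thin CLI) for sector-wide generalized
cost-effectiveness analysis: the method behind WHO-style "best buys"
league tables and optimized health benefit packages for universal health
coverage planning. It is aimed at health economists and analysts who have
intervention-level cost and health-gain estimates and need to turn them
into rankings, efficiency frontiers and budget-constrained packages.

Every intervention scenario is compared to the same **null scenario**
(zero cost, zero health benefit), so ratios are comparable across disease
programmes. A scenario with present-value cost `C` (2010 international
dollars, costs discounted at 3%/year over 100 years) and health gain `E`
(healthy life years, undiscounted) has

* **ACER** = `C / E` — average cost-effectiveness ratio vs. the null,
* **ICER** = `ΔC / ΔE` — incremental ratio of enlarging a package.

From these the library builds:

* **league tables** — every intervention banded by order of magnitude of
  its ACER (`<$10`, `$10–$100`, …), stratified by delivery platform
  (population, community, first-level clinical, referral), with coverage
  overlaps de-duplicated and programme support costs included;
* **expansion paths** — starting from the null, repeatedly adopt the
  cheapest remaining healthy life year: benefits additive across
  programmes, overlap-adjusted within programmes, higher coverage rungs
  replacing lower ones, dominated options excluded or flagged, extended
  dominance cleaned up so the ICER sequence is non-decreasing. In the
  additive limit the path traces the exact efficiency frontier, which a
  brute-force subset-enumeration oracle verifies;
* **benefit packages** — path prefixes under a per-capita annual budget,
  costed with the equivalent-annual-cost convention (PV ÷ annuity factor
  ÷ population);
* **figures** — the log-log isoquant scatter with constant-ACER
  diagonals, the expansion-path plot, and per-platform package summaries;
* **synthetic data** — a generator reproducing the statistical shape of a
  sectoral intervention set (ACERs spanning >4 orders of magnitude,
  coverage ladders with diminishing returns, programme fixed costs), with
  a truth record for recovery tests.

A transcription of the published Eastern sub-Saharan Africa league table
(98 interventions across the four platforms) ships with the package as
reference data.

## Worked example

```python
from gcea import (PathConfig, SynthConfig, apply_budget_constraint,
                  build_expansion_path, generate)

cfg = SynthConfig(seed=1)          # 20 programmes, ~160 scenarios
clusters, truth = generate(cfg)
path = build_expansion_path(clusters, PathConfig(overlap=cfg.overlap))
print(len(path.steps), path.steps[0].icer, path.steps[-1].icer)
```

Running `python examples/01_expansion_path.py` prints:

```
scenarios evaluated: 161 across 20 programmes
path steps: 151   excluded: 10
first point: prog010-i05a, ACER = I$0.67/HLY
final point: prog002-i03c, ICER = I$246,170.24/HLY
full package: 3,406,877,241 HLYs for I$60,436,194,496 (PV)
```

The first adopted intervention buys a healthy life year for I$0.67; the
last increment costs ~I$246k per HLY — the familiar several-orders-of-
magnitude spread of a sectoral league table. The 10 excluded scenarios
are coverage rungs superseded by higher rungs. Applying budget cut-offs
(`python examples/03_budget_package.py`):

```
budget I$ 1.00/capita/yr ->  14 scenarios,  1,476,195,052 HLYs, actual cost I$0.90/capita/yr
budget I$ 5.00/capita/yr ->  43 scenarios,  3,199,734,994 HLYs, actual cost I$4.16/capita/yr
budget I$25.00/capita/yr -> 103 scenarios,  3,406,877,241 HLYs, actual cost I$18.57/capita/yr
```

Because the path buys the cheapest health first, I$1 per capita per year
already secures ~43% of the attainable health, and I$5 about 94%.

The packaged reference table is one call away:

```python
from gcea import Platform, load_table1_fixture
table = load_table1_fixture()
min(e.acer for e in table.platform_entries(Platform.POPULATION))  # 0.3
```

`examples/02_league_table.py` walks the whole table;
`examples/04_figures.py` renders the three figure types.

The same operations are available from a shell:

```bash
gcea simulate --seed 1 --out interventions.csv
gcea expansion-path --input interventions.csv --out path.csv
gcea league-table --input interventions.csv --out table.csv
gcea plot --kind isoquant --input interventions.csv --out isoquant.svg
```

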