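"""Render the three figure types to ./figures/.

* isoquant: every intervention on log-log (HLY, cost) axes with
  constant-ACER diagonals one order of magnitude apart;
* expansion: cumulative health vs. cumulative cost of the optimized path;
* platform stack: health gain and per-capita cost per delivery platform.
"""

from gcea import (
    PlotSpec,
    SynthConfig,
    all_scenarios,
    build_expansion_path,
    build_league_table,
    generate,
    platform_packages,
    plot_expansion,
    plot_isoquant,
    plot_platform_stack,
)

cfg = SynthConfig(seed=1)
clusters, _ = generate(cfg)

iso = plot_isoquant(
    all_scenarios(clusters), spec=PlotSpec(out="figures/isoquant.svg")
)
path = build_expansion_path(clusters)
exp = plot_expansion(path, PlotSpec(out="figures/expansion.svg"))
table = build_league_table(clusters)
packages = platform_packages(table, clusters, population=cfg.region_population)
stack = plot_platform_stack(packages, PlotSpec(out="figures/platforms.svg"))

for p in (iso, exp, stack):
    print("wrote", p)
print(
    "-> points on one isoquant diagonal share a cost-effectiveness ratio;"
    " the expansion plot's segment slopes are the ICERs and only steepen."
)
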