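# mhnet

Signed correlation networks, consensus community detection, and
sliding-window "dynamic connectome" analysis for panels of daily,
state-level mental-health indicators.

During the COVID-19 pandemic, daily surveys tracked the percentage of
respondents in each US state reporting anxiety, depression, or worry
about their finances. `mhnet` asks how *similar* states were in these
indicators and how that similarity evolved: it builds the full signed
Pearson correlation network over the 50 states + DC, finds stable
clusters of states with shared trends, measures which states were most
likely to move together across all three indicators, and tracks
per-region (or per-party) connectivity through the epidemic waves of
2021. It is aimed at epidemiologists and computational social
scientists working with state-panel surveillance data; a synthetic
generator with planted structure makes every stage testable without the
original (access-restricted) survey export.

## The method

For one indicator, each pair of states (x, y) gets the Pearson weight

    P[x,y] = Σ_t (x_t − x̄)(y_t − ȳ) / √(Σ_t (x_t − x̄)² · Σ_t (y_t − ȳ)²),

with every coefficient kept (no cut-off). The signed network is split
into nonnegative positive/negative layers and partitioned by Leiden
optimization of two-layer modularity (layer weights +1 / −1),
stabilized by iterated consensus clustering: 300 runs, co-assignment
frequency matrix, re-cluster, repeat until binary. Consensus partitions
of the three indicators combine into an **allegiance matrix** — the
probability two states share a community across indicators — which is
clustered the same way.

The **dynamic connectome** slides a 30-day window in 1-day steps and,
per window, records each group's mean within-group correlation and mean
eigenvector centrality (leading eigenvector of |P|, L2-normalized,
nonnegative). The curves are segmented by epidemic wave and the
per-wave minima/maxima tabulated. See `docs/methods.md` for
assumptions, conventions and limitations.

## Worked example

Generate a study-scale synthetic panel (51 states, 315 days from
2021-03-02, planted regional structure), cluster it, and summarize its
dynamic connectome:

```python
from mhnet import (builtin_grouping, generate_panel, correlation_network,
                   split_signed, consensus_cluster, dynamic_connectome,
                   wave_extrema, report, default_waves)
from mhnet.synthetic import default_spec

region = builtin_grouping("region")          # Census four regions, 51 units
spec = default_spec(region.assignment, indicator="feeling_anxious", seed=42)
panel = generate_panel(spec)                 # 51 x 315 daily percentages

res = consensus_cluster(split_signed(correlation_network(panel)),
                        n_runs=300, seed=42)
print(res.partition.n_communities, res.n_iterations, res.converged)
# 4 1 True        <- the four planted regional groups, binary after one cycle

series = dynamic_connectome(panel, region)   # 30-day window, 1-day step
print(series.n_windows)                      # 286
print(report([wave_extrema(series, default_waves())]).head(3).to_string(index=False))
#   group wave  feeling_anxious_min  feeling_anxious_max
# midwest    1             0.465530             0.900467
# midwest    2             0.384965             0.913407
# midwest    3             0.636086             0.856336
```

The consensus partition recovers the four planted groups exactly; the
286 windows are the 315-day range minus the 30-day width plus one; each
report row gives a region's lowest and highest mean within-region
correlation among windows starting inside that wave (here high, because
the panel was planted at snr 0.8).

The same pipeline runs from the shell:

```sh
mhnet simulate --outdir sim --seed 42
mhnet cluster  --panel feeling_anxious sim/panel_feeling_anxious.csv \
               --panel feeling_depressed sim/panel_feeling_depressed.csv \
               --panel worried_finances sim/panel_worried_finances.csv \
               --outdir clust
mhnet connectome --panel feeling_anxious sim/panel_feeling_anxious.csv \
                 --grouping region --grouping party --outdir conn
```

Real survey exports enter as the same long-format CSV
(`date,state,indicator,value`); `mhnet.read_panel` / `fill_gaps`
validate and interpolate short gaps.

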