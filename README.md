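# labaudit

Evolutionary agent-based simulation of research quality under
"publish or perish" selection, with random laboratory audits.

## The problem

When career rewards track publication quantity, labs that cut corners
publish more, attract more students and collaborators, and spawn more
"child" labs that inherit their practices.  In a simulated world of
100 competing labs whose heritable *effort* trades output volume
against false-positive risk, this selection reliably produces a
**competitive spiral**: mean effort collapses to its minimum and the
mean false-positive probability

    α = W / (1 + (1 − W) e),      W = 0.8,  e ∈ [1, 100]

climbs from the conventional 0.05 (at `e = 75`) to its maximum of 0.67
(at `e = 1`).  `labaudit` adds **random audits** to this world: every
`j` cycles one established, never-before-audited lab (≥ 50 papers) is
inspected; labs in the top third of the population's cumulative
false-positive (or mistake) proportions are removed, and the audited
lab, its parent and its children respond by raising their effort.  The
package measures how often audits prevent the spiral, what share of
the literature they touch, what they cost per published paper, and how
many false positives and mistakes they keep out of the literature.

It is intended for anyone exploring audit/inspection policies for
research systems: the full scenario grid, the cost model, and every
model parameter are exposed through a small Python API and a CLI.

See `docs/methods.md` for the model in full.

## Worked example

Run a small audited scenario from Python (five replicates of 100,000
cycles; the published study uses 500 × 800,000):

```python
from labaudit import AuditPolicy, ScenarioConfig, run_scenario

config = ScenarioConfig(
    audit=AuditPolicy(cycles_per_audit=50),   # audit one lab every 50 cycles
    total_cycles=100_000, record_every=10_000,
    n_replicates=5, master_seed=1,
)
summary = run_scenario(config)
print(f"avoid spiral: {summary.pct_avoiding_spiral:.0f}%  "
      f"papers audited: {summary.pct_papers_audited:.2f}%  "
      f"cost/paper: ${summary.cost_per_paper:.0f}  "
      f"FPs per 100 papers: {summary.fp_per_100_papers:.1f}")
```

which prints

```
avoid spiral: 100%  papers audited: 1.92%  cost/paper: $168  FPs per 100 papers: 4.2
```

All five replicates keep their false-positive rate near the healthy
4.5-per-100-papers level, at the price of auditing ~2% of papers for
about $168 per published paper (every audited paper is charged one
auditor-month, $105,000 / 12).  With `AuditPolicy(enabled=False)` the
same worlds drift into the spiral and the cumulative false-positive
rate climbs toward 60 per 100 papers.

The same run from the shell:

```bash
labaudit run --replicates 5 --cycles 100000 --record-every 10000 \
    --seed 1 --out results/demo
labaudit plot --records results/demo/records.csv --out results/demo/alpha.png
labaudit costs --annual-papers 94000 --pct-audited 1.94 --cost-per-paper 169
```

`run` writes `records.csv` (one row per replicate per recorded cycle),
`summary.json`, and a `manifest.json` with the resolved config and all
derived seeds, sufficient to reproduce the outputs exactly.  Scenario
files are flat YAML with the parameter-table names (`eta`, `W`, `e0`,
`j`, `n`, `el_plus`, `en_plus`, `c`, `review_error`, `audits`, ...);
`labaudit grid` runs the 16-scenario sensitivity sweep.

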