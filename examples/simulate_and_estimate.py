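"""Simulate a full MA study and estimate per-category mutation rates.

Builds a synthetic mutation-accumulation experiment at the study design
(9 genotypes from 3 populations, 66 lines, 819 total generations, 62 Mb
callable sites) with known per-category rates, then estimates the
species-wide rates back from the event table with bootstrap CIs.
"""

import numpy as np

from svcmr.events import Category
from svcmr.rates import aggregate, line_rate
from svcmr.simulate import DEFAULT_RATES, SimulationConfig, simulate_experiment

config = SimulationConfig()  # study-scale defaults
metadata, events = simulate_experiment(config, seed=42)
print(f"{len(metadata)} MA lines, {len(events)} events, "
      f"{sum(config.generations_for_line(i) for i in range(config.n_lines))} "
      f"total generations\n")

counts = {}
for e in events:
    counts[(e.line_id, e.category)] = counts.get((e.line_id, e.category), 0) + 1

print(f"{'category':28s} {'true':>6s} {'estimate (95% CI)':>26s}  x1e-10/bp/gen")
for cat in Category:
    per_line = [
        line_rate(counts.get((md.line_id, cat), 0), md.generations,
                  md.callable_sites)
        for md in metadata
    ]
    est = aggregate(per_line, "species", cat.value,
                    n_events=sum(counts.get((md.line_id, cat), 0)
                                 for md in metadata),
                    n_bootstrap=10_000, seed=1)
    print(f"{cat.value:28s} {1e10 * DEFAULT_RATES[cat]:6.2f} "
          f"{1e10 * est.rate:8.2f} ({1e10 * est.ci_low:5.2f}, "
          f"{1e10 * est.ci_high:5.2f})   n_events={est.n_events}")

print("\nEach row: the rate used to generate events, and the rate the")
print("estimator recovers (mean over per-line x/(2gn), CI by resampling")
print("MA lines). The CIs should bracket the truth ~95% of the time.")
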