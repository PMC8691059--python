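"""Test for population effects on mutation rates.

Simulates an experiment where one population's CNV rate is 10x the
others', then runs the inferential layer: Kruskal-Wallis on per-line
rates with a Dunn post hoc, and the exposure-aware binomial LRT with a
parametric-bootstrap p-value.
"""

import numpy as np

from svcmr.events import Category
from svcmr.rates import line_rate
from svcmr.simulate import (
    GenomeConfig,
    PopulationConfig,
    SimulationConfig,
    simulate_experiment,
)
from svcmr.stats import dunn_posthoc, kruskal_wallis, population_effect_binomial

base = {Category.CNV_DUPLICATION: 1e-9}
hot = {Category.CNV_DUPLICATION: 1e-8}
config = SimulationConfig(
    populations=[PopulationConfig("Finland", 3, dict(base)),
                 PopulationConfig("Germany", 3, dict(hot)),
                 PopulationConfig("Israel", 3, dict(base))],
    genome=GenomeConfig(n_contigs=1, contig_length=10_000_000),
)
metadata, events = simulate_experiment(config, seed=3)

counts = {md.line_id: 0 for md in metadata}
for e in events:
    counts[e.line_id] += 1
rates = [line_rate(counts[md.line_id], md.generations, md.callable_sites)
         for md in metadata]
pops = [md.population for md in metadata]
exposures = [2 * md.generations * md.callable_sites for md in metadata]

kw = kruskal_wallis(rates, pops)
print(f"Kruskal-Wallis: chi2={kw.statistic:.2f}, df={kw.df}, "
      f"P={kw.p_value:.4g}")
for pair in dunn_posthoc(rates, pops):
    print(f"  Dunn {pair.group_labels[0]:8s} vs {pair.group_labels[1]:8s} "
          f"z={pair.statistic:+.2f} P_holm={pair.extra['p_holm']:.4g}")

lrt = population_effect_binomial([counts[md.line_id] for md in metadata],
                                 exposures, pops, seed=4, n_bootstrap=999)
print(f"binomial LRT: chi2={lrt.statistic:.2f}, df={lrt.df}, "
      f"bootstrap P={lrt.p_value:.4g} (asymptotic "
      f"P={lrt.extra['asymptotic_p']:.3g})")
print("\nGermany's elevated CNV rate should surface in both tests, with")
print("the Dunn pairs involving Germany carrying the largest |z|.")
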