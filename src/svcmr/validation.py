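"""Self-validation experiments for the pipeline.

Each routine runs a seeded simulation study against a known truth and
returns summary numbers: bootstrap-CI coverage of true rates, calibration
of the gene-overlap resampling null, exactness of the spike/call/evaluate
loop, neutrality of the net-length rate under a symmetric indel process,
and type-I error of the population tests.  They are used by the test
suite and by the reproduction script; problem sizes are chosen so the
whole battery runs in a few minutes on one core.
"""

from __future__ import annotations

import numpy as np

from .evaluate import degrade_calls, match_calls, oracle_caller
from .events import Category, Channel, EventTableRow, SVType, classify
from .overlap import GeneAnnotation, resample_null
from .rates import bootstrap_ci, line_net_rates, line_rate
from .simulate import (
    GeneConfig,
    GenomeConfig,
    PopulationConfig,
    SimulationConfig,
    spike_events,
)
from .stats import kruskal_wallis, population_effect_binomial


def _study_scaled_config(rates: dict[Category, float],
                         contig_length: int = 10_000_000) -> SimulationConfig:
    """The study design (9 genotypes / 3 populations, 66 lines, 819 total
    generations) on a genome scaled down to 10 Mb of callable sites."""
    pops = [
        PopulationConfig("Finland", 3, dict(rates)),
        PopulationConfig("Germany", 3, dict(rates)),
        PopulationConfig("Israel", 3, dict(rates)),
    ]
    return SimulationConfig(
        populations=pops,
        genome=GenomeConfig(n_contigs=1, contig_length=contig_length),
        genes=GeneConfig(count=100, mean_length=1_000),
    )


# ---------------------------------------------------------------------------
# rate recovery / CI coverage


#: per-category truth used in recovery experiments: sized to put ~50
#: expected events per category into the 66-line scaled design
RECOVERY_RATES = {cat: 3e-9 for cat in Category}


def rate_recovery(
    seed: int = 0,
    n_replicates: int = 100,
    n_bootstrap: int = 2_000,
    rates: dict[Category, float] | None = None,
) -> dict[Category, int]:
    """How often the species-wide bootstrap 95% CI covers the true rate.

    Returns, per category, the number of replicates (of ``n_replicates``)
    whose CI contains the known simulation rate.
    """
    from .simulate import simulate_experiment

    rates = rates or RECOVERY_RATES
    config = _study_scaled_config(rates)
    root = np.random.default_rng(seed)
    covered = {cat: 0 for cat in rates}
    for _ in range(n_replicates):
        rep_seed = int(root.integers(0, 2**31 - 1))
        metadata, events = simulate_experiment(config, seed=rep_seed)
        counts = {(md.line_id, cat): 0 for md in metadata for cat in rates}
        for e in events:
            counts[(e.line_id, e.category)] += 1
        rng = np.random.default_rng(rep_seed + 1)
        for cat, true_rate in rates.items():
            per_line = np.array([
                line_rate(counts[(md.line_id, cat)], md.generations,
                          md.callable_sites)
                for md in metadata
            ])
            lo, hi = bootstrap_ci(per_line, n_replicates=n_bootstrap, rng=rng)
            if lo <= true_rate <= hi:
                covered[cat] += 1
    return covered


# ---------------------------------------------------------------------------
# calibration of the gene-overlap resampling null


def null_calibration(
    seed: int = 0,
    n_trials: int = 500,
    n_replicates: int = 1_000,
    n_events: int = 2_000,
    contig_length: int = 1_000_000,
) -> float:
    """Fraction of trials with verdict "within" when the null is true.

    Observed events are themselves placed uniformly, so roughly 90% of
    trials should land inside the 5th-95th percentile band.  Many short
    events are used so the replicate count distribution is wide enough
    for the empirical percentiles to behave near-continuously.
    """
    # 500 genes of 1 kb tiled every 2 kb: genic fraction 0.5
    genes = [
        GeneAnnotation(f"g{i}", "c1", 2_000 * i, 2_000 * i + 1_000)
        for i in range(contig_length // 2_000)
    ]
    contig_lengths = {"c1": contig_length}
    root = np.random.default_rng(seed)
    within = 0
    for _ in range(n_trials):
        trial_seed = int(root.integers(0, 2**31 - 1))
        rng = np.random.default_rng(trial_seed)
        starts = rng.integers(0, contig_length, size=n_events)
        events = [
            classify(EventTableRow("L1", "c1", int(s), int(s) + 1,
                                   SVType.DELETION, 1, Channel.SPLIT_READ))
            for s in starts
        ]
        null = resample_null(events, contig_lengths, genes,
                             n_replicates=n_replicates, rng=rng)
        if null.verdict == "within":
            within += 1
    return within / n_trials


# ---------------------------------------------------------------------------
# spike -> oracle caller -> evaluation loop


_EVENT_MENU = [
    (SVType.DELETION, Channel.SPLIT_READ, 5, 45),
    (SVType.INSERTION, Channel.SPLIT_READ, 1, 45),
    (SVType.DELETION, Channel.SPLIT_READ, 50, 1_500),
    (SVType.TANDEM_DUPLICATION, Channel.SPLIT_READ, 60, 1_500),
    (SVType.CNV_DELETION, Channel.READ_DEPTH, 2_000, 3_500),
    (SVType.CNV_DUPLICATION, Channel.READ_DEPTH, 2_000, 3_500),
]


def random_disjoint_events(
    rng: np.random.Generator,
    contig: str = "c1",
    contig_length: int = 80_000,
    n: int = 12,
    gap: int = 60,
    line: str = "L1",
):
    """Random events of all six flavours with >= ``gap`` unmutated bp
    between consecutive events (the regime the oracle caller requires)."""
    events = []
    cursor = 100
    for _ in range(n):
        sv_type, channel, lo, hi = _EVENT_MENU[int(rng.integers(0, len(_EVENT_MENU)))]
        length = int(rng.integers(lo, hi + 1))
        start = cursor + int(rng.integers(0, 200))
        extent = 0 if sv_type is SVType.INSERTION else length
        if start + extent + gap > contig_length - 100:
            break
        end = start if sv_type is SVType.INSERTION else start + length
        cnc = {SVType.CNV_DUPLICATION: 0.5, SVType.CNV_DELETION: -0.5}.get(sv_type)
        events.append(
            classify(EventTableRow(line, contig, start, end, sv_type, length,
                                   channel, copy_number_change=cnc))
        )
        cursor = start + extent + gap
    return events


def spike_eval_loop(
    seed: int = 0,
    n_configs: int = 100,
    contig_length: int = 80_000,
    events_per_config: int = 12,
) -> dict:
    """Run the full simulate -> spike -> call -> evaluate loop.

    Returns pooled false positives/negatives over all configurations
    (expected: zero of each), and the FNR after dropping 6% of calls.
    """
    root = np.random.default_rng(seed)
    fp = fn = n_truth = n_calls = 0
    all_truth, all_calls = [], []
    for _ in range(n_configs):
        rng = np.random.default_rng(int(root.integers(0, 2**31 - 1)))
        ref = {"c1": rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8),
                                size=contig_length).tobytes().decode()}
        truth_events = random_disjoint_events(
            rng, contig_length=contig_length, n=events_per_config)
        truth = spike_events(ref, truth_events, rng=rng)
        mutated = {"c1": truth.mutated_sequences.get(("L1", "c1"), ref["c1"])}
        calls = oracle_caller(ref, mutated)
        report = match_calls(truth_events, calls)["all"]
        fp += report.false_positives
        fn += report.false_negatives
        n_truth += report.n_truth
        n_calls += report.n_calls
        all_truth.extend(truth_events)
        all_calls.extend(calls)
    degraded = degrade_calls(all_calls, 0.06, rng=root)
    fnr_degraded = match_calls(all_truth, degraded)["all"].fnr
    return {
        "false_positives": fp,
        "false_negatives": fn,
        "n_truth": n_truth,
        "n_calls": n_calls,
        "fdr": fp / n_calls if n_calls else float("nan"),
        "fnr": fn / n_truth if n_truth else float("nan"),
        "fnr_after_dropping_6pct": fnr_degraded,
    }


# ---------------------------------------------------------------------------
# net-length neutrality under a symmetric indel process


def net_rate_neutrality(seed: int = 0) -> dict:
    """Mean net-length rate across 66 lines when insertion and deletion
    rates (and length models) are identical; returns the mean and its
    standard error."""
    from .simulate import simulate_experiment

    config = _study_scaled_config({
        Category.SHORT_INSERTION: 1e-8,
        Category.SHORT_DELETION: 1e-8,
    })
    metadata, events = simulate_experiment(config, seed=seed)
    by_line = {md.line_id: [] for md in metadata}
    for e in events:
        by_line[e.line_id].append(e)
    net = np.array([
        line_net_rates(by_line[md.line_id], md.generations,
                       md.callable_sites).net_length_rate
        for md in metadata
    ])
    return {
        "mean_net_length_rate": float(net.mean()),
        "se": float(net.std(ddof=1) / np.sqrt(net.size)),
        "n_lines": int(net.size),
    }


# ---------------------------------------------------------------------------
# type-I error of the population tests


def type1_kruskal_wallis(seed: int = 0, n_reps: int = 1_000,
                         per_group: int = 22, alpha: float = 0.05) -> float:
    """Rejection rate of the Kruskal-Wallis test under a shared null."""
    rng = np.random.default_rng(seed)
    groups = ["Finland"] * per_group + ["Germany"] * per_group + \
        ["Israel"] * per_group
    rejections = 0
    for _ in range(n_reps):
        values = rng.normal(size=3 * per_group)
        if kruskal_wallis(values, groups).p_value < alpha:
            rejections += 1
    return rejections / n_reps


def type1_population_binomial(seed: int = 0, n_reps: int = 200,
                              n_bootstrap: int = 199,
                              alpha: float = 0.05) -> float:
    """Rejection rate of the binomial LRT bootstrap under equal rates."""
    config = _study_scaled_config({})
    root = np.random.default_rng(seed)
    pops, exposures = [], []
    line_index = 0
    genotype_index = 0
    for pop in config.populations:
        for _ in range(pop.n_genotypes):
            for _ in range(config.lines_for_genotype(genotype_index)):
                g = config.generations_for_line(line_index)
                pops.append(pop.name)
                exposures.append(2 * g * config.genome.total_length)
                line_index += 1
            genotype_index += 1
    exposures = np.array(exposures, dtype=float)
    true_rate = 2e-8  # ~5 expected events per line
    rejections = 0
    for _ in range(n_reps):
        rep_seed = int(root.integers(0, 2**31 - 1))
        rng = np.random.default_rng(rep_seed)
        counts = rng.poisson(true_rate * exposures)
        res = population_effect_binomial(counts, exposures, pops,
                                         rng=rng, n_bootstrap=n_bootstrap)
        if res.p_value <= alpha:
            rejections += 1
    return rejections / n_reps


__all__ = [
    "RECOVERY_RATES",
    "rate_recovery",
    "null_calibration",
    "random_disjoint_events",
    "spike_eval_loop",
    "net_rate_neutrality",
    "type1_kruskal_wallis",
    "type1_population_binomial",
]
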