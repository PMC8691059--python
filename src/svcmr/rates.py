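"""Mutation-rate estimators for mutation-accumulation experiments.

For MA line with ``g`` generations and ``n`` callable sites, the per-bp
per-generation rate of mutation category *i* is

    u_i = x_i / (2 g n)

where ``x_i`` counts the events observed on that line; the factor 2
accounts for the diploid genome.  The length-adjusted rate replaces the
count with the summed event lengths,

    v_i = sum_j l_ij / (2 g n),

and measures base pairs of genome altered per bp per generation.  Summing
v_i over categories with a sign (+ for insertions/duplications, - for
deletions) gives the total-length and net-length rates, the latter
quantifying genome-size drift.  Gene-level rates use the gene count m as
the denominator: w_i = y_i / (2 g m).

Group-level estimates (genotype, population, species) are unweighted means
of per-line rates — lines with zero events are included — with percentile
bootstrap confidence intervals resampling MA lines.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .events import SIGN, SVEvent


class DomainError(ValueError):
    """A rate denominator is invalid (zero generations or callable sites)."""


@dataclass
class RateEstimate:
    """A rate with its grouping level, bootstrap CI, and sample sizes."""

    label: str                 # category or aggregate label
    level: str                 # line | genotype | population | species
    group: str                 # genotype/population name, or "all"
    rate: float                # per bp (or per gene) per generation
    ci_low: float
    ci_high: float
    n_lines: int
    n_events: int


@dataclass
class NetRate:
    """Total and net (signed) length rates for one MA line."""

    line_id: str
    total_length_rate: float
    net_length_rate: float
    net_bp_change: int


def _check_denominator(g: float, n: float) -> None:
    if g <= 0:
        raise DomainError(f"generations must be positive, got {g}")
    if n <= 0:
        raise DomainError(f"callable sites must be positive, got {n}")


def line_rate(x: int, g: int, n: int) -> float:
    """Per-line event rate u = x / (2 g n) per bp per generation."""
    _check_denominator(g, n)
    if x < 0:
        raise DomainError(f"event count must be >= 0, got {x}")
    return x / (2 * g * n)


def line_length_adjusted_rate(lengths: Sequence[float], g: int, n: int) -> float:
    """Per-line length-adjusted rate v = sum(lengths) / (2 g n)."""
    _check_denominator(g, n)
    return sum(lengths) / (2 * g * n)


def line_net_rates(events: Sequence[SVEvent], g: int, n: int,
                   line_id: str = "") -> NetRate:
    """Total-length and signed net-length rates for one MA line."""
    _check_denominator(g, n)
    total = sum(e.length for e in events)
    net = sum(SIGN[e.sv_type] * e.length for e in events)
    denom = 2 * g * n
    return NetRate(
        line_id=line_id or (events[0].line_id if events else ""),
        total_length_rate=total / denom,
        net_length_rate=net / denom,
        net_bp_change=net,
    )


def line_gene_rate(y: int, g: int, m: int) -> float:
    """Per-line gene-overlap rate w = y / (2 g m) per gene per generation."""
    if m <= 0:
        raise DomainError(f"gene count must be positive, got {m}")
    if g <= 0:
        raise DomainError(f"generations must be positive, got {g}")
    return y / (2 * g * m)


def bootstrap_ci(
    values: np.ndarray,
    n_replicates: int = 10_000,
    seed: int | None = 0,
    alpha: float = 0.05,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Percentile bootstrap CI for the mean, resampling lines with replacement."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot bootstrap an empty sample")
    if rng is None:
        rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(n_replicates, values.size))
    means = values[idx].mean(axis=1)
    lo, hi = np.quantile(means, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


def aggregate(
    per_line_rates: Sequence[float],
    level: str,
    label: str,
    group: str = "all",
    n_events: int = 0,
    n_bootstrap: int = 10_000,
    seed: int | None = 0,
    rng: np.random.Generator | None = None,
    pooled: bool = False,
    counts: Sequence[int] | None = None,
    denominators: Sequence[float] | None = None,
) -> RateEstimate:
    """Aggregate per-line rates to a group-level estimate with bootstrap CI.

    The point estimate is the unweighted mean over MA lines, zero-event
    lines included — a line that saw no events still carries information
    about the rate.  ``pooled=True`` instead divides pooled counts by
    pooled denominators (requires ``counts`` and ``denominators``); the CI
    still bootstraps lines.
    """
    values = np.asarray(per_line_rates, dtype=float)
    if values.size == 0:
        raise ValueError(f"empty group for {label}/{group}")
    if pooled:
        if counts is None or denominators is None:
            raise ValueError("pooled aggregation requires counts and denominators")
        point = float(np.sum(counts) / np.sum(denominators))
    else:
        point = float(values.mean())
    lo, hi = bootstrap_ci(values, n_replicates=n_bootstrap, seed=seed, rng=rng)
    return RateEstimate(
        label=label,
        level=level,
        group=group,
        rate=point,
        ci_low=lo,
        ci_high=hi,
        n_lines=int(values.size),
        n_events=int(n_events),
    )


def coefficient_of_variation(rates: Sequence[float]) -> float:
    """CV = sample standard deviation / mean across genotype rates.

    Returns NaN (flagged missing) when the mean is zero: with no events at
    all the spread relative to the mean is undefined.
    """
    arr = np.asarray(rates, dtype=float)
    mean = arr.mean()
    if mean == 0:
        return math.nan
    return float(arr.std(ddof=1) / mean)


def insertion_deletion_ratio(n_ins: int, n_del: int) -> float:
    """Insertion:deletion count ratio, reported to two decimals.

    Returns NaN when no deletions were observed (ratio undefined).
    """
    if n_del < 0 or n_ins < 0:
        raise DomainError("counts must be >= 0")
    if n_del == 0:
        return math.nan
    return round(n_ins / n_del, 2)


__all__ = [
    "DomainError",
    "RateEstimate",
    "NetRate",
    "line_rate",
    "line_length_adjusted_rate",
    "line_net_rates",
    "line_gene_rate",
    "bootstrap_ci",
    "aggregate",
    "coefficient_of_variation",
    "insertion_deletion_ratio",
]
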