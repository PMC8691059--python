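"""Inferential layer: population effects, insertion-vs-deletion tests,
and cross-category rate correlations.

Population effects on count-based rates are tested two ways, mirroring
common practice for MA data: a Kruskal-Wallis rank test on per-line rates
(with a Dunn post hoc), and a binomial regression of per-line event counts
on callable-site exposure with population as the fixed effect.  For the
latter, with one aggregate count per line and a single categorical
covariate, the group-wise binomial MLEs are available in closed form, so
the likelihood-ratio statistic is computed exactly; its null distribution
is calibrated by a seeded parametric bootstrap rather than relying on the
chi-square asymptotics, which are poor for sparse counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps


@dataclass
class TestResult:
    test_name: str
    statistic: float
    df: float | tuple[float, float] | None
    p_value: float
    group_labels: list[str] = field(default_factory=list)
    posthoc: Optional[list["TestResult"]] = None
    degenerate: bool = False
    extra: dict = field(default_factory=dict)


def _groups(values: Sequence[float], groups: Sequence[str]):
    values = np.asarray(values, dtype=float)
    labels = sorted(set(groups))
    groups = np.asarray(groups)
    split = [values[groups == lab] for lab in labels]
    for lab, arr in zip(labels, split):
        if arr.size == 0:
            raise ValueError(f"group {lab!r} has no observations")
    return labels, split


def kruskal_wallis(values: Sequence[float], groups: Sequence[str]) -> TestResult:
    """Kruskal-Wallis rank test with tie correction; df = k - 1.

    All-identical data make the tie correction vanish; this degenerate
    case is flagged and reported as H = 0, p = 1.
    """
    labels, split = _groups(values, groups)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    if np.ptp(np.asarray(values, dtype=float)) == 0:
        return TestResult("kruskal_wallis", 0.0, len(labels) - 1, 1.0,
                          labels, degenerate=True)
    h, p = sps.kruskal(*split)
    return TestResult("kruskal_wallis", float(h), len(labels) - 1, float(p), labels)


def dunn_posthoc(values: Sequence[float], groups: Sequence[str]) -> list[TestResult]:
    """Dunn's pairwise post hoc on mean ranks after a Kruskal-Wallis test.

    z_ab = (Rbar_a - Rbar_b) / sqrt(V (1/n_a + 1/n_b)) where
    V = N(N+1)/12 - sum(t^3 - t)/(12(N-1)) corrects for ties; two-sided
    p-values are Holm-adjusted across the pairs.
    """
    labels, split = _groups(values, groups)
    all_vals = np.concatenate(split)
    n_total = all_vals.size
    ranks = sps.rankdata(all_vals)
    mean_ranks, sizes = [], []
    pos = 0
    for arr in split:
        mean_ranks.append(ranks[pos : pos + arr.size].mean())
        sizes.append(arr.size)
        pos += arr.size
    _, tie_counts = np.unique(all_vals, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    variance = n_total * (n_total + 1) / 12.0 - tie_term / (12.0 * (n_total - 1))
    pairs = [
        (i, j) for i in range(len(labels)) for j in range(i + 1, len(labels))
    ]
    results = []
    raw_p = []
    for i, j in pairs:
        se = math.sqrt(variance * (1 / sizes[i] + 1 / sizes[j]))
        if se == 0:
            z, p = 0.0, 1.0
        else:
            z = (mean_ranks[i] - mean_ranks[j]) / se
            p = 2 * sps.norm.sf(abs(z))
        raw_p.append(p)
        results.append(
            TestResult("dunn", float(z), None, float(p),
                       [labels[i], labels[j]])
        )
    for res, adj in zip(results, holm_adjust(raw_p)):
        res.extra["p_holm"] = adj
    return results


def holm_adjust(p_values: Sequence[float]) -> list[float]:
    """Holm step-down adjustment for multiple comparisons."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    m = p.size
    adjusted = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adjusted[idx] = min(1.0, running)
    return adjusted.tolist()


def paired_t(values_a: Sequence[float], values_b: Sequence[float]) -> TestResult:
    """Paired t-test across MA lines; df = n - 1.

    Zero variance of the paired differences (e.g. identical samples) is
    flagged degenerate with t = 0, p = 1.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size != b.size or a.size < 2:
        raise ValueError("paired test needs two equal-length samples, n >= 2")
    diff = a - b
    if np.allclose(diff.std(ddof=1), 0):
        return TestResult("paired_t", 0.0, a.size - 1, 1.0, degenerate=True)
    t, p = sps.ttest_rel(a, b)
    return TestResult("paired_t", float(t), a.size - 1, float(p))


def welch_t(values_a: Sequence[float], values_b: Sequence[float]) -> TestResult:
    """Welch's unequal-variance t-test with Satterthwaite df."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        return TestResult("welch_t", 0.0, a.size + b.size - 2,
                          1.0, degenerate=True)
    t, p = sps.ttest_ind(a, b, equal_var=False)
    va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
    df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
    return TestResult("welch_t", float(t), float(df), float(p))


def rate_correlations(
    per_genotype_rates: np.ndarray, labels: Sequence[str] | None = None
) -> tuple[np.ndarray, list[TestResult]]:
    """Pairwise Pearson correlations among per-genotype category rates.

    ``per_genotype_rates`` is genotypes x categories.  Each off-diagonal
    pair gets a t-test with df = n - 2.  Zero-variance categories give an
    undefined (NaN) correlation, flagged degenerate.
    """
    mat = np.asarray(per_genotype_rates, dtype=float)
    n, k = mat.shape
    if n < 3:
        raise ValueError("need at least 3 genotypes")
    labels = list(labels) if labels is not None else [f"cat{i}" for i in range(k)]
    corr = np.eye(k)
    results: list[TestResult] = []
    for i in range(k):
        for j in range(i + 1, k):
            xi, xj = mat[:, i], mat[:, j]
            if np.ptp(xi) == 0 or np.ptp(xj) == 0:
                corr[i, j] = corr[j, i] = math.nan
                results.append(
                    TestResult("pearson", math.nan, n - 2, math.nan,
                               [labels[i], labels[j]], degenerate=True)
                )
                continue
            r, p = sps.pearsonr(xi, xj)
            corr[i, j] = corr[j, i] = r
            t = r * math.sqrt((n - 2) / max(1 - r**2, 1e-300))
            res = TestResult("pearson", float(r), n - 2, float(p),
                             [labels[i], labels[j]])
            res.extra["t"] = t
            results.append(res)
    raw = [r.p_value for r in results if not r.degenerate]
    adjusted = iter(holm_adjust(raw))
    for r in results:
        if not r.degenerate:
            r.extra["p_holm"] = next(adjusted)
    return corr, results


# ---------------------------------------------------------------------------
# binomial population-effect test


def _binomial_loglik(x: np.ndarray, n: np.ndarray, p: float) -> float:
    # binomial coefficient terms cancel in likelihood ratios
    ll = 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        term1 = np.where(x > 0, x * np.log(p), 0.0)
        term2 = np.where(n - x > 0, (n - x) * np.log1p(-p), 0.0)
    return float(np.sum(term1 + term2))


def binomial_lrt(
    counts: np.ndarray, exposures: np.ndarray, group_idx: np.ndarray, k: int
) -> float:
    """Exact LRT statistic for a binomial GLM with one categorical covariate.

    The MLE under the null is the pooled proportion; under the
    alternative, each group's pooled proportion.  Twice the log-likelihood
    difference is the deviance-based chi-square statistic a GLM fit would
    return.
    """
    p0 = counts.sum() / exposures.sum()
    ll0 = _binomial_loglik(counts, exposures, p0) if p0 > 0 else 0.0
    ll1 = 0.0
    for g in range(k):
        mask = group_idx == g
        xg, ng = counts[mask].sum(), exposures[mask].sum()
        pg = xg / ng
        if 0 < pg < 1:
            ll1 += _binomial_loglik(counts[mask], exposures[mask], pg)
        # pg == 0: saturated contribution is 0 (all-failure likelihood = 1)
    if p0 <= 0:
        return 0.0
    return max(0.0, 2 * (ll1 - ll0))


def population_effect_binomial(
    counts: Sequence[int],
    exposures: Sequence[float],
    populations: Sequence[str],
    genotypes: Sequence[str] | None = None,
    seed: int | None = 0,
    n_bootstrap: int = 999,
    rng: np.random.Generator | None = None,
) -> TestResult:
    """Population effect on per-line event counts via a binomial LRT.

    Counts are modelled as Binomial(exposure, p) with exposure 2gn per
    line and population as the only fixed effect.  The p-value is
    calibrated by a parametric bootstrap under the fitted null (seeded);
    the asymptotic chi-square p-value is reported alongside in ``extra``.
    All-zero counts are a degenerate no-information case (p = 1).
    """
    x = np.asarray(counts, dtype=float)
    n = np.asarray(exposures, dtype=float)
    labels, _ = _groups(x, populations)
    k = len(labels)
    if k < 2:
        raise ValueError("need at least 2 populations")
    group_idx = np.asarray([labels.index(p) for p in populations])
    df = k - 1
    if x.sum() == 0:
        return TestResult("population_effect_binomial", 0.0, df, 1.0,
                          labels, degenerate=True)
    observed = binomial_lrt(x, n, group_idx, k)
    asymptotic_p = float(sps.chi2.sf(observed, df))
    if rng is None:
        rng = np.random.default_rng(seed)
    p0 = x.sum() / n.sum()
    exceed = 0
    for _ in range(n_bootstrap):
        xb = rng.binomial(n.astype(np.int64), p0).astype(float)
        if binomial_lrt(xb, n, group_idx, k) >= observed:
            exceed += 1
    boot_p = (1 + exceed) / (1 + n_bootstrap)
    res = TestResult("population_effect_binomial", float(observed), df,
                     float(boot_p), labels)
    res.extra["asymptotic_p"] = asymptotic_p
    res.extra["pooled_rate"] = float(p0)
    return res


__all__ = [
    "TestResult",
    "kruskal_wallis",
    "dunn_posthoc",
    "holm_adjust",
    "paired_t",
    "welch_t",
    "rate_correlations",
    "binomial_lrt",
    "population_effect_binomial",
]
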