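"""Gene overlap statistics and the resampling null.

Observed statistics: how many events overlap genes, and how many genes are
hit partially versus completely (an event covers > 95% of the gene's
length).  The null asks whether events land in genes more or less often
than chance: every observed event is re-placed uniformly on its original
contig keeping its original length, the gene-overlapping event count is
recorded per replicate, and the observed count is compared against the
empirical 5th/95th percentiles (nearest-rank; equality with a bound counts
as within).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree

from .events import CATEGORY_FAMILY, Category, SVEvent
from .io import LineMetadataRow
from .rates import RateEstimate, aggregate, line_gene_rate

logger = logging.getLogger(__name__)

COMPLETE_FRACTION = 0.95


@dataclass
class GeneAnnotation:
    """A gene interval, 0-based half-open; strand is ignored throughout."""

    gene_id: str
    contig: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"gene {self.gene_id}: start {self.start} >= end {self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class LineOverlap:
    """Observed gene overlap for one MA line."""

    line_id: str
    n_events_overlapping_genes: int
    genes_partial: int
    genes_complete: int
    # gene counts per category, keyed (category, "partial"|"complete")
    per_category: dict = field(default_factory=dict)


@dataclass
class NullDistribution:
    counts: np.ndarray
    percentile_5: int
    percentile_95: int
    observed: int
    verdict: str  # below | within | above


def check_genes_disjoint(
    genes: Sequence[GeneAnnotation], merge: bool = False
) -> list[GeneAnnotation]:
    """Validate that genes do not overlap; optionally merge overlapping ones."""
    out: list[GeneAnnotation] = []
    for g in sorted(genes, key=lambda g: (g.contig, g.start)):
        if out and out[-1].contig == g.contig and g.start < out[-1].end:
            warnings.warn(
                f"genes {out[-1].gene_id} and {g.gene_id} overlap on {g.contig}"
            )
            if merge:
                prev = out.pop()
                g = GeneAnnotation(
                    prev.gene_id, g.contig, prev.start, max(prev.end, g.end)
                )
            else:
                raise ValueError(
                    f"overlapping genes {out[-1].gene_id}/{g.gene_id} on {g.contig} "
                    f"(pass merge=True to merge)"
                )
        out.append(g)
    return out


def _gene_trees(genes: Sequence[GeneAnnotation]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        trees.setdefault(g.contig, IntervalTree()).addi(g.start, g.end, g)
    return trees


def overlap_events_genes(
    events: Sequence[SVEvent],
    genes: Sequence[GeneAnnotation],
    complete_fraction: float = COMPLETE_FRACTION,
) -> dict[str, LineOverlap]:
    """Per-line observed gene-overlap statistics.

    An event overlaps a gene iff their half-open intervals share >= 1 bp;
    the overlap is complete iff the intersection exceeds
    ``complete_fraction`` of the gene's length.  A gene hit by two events
    of the same category on the same line is counted once for that
    category (at its deepest overlap level).  Insertions have zero genomic
    extent and never overlap genes.
    """
    trees = _gene_trees(genes)
    known_contigs = set(trees)
    # (line, category, gene) -> best covered fraction
    best: dict[tuple[str, Category, str], float] = {}
    events_overlapping: dict[str, int] = {}
    for e in events:
        if e.contig not in known_contigs:
            if genes:
                logger.warning(
                    "contig %s absent from gene annotation; events counted as "
                    "non-genic", e.contig,
                )
            continue
        if e.end <= e.start:  # insertion: zero genomic extent
            continue
        hits = trees[e.contig].overlap(e.start, e.end)
        if hits:
            events_overlapping[e.line_id] = events_overlapping.get(e.line_id, 0) + 1
        for iv in hits:
            gene: GeneAnnotation = iv.data
            frac = (min(e.end, gene.end) - max(e.start, gene.start)) / gene.length
            key = (e.line_id, e.category, gene.gene_id)
            best[key] = max(best.get(key, 0.0), frac)
    results: dict[str, LineOverlap] = {}
    lines = {e.line_id for e in events}
    for line in lines:
        per_category: dict[tuple[Category, str], int] = {}
        partial = complete = 0
        for (line_id, cat, _gene), frac in best.items():
            if line_id != line:
                continue
            kind = "complete" if frac > complete_fraction else "partial"
            per_category[(cat, kind)] = per_category.get((cat, kind), 0) + 1
            if kind == "complete":
                complete += 1
            else:
                partial += 1
        results[line] = LineOverlap(
            line_id=line,
            n_events_overlapping_genes=events_overlapping.get(line, 0),
            genes_partial=partial,
            genes_complete=complete,
            per_category=per_category,
        )
    return results


def _nearest_rank(sorted_counts: np.ndarray, q: float) -> int:
    n = sorted_counts.size
    rank = max(1, int(np.ceil(q * n)))
    return int(sorted_counts[rank - 1])


def resample_null(
    observed_events: Sequence[SVEvent],
    contig_lengths: Mapping[str, int],
    genes: Sequence[GeneAnnotation],
    n_replicates: int = 1_000,
    seed: int | None = 0,
    rng: np.random.Generator | None = None,
) -> NullDistribution:
    """Resampling null for the gene-overlapping event count.

    Each replicate redraws every observed event's start uniformly on its
    original contig with its original length (start uniform on
    [0, contig_len - length], so the event always fits) and counts events
    overlapping >= 1 gene.  The verdict compares the observed count to the
    nearest-rank 5th/95th percentiles of the replicate distribution;
    observed equal to a bound counts as within.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)

    # merged, sorted gene intervals per contig for vectorized lookup
    gene_arrays: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for contig in {g.contig for g in genes}:
        ivs = sorted((g.start, g.end) for g in genes if g.contig == contig)
        merged: list[list[int]] = []
        for s, e in ivs:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        starts = np.array([m[0] for m in merged], dtype=np.int64)
        ends = np.array([m[1] for m in merged], dtype=np.int64)
        gene_arrays[contig] = (starts, ends)

    total = np.zeros(n_replicates, dtype=np.int64)
    observed = 0
    # events with the same contig and genomic extent share a placement
    # distribution; batch their replicate draws
    batches: dict[tuple[str, int], int] = {}
    for e in observed_events:
        clen = contig_lengths.get(e.contig)
        if clen is None:
            raise ValueError(f"no contig length for {e.contig}")
        extent = max(e.end - e.start, 1)  # insertions occupy 1 bp for placement
        if extent > clen:
            raise ValueError(
                f"event of {extent} bp longer than contig {e.contig} ({clen} bp)"
            )
        arrays = gene_arrays.get(e.contig)
        if arrays is None:
            continue  # no genes on this contig: never overlaps
        starts_arr, ends_arr = arrays
        # observed overlap (genomic extent; insertions use their point)
        obs_extent_end = e.end if e.end > e.start else e.start + 1
        k = np.searchsorted(ends_arr, e.start, side="right")
        if k < starts_arr.size and starts_arr[k] < obs_extent_end:
            observed += 1
        batches[(e.contig, extent)] = batches.get((e.contig, extent), 0) + 1
    for (contig, extent), n_batch in batches.items():
        starts_arr, ends_arr = gene_arrays[contig]
        clen = contig_lengths[contig]
        s = rng.integers(0, clen - extent + 1, size=(n_replicates, n_batch))
        idx = np.searchsorted(ends_arr, s, side="right")
        hit = np.zeros(s.shape, dtype=bool)
        valid = idx < starts_arr.size
        hit[valid] = starts_arr[idx[valid]] < s[valid] + extent
        total += hit.sum(axis=1)

    counts = np.sort(total)
    p5 = _nearest_rank(counts, 0.05)
    p95 = _nearest_rank(counts, 0.95)
    if observed < p5:
        verdict = "below"
    elif observed > p95:
        verdict = "above"
    else:
        verdict = "within"
    return NullDistribution(
        counts=total, percentile_5=p5, percentile_95=p95,
        observed=observed, verdict=verdict,
    )


def gene_rate_report(
    overlaps: Mapping[str, LineOverlap],
    metadata: Sequence[LineMetadataRow],
    n_bootstrap: int = 10_000,
    seed: int | None = 0,
) -> list[RateEstimate]:
    """Gene deletion/duplication rates per gene per generation.

    Rows per genotype, per population, and species-wide for deletion and
    duplication at CNV sites, each for partial+complete and complete-only
    gene overlap.  Lines with no overlapping genes contribute zeros, so
    the species estimate averages over every MA line in the experiment.
    """
    del_cats = {Category.CNV_DELETION}
    dup_cats = {Category.CNV_DUPLICATION}
    variants = {
        ("deletion", "partial_and_complete"): (del_cats, ("partial", "complete")),
        ("duplication", "partial_and_complete"): (dup_cats, ("partial", "complete")),
        ("deletion", "complete_only"): (del_cats, ("complete",)),
        ("duplication", "complete_only"): (dup_cats, ("complete",)),
    }
    rows: list[RateEstimate] = []
    groupings = [("species", lambda md: "all"),
                 ("population", lambda md: md.population),
                 ("genotype", lambda md: md.genotype)]
    for (sv_label, scope), (cats, kinds) in variants.items():
        per_line = {}
        per_line_y = {}
        for md in metadata:
            ov = overlaps.get(md.line_id)
            y = 0
            if ov is not None:
                y = sum(
                    ov.per_category.get((cat, kind), 0)
                    for cat in cats for kind in kinds
                )
            per_line[md.line_id] = line_gene_rate(y, md.generations, md.gene_count)
            per_line_y[md.line_id] = y
        for level, keyfun in groupings:
            groups = sorted({keyfun(md) for md in metadata})
            for grp in groups:
                members = [md for md in metadata if keyfun(md) == grp]
                rows.append(
                    aggregate(
                        [per_line[md.line_id] for md in members],
                        level=level,
                        label=f"gene_{sv_label}_{scope}",
                        group=grp,
                        n_events=sum(per_line_y[md.line_id] for md in members),
                        n_bootstrap=n_bootstrap,
                        seed=seed,
                    )
                )
    return rows


__all__ = [
    "GeneAnnotation",
    "LineOverlap",
    "NullDistribution",
    "check_genes_disjoint",
    "overlap_events_genes",
    "resample_null",
    "gene_rate_report",
]
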