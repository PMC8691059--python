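"""Tidy rate reports: one RateEstimate row per category, level and group."""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .events import Category, SVEvent, SVType
from .io import LineMetadataRow
from .rates import (
    RateEstimate,
    aggregate,
    line_length_adjusted_rate,
    line_net_rates,
    line_rate,
)


def per_line_tables(
    events: Sequence[SVEvent], metadata: Sequence[LineMetadataRow]
) -> pd.DataFrame:
    """Per-line, per-category counts, length sums and rates (long format)."""
    counts: dict[tuple[str, Category], int] = {}
    length_sums: dict[tuple[str, Category], int] = {}
    for e in events:
        key = (e.line_id, e.category)
        counts[key] = counts.get(key, 0) + 1
        length_sums[key] = length_sums.get(key, 0) + e.length
    rows = []
    for md in metadata:
        for cat in Category:
            x = counts.get((md.line_id, cat), 0)
            total_len = length_sums.get((md.line_id, cat), 0)
            rows.append(
                {
                    "line_id": md.line_id,
                    "genotype": md.genotype,
                    "population": md.population,
                    "category": cat.value,
                    "count": x,
                    "length_sum": total_len,
                    "rate": line_rate(x, md.generations, md.callable_sites),
                    "length_adjusted_rate": line_length_adjusted_rate(
                        [total_len], md.generations, md.callable_sites
                    ),
                }
            )
    return pd.DataFrame(rows)


def rate_report(
    events: Sequence[SVEvent],
    metadata: Sequence[LineMetadataRow],
    n_bootstrap: int = 10_000,
    seed: int | None = 0,
) -> list[RateEstimate]:
    """All-level rate estimates: per category x {genotype, population,
    species}, count-based and length-adjusted, plus total- and net-length
    aggregate rows."""
    table = per_line_tables(events, metadata)
    by_line_events: dict[str, list[SVEvent]] = {md.line_id: [] for md in metadata}
    for e in events:
        if e.line_id in by_line_events:
            by_line_events[e.line_id].append(e)
    md_by_line = {md.line_id: md for md in metadata}

    rows: list[RateEstimate] = []
    groupings = [
        ("species", lambda md: "all"),
        ("population", lambda md: md.population),
        ("genotype", lambda md: md.genotype),
    ]
    for cat in Category:
        sub = table[table["category"] == cat.value].set_index("line_id")
        for level, keyfun in groupings:
            for grp in sorted({keyfun(md) for md in metadata}):
                members = [md.line_id for md in metadata if keyfun(md_by_line[md.line_id]) == grp]
                vals = sub.loc[members]
                rows.append(
                    aggregate(
                        vals["rate"].to_numpy(), level, cat.value, grp,
                        n_events=int(vals["count"].sum()),
                        n_bootstrap=n_bootstrap, seed=seed,
                    )
                )
                rows.append(
                    aggregate(
                        vals["length_adjusted_rate"].to_numpy(), level,
                        f"{cat.value}_length_adjusted", grp,
                        n_events=int(vals["count"].sum()),
                        n_bootstrap=n_bootstrap, seed=seed,
                    )
                )
    # total- and net-length rates across all categories
    net = {
        md.line_id: line_net_rates(
            by_line_events[md.line_id], md.generations, md.callable_sites,
            line_id=md.line_id,
        )
        for md in metadata
    }
    for label, attr in (("total_length", "total_length_rate"),
                        ("net_length", "net_length_rate")):
        for level, keyfun in groupings:
            for grp in sorted({keyfun(md) for md in metadata}):
                members = [md for md in metadata if keyfun(md) == grp]
                vals = np.array([getattr(net[md.line_id], attr) for md in members])
                rows.append(
                    aggregate(
                        vals, level, label, grp,
                        n_events=sum(len(by_line_events[md.line_id]) for md in members),
                        n_bootstrap=n_bootstrap, seed=seed,
                    )
                )
    return rows


def estimates_to_frame(rows: Sequence[RateEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "label": r.label,
                "level": r.level,
                "group": r.group,
                "rate": r.rate,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "n_lines": r.n_lines,
                "n_events": r.n_events,
            }
            for r in rows
        ]
    )


__all__ = ["per_line_tables", "rate_report", "estimates_to_frame"]
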