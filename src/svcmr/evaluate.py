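"""Call-set evaluation against a spiked truth set.

Given events spiked into a reference (the truth) and a call set from any
SV caller, computes false-discovery and false-negative rates per event
family.  A call matches a truth event iff they are in the same family
(insertion / deletion / duplication — the detection channel cannot be
recovered from sequence, so CNV and split-read deletions share a family),
and either both breakpoints agree within a tolerance (short indels) or
the intervals reciprocally overlap above a threshold (long and CNV
events).  Matching is greedy one-to-one by ascending breakpoint distance.

``oracle_caller`` is a diff-based perfect caller: it recovers spiked
events directly by anchored comparison of the reference and mutated
sequences, closing the simulate -> spike -> call -> evaluate loop without
any read simulation or external caller.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .events import CATEGORY_FAMILY, SVEvent


@dataclass
class CallRecord:
    """One structural-variant call, 0-based half-open coordinates.

    ``sv_type`` is the family: insertion, deletion or duplication.  For
    duplications [start, end) is the duplicated source interval.
    """

    contig: str
    start: int
    end: int
    sv_type: str
    length: int


@dataclass
class EvalReport:
    family: str
    n_truth: int
    n_calls: int
    true_positives: int
    false_positives: int
    false_negatives: int
    fdr: float  # FP / (TP + FP); NaN when no calls were made
    fnr: float  # FN / n_truth; NaN when the truth set is empty


def _make_report(family: str, n_truth: int, n_calls: int, tp: int) -> EvalReport:
    fp = n_calls - tp
    fn = n_truth - tp
    return EvalReport(
        family=family,
        n_truth=n_truth,
        n_calls=n_calls,
        true_positives=tp,
        false_positives=fp,
        false_negatives=fn,
        fdr=fp / n_calls if n_calls else math.nan,
        fnr=fn / n_truth if n_truth else math.nan,
    )


def match_calls(
    truth: Sequence[SVEvent],
    calls: Sequence[CallRecord],
    tol: int = 10,
    reciprocal_overlap: float = 0.5,
    long_min: int = 50,
) -> dict[str, EvalReport]:
    """Greedy one-to-one matching of calls to truth events.

    Short truth events (< ``long_min`` bp) match on breakpoints within
    ``tol`` bp; longer ones on reciprocal overlap >= the threshold.  Pairs
    are consumed in order of ascending breakpoint distance, ties broken by
    the leftmost truth event.  Returns a report per family plus "all".
    """
    if tol < 0:
        raise ValueError("tol must be >= 0")
    if not 0 < reciprocal_overlap <= 1:
        raise ValueError("reciprocal_overlap must be in (0, 1]")
    candidates = []
    for ti, t in enumerate(truth):
        t_family = CATEGORY_FAMILY[t.category]
        for ci, c in enumerate(calls):
            if c.contig != t.contig or c.sv_type != t_family:
                continue
            d_start, d_end = abs(c.start - t.start), abs(c.end - t.end)
            if t.length < long_min:
                ok = (d_start <= tol and d_end <= tol
                      and abs(c.length - t.length) <= tol)
            else:
                inter = min(t.end, c.end) - max(t.start, c.start)
                ok = (
                    inter > 0
                    and inter / t.length >= reciprocal_overlap
                    and c.end > c.start
                    and inter / (c.end - c.start) >= reciprocal_overlap
                )
            if ok:
                candidates.append((d_start + d_end, t.start, ti, ci))
    candidates.sort()
    used_t: set[int] = set()
    used_c: set[int] = set()
    matched_t: list[int] = []
    for _dist, _tstart, ti, ci in candidates:
        if ti in used_t or ci in used_c:
            continue
        used_t.add(ti)
        used_c.add(ci)
        matched_t.append(ti)

    families = sorted({CATEGORY_FAMILY[t.category] for t in truth}
                      | {c.sv_type for c in calls})
    reports: dict[str, EvalReport] = {}
    for fam in families:
        n_truth = sum(1 for t in truth if CATEGORY_FAMILY[t.category] == fam)
        n_calls = sum(1 for c in calls if c.sv_type == fam)
        tp = sum(1 for ti in matched_t if CATEGORY_FAMILY[truth[ti].category] == fam)
        reports[fam] = _make_report(fam, n_truth, n_calls, tp)
    reports["all"] = _make_report("all", len(truth), len(calls), len(matched_t))
    return reports


# ---------------------------------------------------------------------------
# diff-based oracle caller


ANCHOR = 50  # bp of exact sequence agreement required to accept a breakpoint


def _common_prefix(a: np.ndarray, b: np.ndarray, i: int, j: int) -> int:
    m = min(a.size - i, b.size - j)
    if m == 0:
        return 0
    neq = np.flatnonzero(a[i : i + m] != b[j : j + m])
    return int(neq[0]) if neq.size else m


def oracle_caller(
    reference: Mapping[str, str],
    mutated: Mapping[str, str],
    max_event: int = 20_000,
    anchor: int = ANCHOR,
) -> list[CallRecord]:
    """Recover spiked events by anchored comparison of two haplotypes.

    Scans each contig left to right; at each divergence point it searches
    for the smallest deletion or insertion whose downstream sequence
    re-anchors (``anchor`` bp of exact agreement, or the full remaining
    suffix when shorter).  An insertion whose content equals the reference
    segment immediately to its left is reported as a duplication of that
    segment.  Correct whenever spiked events are separated by at least one
    unmutated base and the genome is non-repetitive at the anchor scale.
    """
    missing = set(mutated) - set(reference)
    if missing:
        raise ValueError(f"mutated contigs absent from reference: {sorted(missing)}")
    calls: list[CallRecord] = []
    for contig in reference:
        ref_s = reference[contig]
        mut_s = mutated.get(contig, ref_s)
        ref = np.frombuffer(ref_s.encode(), dtype=np.uint8)
        mut = np.frombuffer(mut_s.encode(), dtype=np.uint8)
        i = j = 0
        while True:
            k = _common_prefix(ref, mut, i, j)
            i += k
            j += k
            if i == ref.size and j == mut.size:
                break
            if j == mut.size:  # everything left in ref was deleted
                calls.append(CallRecord(contig, i, ref.size, "deletion",
                                        ref.size - i))
                break
            if i == ref.size:  # trailing insertion
                length = mut.size - j
                calls.append(_classify_insertion(contig, ref_s, mut_s, i, j, length))
                break
            size = _find_edit(ref, mut, i, j, max_event, anchor)
            if size is None:
                raise ValueError(
                    f"{contig}: no deletion/insertion up to {max_event} bp "
                    f"explains the divergence at reference position {i}"
                )
            kind, length = size
            if kind == "deletion":
                calls.append(CallRecord(contig, i, i + length, "deletion", length))
                i += length
            else:
                calls.append(_classify_insertion(contig, ref_s, mut_s, i, j, length))
                j += length
    return calls


def _find_edit(
    ref: np.ndarray, mut: np.ndarray, i: int, j: int, max_event: int, anchor: int
) -> Optional[tuple[str, int]]:
    """Smallest single edit at (i, j) after which sequences re-anchor."""
    limit = min(max_event, max(ref.size - i, mut.size - j))
    for size in range(1, limit + 1):
        # deletion of ref[i : i+size]?  then mut[j:] must continue ref[i+size:]
        rem_r, rem_m = ref.size - i - size, mut.size - j
        if rem_r >= 0:
            n_check = min(anchor, rem_r, rem_m)
            # accept on a full anchor, or on complete terminal suffix equality
            if (n_check == anchor or rem_r == rem_m) and np.array_equal(
                ref[i + size : i + size + n_check], mut[j : j + n_check]
            ):
                return ("deletion", size)
        # insertion of mut[j : j+size]?  then mut[j+size:] continues ref[i:]
        rem_m, rem_r = mut.size - j - size, ref.size - i
        if rem_m >= 0:
            n_check = min(anchor, rem_m, rem_r)
            if (n_check == anchor or rem_m == rem_r) and np.array_equal(
                mut[j + size : j + size + n_check], ref[i : i + n_check]
            ):
                return ("insertion", size)
    return None


DUP_MIN = 50  # tandem duplications are >= 50 bp by definition; a shorter
              # inserted copy of adjacent sequence is reported as an insertion


def _classify_insertion(
    contig: str, ref: str, mut: str, i: int, j: int, length: int
) -> CallRecord:
    inserted = mut[j : j + length]
    if length >= DUP_MIN and i - length >= 0 and ref[i - length : i] == inserted:
        # tandem copy of the segment just left of the breakpoint
        return CallRecord(contig, i - length, i, "duplication", length)
    return CallRecord(contig, i, i, "insertion", length)


def degrade_calls(
    calls: Sequence[CallRecord],
    drop_fraction: float,
    seed: int | None = 0,
    rng: np.random.Generator | None = None,
) -> list[CallRecord]:
    """Randomly drop a fraction of calls (models caller false negatives)."""
    if not 0 <= drop_fraction <= 1:
        raise ValueError("drop_fraction must be in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(seed)
    keep = rng.random(len(calls)) >= drop_fraction
    return [c for c, k in zip(calls, keep) if k]


__all__ = [
    "CallRecord",
    "EvalReport",
    "match_calls",
    "oracle_caller",
    "degrade_calls",
]
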