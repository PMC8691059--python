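"""Gene-overlap statistics and the resampling null."""

import numpy as np
import pytest

from svcmr.events import Category, Channel, EventTableRow, SVType, classify
from svcmr.io import LineMetadataRow
from svcmr.overlap import (
    GeneAnnotation,
    check_genes_disjoint,
    gene_rate_report,
    overlap_events_genes,
    resample_null,
)


def _del(line, contig, start, length):
    return classify(EventTableRow(line, contig, start, start + length,
                                  SVType.DELETION, length, Channel.SPLIT_READ))


def _cnv(line, contig, start, length, sv_type=SVType.CNV_DUPLICATION):
    return classify(EventTableRow(line, contig, start, start + length,
                                  sv_type, length, Channel.READ_DEPTH,
                                  copy_number_change=0.5))


class TestObservedOverlap:
    def test_partial_overlap(self):
        genes = [GeneAnnotation("g1", "c1", 200, 400)]
        res = overlap_events_genes([_del("L1", "c1", 100, 200)], genes)
        assert res["L1"].genes_partial == 1
        assert res["L1"].genes_complete == 0
        assert res["L1"].n_events_overlapping_genes == 1

    def test_event_engulfing_gene_is_complete(self):
        genes = [GeneAnnotation("g1", "c1", 100, 200)]
        res = overlap_events_genes([_del("L1", "c1", 0, 1_000)], genes)
        assert res["L1"].genes_complete == 1
        assert res["L1"].genes_partial == 0

    def test_ninety_seven_point_five_percent_is_complete(self):
        # intersection 195 of a 200 bp gene = 97.5% > 95%
        genes = [GeneAnnotation("g1", "c1", 100, 300)]
        res = overlap_events_genes([_del("L1", "c1", 100, 195)], genes)
        assert res["L1"].genes_complete == 1

    def test_exactly_95_percent_is_partial(self):
        # the threshold is strict: > 95%, not >=
        genes = [GeneAnnotation("g1", "c1", 0, 200)]
        res = overlap_events_genes([_del("L1", "c1", 0, 190)], genes)
        assert res["L1"].genes_partial == 1
        assert res["L1"].genes_complete == 0

    def test_gene_counted_once_per_line_per_category(self):
        genes = [GeneAnnotation("g1", "c1", 0, 10_000)]
        events = [_del("L1", "c1", 100, 50), _del("L1", "c1", 500, 50)]
        res = overlap_events_genes(events, genes)
        assert res["L1"].genes_partial == 1
        assert res["L1"].n_events_overlapping_genes == 2

    def test_unknown_contig_counts_as_non_genic(self):
        genes = [GeneAnnotation("g1", "c1", 0, 100)]
        res = overlap_events_genes([_del("L1", "cX", 0, 50)], genes)
        assert res["L1"].n_events_overlapping_genes == 0

    def test_brute_force_equivalence(self, rng):
        """Interval-overlap counts match an all-pairs scan exactly."""
        genes = []
        pos = 0
        for i in range(500):
            pos += int(rng.integers(50, 400))
            glen = int(rng.integers(100, 2_000))
            genes.append(GeneAnnotation(f"g{i}", f"c{i % 3}", pos, pos + glen))
        events = []
        for i in range(100):
            start = int(rng.integers(0, 300_000))
            length = int(rng.integers(1, 5_000))
            events.append(_del(f"L{i % 5}", f"c{i % 3}", start, length))
        res = overlap_events_genes(events, genes)
        # brute force
        hits = {}
        complete = {}
        for e in events:
            overlapped = False
            for g in genes:
                if g.contig != e.contig:
                    continue
                inter = min(e.end, g.end) - max(e.start, g.start)
                if inter > 0:
                    overlapped = True
                    key = (e.line_id, g.gene_id)
                    frac = inter / (g.end - g.start)
                    complete[key] = max(complete.get(key, 0), frac)
            if overlapped:
                hits[e.line_id] = hits.get(e.line_id, 0) + 1
        for line, lo in res.items():
            assert lo.n_events_overlapping_genes == hits.get(line, 0)
            expected_partial = sum(
                1 for (l, _), f in complete.items() if l == line and f <= 0.95
            )
            expected_complete = sum(
                1 for (l, _), f in complete.items() if l == line and f > 0.95
            )
            assert lo.genes_partial == expected_partial
            assert lo.genes_complete == expected_complete


class TestResampleNull:
    def test_saturated_genes_always_within(self):
        genes = [GeneAnnotation("g1", "c1", 0, 10_000)]
        events = [_del("L1", "c1", i * 100, 50) for i in range(10)]
        null = resample_null(events, {"c1": 10_000}, genes,
                             n_replicates=200, seed=0)
        assert (null.counts == 10).all()
        assert null.observed == 10
        assert null.verdict == "within"

    def test_zero_genes_always_within(self):
        events = [_del("L1", "c1", 100, 50)]
        null = resample_null(events, {"c1": 10_000}, [], n_replicates=200, seed=0)
        assert (null.counts == 0).all()
        assert null.observed == 0
        assert null.verdict == "within"

    def test_binomial_oracle_for_unit_events(self):
        """With genes covering fraction p and events of length 1, replicate
        counts are Binomial(n_events, ~p); the empirical mean must fall
        within 3 SE of n p."""
        clen = 100_000
        genes = [GeneAnnotation(f"g{i}", "c1", i * 1_000, i * 1_000 + 300)
                 for i in range(100)]  # covers 30%
        p = 0.3
        n_events = 50
        events = [_del("L1", "c1", 2 * i, 1) for i in range(n_events)]
        null = resample_null(events, {"c1": clen}, genes,
                             n_replicates=1_000, seed=1)
        expected = n_events * p
        se = np.sqrt(n_events * p * (1 - p) / 1_000)
        assert abs(null.counts.mean() - expected) < 3 * se

    def test_adding_a_gene_never_decreases_counts(self):
        genes = [GeneAnnotation("g1", "c1", 1_000, 2_000)]
        more = genes + [GeneAnnotation("g2", "c1", 5_000, 6_000)]
        events = [_del("L1", "c1", i * 50, 20) for i in range(20)]
        a = resample_null(events, {"c1": 10_000}, genes, n_replicates=500, seed=3)
        b = resample_null(events, {"c1": 10_000}, more, n_replicates=500, seed=3)
        assert (b.counts >= a.counts).all()

    def test_event_longer_than_contig_rejected(self):
        with pytest.raises(ValueError):
            resample_null([_del("L1", "c1", 0, 500)], {"c1": 100}, [],
                          n_replicates=10, seed=0)

    def test_seed_determinism(self):
        genes = [GeneAnnotation("g1", "c1", 0, 5_000)]
        events = [_del("L1", "c1", 100, 50)]
        a = resample_null(events, {"c1": 10_000}, genes, n_replicates=100, seed=7)
        b = resample_null(events, {"c1": 10_000}, genes, n_replicates=100, seed=7)
        assert (a.counts == b.counts).all()


class TestGeneDisjointness:
    def test_overlapping_genes_rejected_without_merge(self):
        genes = [GeneAnnotation("g1", "c1", 0, 100),
                 GeneAnnotation("g2", "c1", 50, 150)]
        with pytest.raises(ValueError):
            with pytest.warns(UserWarning):
                check_genes_disjoint(genes)

    def test_merge_option(self):
        genes = [GeneAnnotation("g1", "c1", 0, 100),
                 GeneAnnotation("g2", "c1", 50, 150)]
        with pytest.warns(UserWarning):
            merged = check_genes_disjoint(genes, merge=True)
        assert len(merged) == 1
        assert (merged[0].start, merged[0].end) == (0, 150)


class TestGeneRateReport:
    def _metadata(self):
        return [
            LineMetadataRow("L1", "GA", "Germany", 10, 1_000_000, 20_000),
            LineMetadataRow("L2", "GA", "Germany", 10, 1_000_000, 20_000),
        ]

    def test_zero_overlaps_zero_rates(self):
        report = gene_rate_report({}, self._metadata(), n_bootstrap=100, seed=0)
        assert all(r.rate == 0 for r in report)

    def test_complete_duplication_rate_arithmetic(self):
        genes = [GeneAnnotation("g1", "c1", 1_000, 2_000),
                 GeneAnnotation("g2", "c1", 3_000, 4_000)]
        events = [_cnv("L1", "c1", 500, 4_000)]  # engulfs both genes
        overlaps = overlap_events_genes(events, genes)
        report = gene_rate_report(overlaps, self._metadata(),
                                  n_bootstrap=100, seed=0)
        row = next(r for r in report
                   if r.label == "gene_duplication_complete_only"
                   and r.level == "genotype")
        # line 1: w = 2 / (2 * 10 * 20000) = 5e-6; line 2: 0; mean 2.5e-6
        assert row.rate == pytest.approx(2.5e-6)

    def test_single_genotype_equals_species(self):
        genes = [GeneAnnotation("g1", "c1", 1_000, 2_000)]
        events = [_cnv("L1", "c1", 500, 4_000)]
        overlaps = overlap_events_genes(events, genes)
        report = gene_rate_report(overlaps, self._metadata(),
                                  n_bootstrap=100, seed=0)
        for label in {"gene_duplication_partial_and_complete"}:
            by_level = {r.level: r for r in report if r.label == label}
            assert by_level["genotype"].rate == by_level["species"].rate
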