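"""Synthetic experiment generator: Poisson counts, spiking, determinism."""

import numpy as np
import pytest

from svcmr.events import Category, Channel, EventTableRow, SVType, classify
from svcmr.io import write_event_table
from svcmr.simulate import (
    ConfigError,
    GeneConfig,
    GenomeConfig,
    PopulationConfig,
    SimulationConfig,
    simulate_experiment,
    simulate_genome,
    spike_events,
)

from conftest import small_config


class TestSimulateExperiment:
    def test_zero_rates_give_no_events_but_full_metadata(self):
        cfg = small_config(rates={cat: 0.0 for cat in Category})
        metadata, events = simulate_experiment(cfg, seed=0)
        assert events == []
        assert len(metadata) == cfg.n_lines

    def test_poisson_mean_matches_closed_form(self):
        """count ~ Poisson(rate * 2 g n): with r=1e-8, g=10, n=10 Mb the
        per-line mean is 2; the empirical mean over 100 lines must fall
        within 3 standard errors of the analytic value."""
        rate = 1e-8
        cfg = SimulationConfig(
            populations=[PopulationConfig(
                "P", 1, {Category.SHORT_DELETION: rate})],
            lines_per_genotype=100,
            generations=10,
            genome=GenomeConfig(n_contigs=1, contig_length=10_000_000),
            genes=GeneConfig(count=10),
        )
        metadata, events = simulate_experiment(cfg, seed=11)
        mean_expected = rate * 2 * 10 * 10_000_000  # = 2
        counts = np.zeros(100)
        index = {md.line_id: i for i, md in enumerate(metadata)}
        for e in events:
            counts[index[e.line_id]] += 1
        se = np.sqrt(mean_expected / 100)
        assert abs(counts.mean() - mean_expected) < 3 * se
        # Poisson: variance should be of the same order as the mean
        assert 0.5 * mean_expected < counts.var() < 2 * mean_expected

    def test_default_design_totals(self):
        """The default design: 9 genotypes from 3 populations, 66 lines,
        819 total generations (mean 12.4)."""
        cfg = SimulationConfig()
        assert cfg.n_genotypes == 9
        assert cfg.n_lines == 66
        total_g = sum(cfg.generations_for_line(i) for i in range(cfg.n_lines))
        assert total_g == 819
        assert round(total_g / cfg.n_lines, 1) == 12.4

    def test_determinism_byte_identical_truth_tables(self, tmp_path):
        cfg = small_config(seed=9)
        out_a, out_b = tmp_path / "a.tsv", tmp_path / "b.tsv"
        for out in (out_a, out_b):
            _, events = simulate_experiment(cfg)
            write_event_table(events, out, seed=9)
        assert out_a.read_bytes() == out_b.read_bytes()

    def test_events_respect_contig_bounds_and_disjointness(self):
        cfg = small_config(rates={cat: 5e-8 for cat in Category})
        _, events = simulate_experiment(cfg, seed=2)
        assert events
        by_line_contig = {}
        for e in events:
            assert 0 <= e.start <= e.end <= cfg.genome.contig_length
            by_line_contig.setdefault((e.line_id, e.contig), []).append(e)
        for evs in by_line_contig.values():
            evs.sort(key=lambda e: e.start)
            for a, b in zip(evs, evs[1:]):
                assert max(a.end, a.start + 1) <= b.start

    def test_cnv_copy_number_semantics(self):
        cfg = small_config(rates={Category.CNV_DELETION: 5e-8,
                                  Category.CNV_DUPLICATION: 5e-8})
        _, events = simulate_experiment(cfg, seed=3)
        dels = [e for e in events if e.category == Category.CNV_DELETION]
        dups = [e for e in events if e.category == Category.CNV_DUPLICATION]
        assert dels and dups
        assert all(e.copy_number_change in (-0.5, -1.0) for e in dels)
        assert all(e.copy_number_change == 0.5 for e in dups)

    def test_excessive_rate_rejected(self):
        cfg = small_config(rates={Category.CNV_DUPLICATION: 1e-4})
        with pytest.raises(ConfigError):
            simulate_experiment(cfg, seed=0)


class TestSimulateGenome:
    def test_genes_disjoint_and_within_bounds(self):
        cfg = small_config(n_contigs=1, contig_length=1_000_000, n_genes=100)
        _, genes = simulate_genome(cfg, seed=4)
        assert len(genes) == 100
        for a, b in zip(genes, genes[1:]):
            if a.contig == b.contig:
                assert a.end <= b.start
        assert all(0 <= g.start < g.end <= 1_000_000 for g in genes)

    def test_gc_one_gives_only_gc_bases(self):
        cfg = small_config(n_contigs=1, contig_length=10_000, n_genes=2)
        cfg.genome.gc = 1.0
        seqs, _ = simulate_genome(cfg, seed=5)
        assert set(seqs["contig1"]) <= {"G", "C"}

    def test_seed_determinism(self):
        cfg = small_config(n_contigs=1, contig_length=50_000, n_genes=10)
        a = simulate_genome(cfg, seed=6)
        b = simulate_genome(cfg, seed=6)
        assert a[0] == b[0] and a[1] == b[1]

    def test_infeasible_gene_packing_rejected(self):
        cfg = small_config(n_contigs=1, contig_length=10_000, n_genes=50)
        with pytest.raises(ConfigError):
            simulate_genome(cfg, seed=0)


def _ev(line, contig, start, sv_type, length):
    end = start if sv_type == SVType.INSERTION else start + length
    channel = (Channel.READ_DEPTH
               if sv_type in (SVType.CNV_DELETION, SVType.CNV_DUPLICATION)
               else Channel.SPLIT_READ)
    return classify(EventTableRow(line, contig, start, end, sv_type, length, channel))


class TestSpikeEvents:
    def test_deletion_shortens_sequence(self, rng):
        ref = {"c1": "".join(rng.choice(list("ACGT"), size=10_000))}
        truth = spike_events(ref, [_ev("L1", "c1", 5_000, SVType.DELETION, 417)],
                             seed=0)
        assert len(truth.mutated_sequences[("L1", "c1")]) == 9_583

    def test_tandem_duplication_inserts_copy_after_end(self, rng):
        ref = {"c1": "".join(rng.choice(list("ACGT"), size=10_000))}
        ev = _ev("L1", "c1", 3_000, SVType.TANDEM_DUPLICATION, 1_697)
        truth = spike_events(ref, [ev], seed=0)
        mut = truth.mutated_sequences[("L1", "c1")]
        assert len(mut) == 10_000 + 1_697
        assert mut[ev.end : ev.end + 1_697] == ref["c1"][ev.start : ev.end]

    def test_empty_event_list_is_identity(self):
        ref = {"c1": "ACGTACGT"}
        truth = spike_events(ref, [], seed=0)
        assert truth.mutated_sequences == {}

    def test_length_conservation_across_many_events(self, rng):
        """Sum of signed length changes equals the sequence-length delta,
        per line and contig."""
        cfg = small_config(rates={cat: 3e-8 for cat in Category},
                           n_contigs=2, contig_length=300_000)
        _, events = simulate_experiment(cfg, seed=7)
        seqs, _ = simulate_genome(cfg, seed=8)
        truth = spike_events(seqs, events, seed=9)
        assert truth.mutated_sequences
        for (line, contig), mut in truth.mutated_sequences.items():
            delta = sum(e.signed_length_change for e in events
                        if e.line_id == line and e.contig == contig)
            assert len(mut) - len(seqs[contig]) == delta

    def test_liftover_composes_under_multiple_events(self):
        ref = {"c1": "AAAACCCCGGGGTTTTAAAACCCCGGGGTTTT"}
        events = [
            _ev("L1", "c1", 4, SVType.DELETION, 4),     # removes CCCC
            _ev("L1", "c1", 12, SVType.DELETION, 4),    # removes TTTT
        ]
        truth = spike_events(ref, events, seed=0)
        mut = truth.mutated_sequences[("L1", "c1")]
        assert mut == "AAAAGGGGAAAACCCCGGGGTTTT"
        # position 16 (second AAAA block) maps back by the cumulative -8
        assert truth.ref_to_mut("L1", "c1", 16) == 8
        assert mut[truth.ref_to_mut("L1", "c1", 16)] == ref["c1"][16]

    def test_overlapping_events_rejected_with_pair(self):
        ref = {"c1": "A" * 1_000}
        events = [_ev("L1", "c1", 100, SVType.DELETION, 50),
                  _ev("L1", "c1", 120, SVType.DELETION, 50)]
        with pytest.raises(ValueError, match="colliding"):
            spike_events(ref, events, seed=0)

    def test_event_beyond_contig_end_rejected(self):
        ref = {"c1": "A" * 100}
        with pytest.raises(ValueError, match="beyond"):
            spike_events(ref, [_ev("L1", "c1", 80, SVType.DELETION, 50)], seed=0)
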