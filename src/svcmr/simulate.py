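"""Synthetic mutation-accumulation experiments with known ground truth.

The generator emulates a *Daphnia magna*-style MA study: genotypes sampled
from a few source populations, each propagated as several MA lines for
~12 generations, with structural mutations arising as a Poisson process at
a constant per-bp per-generation rate per category.  Event counts for
category *i* on a line with g generations and n callable sites are
Poisson(rate_i * 2 * g * n); positions are uniform over the callable
contigs and lengths follow per-category length models.  The same machinery
spikes events into reference contigs to produce mutated sequences plus a
liftover, closing the loop for caller validation.

Default length models (configurable): short indels are geometric on
1..49 bp with mean ~3.7 bp; long deletions/duplications are log-uniform on
50..6,000 bp; CNV events are whole multiples of 1 kb on 2..10 kb,
mirroring the quantized resolution of read-depth calling.  CNV deletions
carry a copy-number change of -0.5 or -1.0 (equal probability);
duplications always +0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import numpy as np

from .events import Category, Channel, SVEvent, SVType, classify, EventTableRow
from .io import LineMetadataRow
from .overlap import GeneAnnotation


class ConfigError(ValueError):
    """The simulation configuration is infeasible."""


#: category -> (sv_type, channel) used when materializing drawn events
CATEGORY_TO_TYPE = {
    Category.SHORT_INSERTION: (SVType.INSERTION, Channel.SPLIT_READ),
    Category.SHORT_DELETION: (SVType.DELETION, Channel.SPLIT_READ),
    Category.LONG_DELETION: (SVType.DELETION, Channel.SPLIT_READ),
    Category.LONG_TANDEM_DUPLICATION: (SVType.TANDEM_DUPLICATION, Channel.SPLIT_READ),
    Category.CNV_DELETION: (SVType.CNV_DELETION, Channel.READ_DEPTH),
    Category.CNV_DUPLICATION: (SVType.CNV_DUPLICATION, Channel.READ_DEPTH),
}

#: species-wide per-category rates (per bp per generation) matching the
#: scale of direct MA estimates in Daphnia; used as generator defaults
DEFAULT_RATES: dict[Category, float] = {
    Category.SHORT_INSERTION: 2.72e-10,
    Category.SHORT_DELETION: 10.68e-10,
    Category.LONG_TANDEM_DUPLICATION: 0.06e-10,
    Category.LONG_DELETION: 0.98e-10,
    Category.CNV_DUPLICATION: 3.48e-10,
    Category.CNV_DELETION: 3.05e-10,
}


def _geometric_truncated(rng: np.random.Generator, size: int, mean: float,
                         lo: int, hi: int) -> np.ndarray:
    draws = rng.geometric(1.0 / mean, size=size)
    while True:
        bad = (draws < lo) | (draws > hi)
        if not bad.any():
            return draws
        draws[bad] = rng.geometric(1.0 / mean, size=int(bad.sum()))


def _log_uniform(rng: np.random.Generator, size: int, lo: int, hi: int) -> np.ndarray:
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size=size)).astype(np.int64)


def default_length_models() -> dict[Category, Callable]:
    """Per-category length samplers: (rng, size) -> int array of bp."""
    short = lambda rng, size: _geometric_truncated(rng, size, 3.7, 1, 49)
    long_ = lambda rng, size: _log_uniform(rng, size, 50, 6000)
    cnv = lambda rng, size: 1000 * rng.integers(2, 11, size=size)
    return {
        Category.SHORT_INSERTION: short,
        Category.SHORT_DELETION: short,
        Category.LONG_DELETION: long_,
        Category.LONG_TANDEM_DUPLICATION: long_,
        Category.CNV_DELETION: cnv,
        Category.CNV_DUPLICATION: cnv,
    }


@dataclass
class PopulationConfig:
    name: str
    n_genotypes: int
    rates: dict[Category, float] = field(default_factory=lambda: dict(DEFAULT_RATES))

    def __post_init__(self) -> None:
        self.rates = {Category(k): float(v) for k, v in self.rates.items()}
        if any(v < 0 for v in self.rates.values()):
            raise ConfigError("rates must be >= 0")


@dataclass
class GenomeConfig:
    n_contigs: int = 10
    contig_length: int = 6_200_000
    gc: float = 0.41

    @property
    def total_length(self) -> int:
        return self.n_contigs * self.contig_length


@dataclass
class GeneConfig:
    count: int = 25_000
    mean_length: int = 1_500
    min_length: int = 200


@dataclass
class SimulationConfig:
    """Full description of a synthetic MA experiment."""

    populations: list[PopulationConfig] = field(
        default_factory=lambda: [
            PopulationConfig("Finland", 3),
            PopulationConfig("Germany", 3),
            PopulationConfig("Israel", 3),
        ]
    )
    lines_per_genotype: int | Sequence[int] = field(
        default_factory=lambda: [8, 7, 7, 8, 7, 7, 8, 7, 7]
    )
    generations: int | Sequence[int] = field(
        default_factory=lambda: [13] * 27 + [12] * 39
    )
    genome: GenomeConfig = field(default_factory=GenomeConfig)
    genes: GeneConfig = field(default_factory=GeneConfig)
    length_models: dict[Category, Callable] = field(
        default_factory=default_length_models
    )
    max_placement_attempts: int = 1_000
    seed: int = 0

    @property
    def n_genotypes(self) -> int:
        return sum(p.n_genotypes for p in self.populations)

    def lines_for_genotype(self, index: int) -> int:
        if isinstance(self.lines_per_genotype, int):
            return self.lines_per_genotype
        return self.lines_per_genotype[index]

    @property
    def n_lines(self) -> int:
        return sum(self.lines_for_genotype(i) for i in range(self.n_genotypes))

    def generations_for_line(self, index: int) -> int:
        if isinstance(self.generations, int):
            return self.generations
        return self.generations[index]

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationConfig":
        """Build a config from a plain (e.g. YAML-loaded) dictionary."""
        kwargs = dict(data)
        if "populations" in kwargs:
            kwargs["populations"] = [
                PopulationConfig(**p) for p in kwargs["populations"]
            ]
        if "genome" in kwargs:
            kwargs["genome"] = GenomeConfig(**kwargs["genome"])
        if "genes" in kwargs:
            kwargs["genes"] = GeneConfig(**kwargs["genes"])
        return cls(**kwargs)


@dataclass
class TruthSet:
    """Events spiked into a reference, plus the mutated sequences.

    ``liftover[(line, contig)]`` is a sorted list of (ref_position,
    cumulative_offset) breakpoints: a reference coordinate p maps to
    p + offset of the last breakpoint at or before p.
    """

    events: list[SVEvent]
    mutated_sequences: dict[tuple[str, str], str]
    liftover: dict[tuple[str, str], list[tuple[int, int]]]

    def ref_to_mut(self, line: str, contig: str, pos: int) -> int:
        breaks = self.liftover.get((line, contig), [])
        offset = 0
        for p, off in breaks:
            if p <= pos:
                offset = off
            else:
                break
        return pos + offset


# ---------------------------------------------------------------------------


def simulate_genome(
    config: SimulationConfig, seed: int | None = None
) -> tuple[dict[str, str], list[GeneAnnotation]]:
    """Random reference contigs plus non-overlapping gene annotations."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    gcfg, genes_cfg = config.genome, config.genes
    if genes_cfg.count * genes_cfg.mean_length > 0.8 * gcfg.total_length:
        raise ConfigError(
            f"cannot pack {genes_cfg.count} genes of mean "
            f"{genes_cfg.mean_length} bp into {gcfg.total_length} bp"
        )
    gc = gcfg.gc
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    alphabet = np.frombuffer(b"AGCT", dtype=np.uint8)
    sequences: dict[str, str] = {}
    for c in range(gcfg.n_contigs):
        draws = rng.choice(alphabet, size=gcfg.contig_length, p=probs)
        sequences[f"contig{c + 1}"] = draws.tobytes().decode("ascii")

    # uniform placement with per-contig rejection until disjoint
    contigs = list(sequences)
    lengths = np.maximum(
        rng.exponential(
            genes_cfg.mean_length - genes_cfg.min_length, size=genes_cfg.count
        ).astype(np.int64)
        + genes_cfg.min_length,
        genes_cfg.min_length,
    )
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in contigs}
    genes: list[GeneAnnotation] = []
    weights = np.full(len(contigs), 1.0 / len(contigs))
    for i, glen in enumerate(lengths):
        for attempt in range(config.max_placement_attempts):
            contig = contigs[rng.choice(len(contigs), p=weights)]
            clen = gcfg.contig_length
            if glen >= clen:
                raise ConfigError(f"gene of {glen} bp exceeds contig length {clen}")
            start = int(rng.integers(0, clen - glen + 1))
            if _disjoint(placed[contig], start, start + int(glen)):
                placed[contig].append((start, start + int(glen)))
                genes.append(
                    GeneAnnotation(f"gene{i + 1}", contig, start, start + int(glen))
                )
                break
        else:
            raise ConfigError(
                f"could not place gene {i + 1} after "
                f"{config.max_placement_attempts} attempts"
            )
    genes.sort(key=lambda g: (g.contig, g.start))
    return sequences, genes


def _disjoint(intervals: list[tuple[int, int]], start: int, end: int) -> bool:
    return all(end <= s or start >= e for s, e in intervals)


def simulate_experiment(
    config: SimulationConfig, seed: int | None = None
) -> tuple[list[LineMetadataRow], list[SVEvent]]:
    """Draw a full synthetic experiment: line metadata plus true events.

    Per line and category, the event count is Poisson with mean
    rate * 2 * g * n where n is the total contig length (all sites
    callable in the synthetic genome).  Events on a line are placed
    disjointly by rejection sampling.  Deterministic under a fixed seed.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n_callable = config.genome.total_length
    contig_lengths = {
        f"contig{c + 1}": config.genome.contig_length
        for c in range(config.genome.n_contigs)
    }

    # sanity: expected mutated bp must stay well below the genome length
    mean_lengths = {
        Category.SHORT_INSERTION: 3.7, Category.SHORT_DELETION: 3.7,
        Category.LONG_DELETION: 1300.0, Category.LONG_TANDEM_DUPLICATION: 1300.0,
        Category.CNV_DELETION: 6000.0, Category.CNV_DUPLICATION: 6000.0,
    }
    g_max = (config.generations if isinstance(config.generations, int)
             else max(config.generations))
    for pop in config.populations:
        expected_bp = sum(
            rate * 2 * g_max * n_callable * mean_lengths[cat]
            for cat, rate in pop.rates.items()
        )
        if expected_bp > 0.1 * n_callable:
            raise ConfigError(
                f"population {pop.name}: expected mutated bp ({expected_bp:.3g}) "
                f"exceeds 10% of genome length; the disjoint-placement model "
                f"breaks at this density"
            )

    metadata: list[LineMetadataRow] = []
    events: list[SVEvent] = []
    genotype_index = 0
    line_index = 0
    contigs = list(contig_lengths)
    clens = np.array([contig_lengths[c] for c in contigs], dtype=np.int64)
    weights = clens / clens.sum()
    for pop in config.populations:
        for _ in range(pop.n_genotypes):
            genotype = f"{pop.name[0]}{genotype_index + 1}"
            for line_no in range(config.lines_for_genotype(genotype_index)):
                g = config.generations_for_line(line_index)
                line_id = f"{genotype}_L{line_no + 1:02d}"
                metadata.append(
                    LineMetadataRow(
                        line_id=line_id,
                        genotype=genotype,
                        population=pop.name,
                        generations=g,
                        callable_sites=n_callable,
                        gene_count=config.genes.count,
                    )
                )
                events.extend(
                    _draw_line_events(
                        rng, config, pop.rates, line_id, g, n_callable,
                        contigs, clens, weights,
                    )
                )
                line_index += 1
            genotype_index += 1
    return metadata, events


def _draw_line_events(
    rng: np.random.Generator,
    config: SimulationConfig,
    rates: Mapping[Category, float],
    line_id: str,
    g: int,
    n_callable: int,
    contigs: list[str],
    clens: np.ndarray,
    weights: np.ndarray,
) -> list[SVEvent]:
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in contigs}
    out: list[SVEvent] = []
    for cat in Category:
        rate = rates.get(cat, 0.0)
        count = int(rng.poisson(rate * 2 * g * n_callable))
        if count == 0:
            continue
        lengths = np.asarray(config.length_models[cat](rng, count), dtype=np.int64)
        sv_type, channel = CATEGORY_TO_TYPE[cat]
        for length in lengths:
            length = int(length)
            extent = 0 if sv_type is SVType.INSERTION else length
            for attempt in range(config.max_placement_attempts):
                ci = int(rng.choice(len(contigs), p=weights))
                contig, clen = contigs[ci], int(clens[ci])
                if extent > clen:
                    raise ConfigError(
                        f"event of {extent} bp exceeds contig length {clen}"
                    )
                start = int(rng.integers(0, clen - extent + 1))
                # insertions occupy one placement slot so edits stay disjoint
                s, e = start, start + max(extent, 1)
                if _disjoint(placed[contig], s, e):
                    placed[contig].append((s, e))
                    break
            else:
                raise ConfigError(
                    f"could not place a {length} bp event on line {line_id} "
                    f"after {config.max_placement_attempts} attempts"
                )
            cnc = None
            if cat is Category.CNV_DUPLICATION:
                cnc = 0.5
            elif cat is Category.CNV_DELETION:
                cnc = -0.5 if rng.random() < 0.5 else -1.0
            out.append(
                classify(
                    EventTableRow(
                        line_id=line_id,
                        contig=contig,
                        start=start,
                        end=start + extent,
                        sv_type=sv_type,
                        length=length,
                        channel=channel,
                        copy_number_change=cnc,
                    )
                )
            )
    return out


# ---------------------------------------------------------------------------
# spiking events into sequence


BASES = "ACGT"


def spike_events(
    reference: Mapping[str, str],
    events: Sequence[SVEvent],
    seed: int | None = 0,
    rng: np.random.Generator | None = None,
) -> TruthSet:
    """Apply events to reference contigs, producing mutated haplotypes.

    Deletions remove [start, end); insertions insert ``length`` random
    bases at ``start``; tandem and CNV duplications insert one extra copy
    of [start, end) immediately after ``end``.  Events sharing a contig
    must be disjoint and are applied right-to-left so reference
    coordinates stay valid.  One mutated haplotype is produced per line.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    mutated: dict[tuple[str, str], str] = {}
    liftover: dict[tuple[str, str], list[tuple[int, int]]] = {}
    by_line_contig: dict[tuple[str, str], list[SVEvent]] = {}
    for e in events:
        if e.contig not in reference:
            raise ValueError(f"event contig {e.contig!r} not in reference")
        clen = len(reference[e.contig])
        if e.end > clen or e.start > clen:
            raise ValueError(
                f"event [{e.start}, {e.end}) beyond end of {e.contig} ({clen} bp)"
            )
        by_line_contig.setdefault((e.line_id, e.contig), []).append(e)

    lines = {e.line_id for e in events}
    for line in sorted(lines):
        for contig in sorted(reference):
            key = (line, contig)
            evs = sorted(by_line_contig.get(key, []), key=lambda e: (e.start, e.end))
            for a, b in zip(evs, evs[1:]):
                if b.start < a.end or (a.start == b.start and a.end == b.end == a.start):
                    raise ValueError(
                        f"colliding events on {line}/{contig}: "
                        f"[{a.start}, {a.end}) and [{b.start}, {b.end})"
                    )
            seq = reference[contig]
            # right-to-left so earlier coordinates are untouched
            for e in reversed(evs):
                if e.sv_type in (SVType.DELETION, SVType.CNV_DELETION):
                    seq = seq[: e.start] + seq[e.end :]
                elif e.sv_type is SVType.INSERTION:
                    ins = "".join(
                        BASES[i] for i in rng.integers(0, 4, size=e.length)
                    )
                    seq = seq[: e.start] + ins + seq[e.start :]
                else:  # tandem or CNV duplication: extra copy after end
                    seq = seq[: e.end] + seq[e.start : e.end] + seq[e.end :]
            mutated[key] = seq
            # liftover breakpoints: cumulative offset after each event
            breaks: list[tuple[int, int]] = []
            offset = 0
            for e in evs:
                offset += e.signed_length_change if e.sv_type is not SVType.INSERTION \
                    else e.length
                anchor = e.end if e.sv_type is not SVType.INSERTION else e.start
                breaks.append((anchor, offset))
            liftover[key] = breaks
    return TruthSet(events=list(events), mutated_sequences=mutated, liftover=liftover)


__all__ = [
    "ConfigError",
    "DEFAULT_RATES",
    "CATEGORY_TO_TYPE",
    "default_length_models",
    "PopulationConfig",
    "GenomeConfig",
    "GeneConfig",
    "SimulationConfig",
    "TruthSet",
    "simulate_genome",
    "simulate_experiment",
    "spike_events",
]
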