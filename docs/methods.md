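# Methods

## The rate model

Structural mutations are assumed to arise as a constant-rate process per
base pair per generation along each MA line. A line observed after `g`
generations with `n` callable sites therefore carries an exposure of
`2 g n` diploid base-generations, and the per-category count rate is the
ratio estimator `u_i = x_i / (2 g n)`. Length-adjusted (`v_i`),
net-length (`Σ c_i v_i`, `c_i = ±1`) and per-gene (`w_i = y_i / (2 g m)`)
rates reuse the same exposure. Key assumptions: callable sites are an
unbiased sampling frame for events of every size class; events are
independent across lines and generations; and diploidy enters only
through the factor 2 (no phasing is modelled anywhere).

Each line uses its own `g` and `n`; denominators are never shared or
harmonized across genotypes. Group estimates (genotype, population,
species) are unweighted means of per-line rates with zero-event lines
included — a line that saw nothing still measured the process. A pooled
estimator (`Σx / Σ2gn`) is available behind a flag for comparison, since
the two differ when generations or callable fractions vary across lines.

## Confidence intervals

CIs are percentile bootstrap over MA lines (default 10,000 replicates,
seeded). The bootstrap was chosen because the per-line rates are highly
skewed mixtures of zeros and small counts; resampling lines reproduces
the zero-truncated lower bounds that rare categories should have
(an all-zero resample gives a lower bound of exactly 0) without any
distributional assumption. Degenerate input (all lines identical)
collapses the CI to a point, by design. Self-validation
(`validation.rate_recovery`) measures empirical coverage on the scaled
study design: with ~50 expected events per category, species-wide 95%
CIs cover the truth in ≈93–96 of 100 replicates.

## Event categories

Six categories partition all events: short insertion / short deletion
(< 50 bp, split-read channel), long deletion / long tandem duplication
(≥ 50 bp, split-read channel), CNV deletion / CNV duplication (≥ 2,000
bp, read-depth channel). The long-deletion and CNV-deletion length
ranges overlap, so **the detection channel, not length, is the category
authority**; the classifier rejects inconsistent combinations (a
read-depth event under 2 kb, a split-read event typed as CNV) rather
than reassigning them. Events are never deduplicated across channels:
a split-read deletion and a read-depth deletion at the same locus would
be counted twice, because the two calling pipelines are treated as
independent evidence streams. Thresholds (49/50/2,000 bp, and the
complete-gene fraction below) are configurable.

CNV copy-number semantics: duplications carry a copy-number change of
+0.5 (one extra copy against a diploid background); deletions carry
−0.5 or −1.0 (heterozygous or homozygous loss).

## Gene overlap and the resampling null

An event overlaps a gene iff their half-open intervals share ≥ 1 bp;
the overlap is *complete* iff the intersection exceeds 95% of the gene
length (strictly greater). A gene hit by several same-category events
on one line counts once, at its deepest overlap. Insertions have zero
genomic extent and never overlap genes. Strand is ignored throughout.

The null re-places every observed event uniformly on its **original
contig** with its **original length** (start uniform on
`[0, contig_len − length]`, so replicates keep the observed event count
and per-contig density), and counts events overlapping ≥ 1 gene per
replicate. Percentiles use the nearest-rank method and an observed
count equal to a bound counts as "within". Because events are placed
independently, randomizing per line or pooled over lines yields the
same distribution for the total count; per-line or per-category
verdicts are obtained by passing the corresponding event subset.

Calibration note: with few, large events the replicate count
distribution is coarse, and ties at the percentile bounds push the
"within" probability above the nominal 90%. The calibration experiment
(`validation.null_calibration`) therefore uses many short events (2,000
events, genic fraction 0.5) so the count distribution is wide
(σ ≈ 22) and the band behaves near-continuously; measured "within"
frequency is ≈0.90–0.92.

## Population tests

- Kruskal–Wallis with tie correction on per-line rates; all-identical
  data are flagged degenerate (H = 0, p = 1) rather than erroring.
- Dunn's post hoc on mean ranks with tie-corrected variance and Holm
  adjustment.
- Paired t (insertions vs deletions across lines, df = n−1) and Welch t
  (lengths, Satterthwaite df); zero-variance inputs flagged degenerate.
- Pearson correlations among per-genotype category rates (t-test,
  df = n−2), raw p-values by default with Holm alongside.
- An exposure-aware binomial test for population effects: per-line
  counts are Binomial(2gn, p) with population the only fixed effect.
  With a single categorical covariate the group MLEs are closed form
  (pooled proportions), so the likelihood-ratio statistic is computed
  exactly; a unit test verifies it equals the deviance difference of
  the corresponding statsmodels GLM fits. The p-value comes from a
  seeded parametric bootstrap under the fitted null (asymptotic
  chi-square p reported alongside), because with one observation per
  line a mixed model's line-level random effect is essentially an
  overdispersion device and the bootstrap LRT is a fully specified
  surrogate. Type-I error measured at α = 0.05 is ≈0.04–0.05 for both
  omnibus tests.

## The synthetic-experiment generator

Defaults encode the emulated study design: 9 genotypes from 3
populations (Finland, Germany, Israel), 66 MA lines (8+7+7 per
population triple), 819 total generations (27 lines at 13, 39 at 12;
mean 12.4), a 62 Mb genome (10 × 6.2 Mb contigs, GC 0.41, all sites
callable), 25,000 genes, and species-wide per-category rates of
{2.72, 10.68, 0.06, 0.98, 3.05, 3.48} × 10⁻¹⁰ per bp per generation
for short insertion / short deletion / long duplication / long deletion
/ CNV deletion / CNV duplication.

Event counts per line and category are Poisson(rate · 2 g n); positions
are uniform over contigs (length-weighted) with rejection sampling until
all edits on a line are disjoint (capped at 1,000 attempts); lengths
follow per-category models chosen to mimic the observed spectra:
truncated geometric on 1–49 bp with mean 3.7 for short indels,
log-uniform on 50–6,000 bp for long events, and whole multiples of 1 kb
on 2–10 kb for CNVs (read-depth calling quantizes CNV lengths at the
window scale). All are configurable; the length models are artifact
choices, not fitted distributions.

Spiking applies events right-to-left per contig (deletions remove
`[start, end)`; insertions add seeded random bases; tandem and CNV
duplications insert one extra copy after `end`) and emits one mutated
haplotype per line plus a breakpoint liftover. What the generator does
**not** emulate: reads and sequencing error, mapping artifacts,
heterozygosity and base substitutions, repeat-mediated mutation
hotspots, and overlapping/nested events. Passing tests therefore
demonstrate correctness of the estimators and evaluators on the assumed
process, not robustness to real calling noise.

## Caller evaluation

A call matches a truth event iff they share an event *family*
(insertion / deletion / duplication — the detection channel cannot be
recovered from sequence alone, so split-read and read-depth deletions
share a family) and either both breakpoints agree within a tolerance
(default 10 bp; short events) or the intervals reciprocally overlap
(default ≥ 0.5; events ≥ 50 bp). Matching is greedy one-to-one by
ascending total breakpoint distance, ties to the leftmost truth event.
Both knobs are exposed; published FNRs from read-level pipelines depend
on their own matching criteria and are not comparable directly.

The oracle caller recovers spiked events by anchored sequence
comparison: scan to the first divergence, then find the smallest single
deletion or insertion after which the sequences re-align over a 50 bp
anchor (or the full remaining suffix at contig ends). An inserted
segment ≥ 50 bp that equals the sequence immediately to its left is
reported as a tandem duplication; shorter coincidental copies stay
insertions, since duplications are ≥ 50 bp by definition (a 1 bp
insertion that happens to duplicate its left neighbour is genuinely
indistinguishable from a 1 bp duplication). The oracle is exact when
events are separated by ≥ 1 unmutated bp and the genome is
non-repetitive at the anchor scale; the end-to-end loop
(simulate → spike → call → evaluate) yields FDR = FNR = 0 over 100
seeded configurations.

## Numerical and design choices

- Coordinates are 0-based half-open everywhere; GFF3 converted on read.
- Overlapping gene annotations are rejected on load unless merged.
- Nearest-rank percentiles; percentile-bound ties count as "within".
- Insertions occupy a 1 bp placement slot during generation so edits
  stay disjoint; two events may abut but never overlap.
- Bootstrap and resampling seeds are explicit arguments; every output
  file header records tool version, config hash and seed.
- Validation problem sizes (66-line design on a 10 Mb genome, 100
  recovery replicates at 2,000 bootstrap draws, 500 calibration trials,
  100 spike configurations, 1,000/200 type-I simulations) keep the full
  battery within a few minutes on one core while leaving every check
  adequately powered.

## Known limitations

- The binomial LRT is a surrogate for a mixed model with line-level
  random effects; genotype-level clustering within populations is not
  modelled and its omnibus statistic is not comparable to a GLMM's.
- The liftover maps coordinates outside deleted intervals exactly, but
  positions inside a deletion have no image and map approximately to
  the deletion's left edge region.
- The oracle caller assumes separated, non-nested events; it is a
  validation instrument for the evaluator, not a general SV caller.
- Rates are conservative lower bounds in real data (caller false
  negatives); nothing in this package corrects for detection power.
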