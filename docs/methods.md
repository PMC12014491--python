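# Methods

## The mapping model

The pipeline targets a dominant mutation segregating in a backcross
(*m*/+ × +/+). Two phenotype-selected bulks are pooled and sequenced;
the per-variant statistic is the signed allelic distance
d = f_MUT − f_WT of pooled alternate-allele frequencies. Under the
backcross model every mutant-bulk individual carries the causal allele
heterozygously and no normal-bulk individual carries it, giving
E[d] = ½ at the causal site; at recombination fraction r the carrier
probabilities are 1 − r (MUT bulk) and r (WT bulk), so
E[d] = (1 − 2r)/2. Map distance converts to r by the Haldane function
r = ½(1 − e^(−2m)) with m = |Δbp| × (cM/Mbp) × 10⁻⁸ Morgans; Haldane
(no interference) is the simplest standard choice and the default map
density is 1 cM/Mbp. The sign of d is retained throughout: shared
polymorphisms and noise scatter around 0 and can go negative, and the
scan's window means are plotted on a signed scale.

## Simulator

The synthetic-data generator (`bsamap.simulate`) emulates the full
study design and is first-class, tested code:

- **Genome** — i.i.d. uniform bases per chromosome (defaults: 3 ×
  10 Mbp). Real genomes have repeats, GC structure and gaps; none of
  that matters to the allele-frequency arithmetic being tested, but it
  does mean the simulator says nothing about alignment/calling
  artifacts in repetitive regions.
- **Gene models** — non-overlapping multi-exon genes on both strands
  (default 40), with UTRs and a spliced CDS rewritten into the genome
  so it begins ATG, ends at a stop, has length divisible by 3 and no
  internal stop. This guarantees the translation oracle used to verify
  the effect classifier is well defined.
- **EMS spectrum** — variants are placed uniformly; a configurable
  fraction (default 0.99, canonical EMS chemistry) are G→A or C→T at
  G/C reference sites. Exactly one variant is designated causal: an
  EMS transition inside a CDS chosen to be protein-altering (missense
  preferred, stop-gain otherwise), mirroring the class of lesion such
  screens recover. A configurable subset of non-causal variants
  (default 10%) is also emitted to a panel VCF, mimicking
  polymorphisms shared with other inbred backgrounds.
- **Pooled sequencing** — per variant and bulk, carriers ~
  Binomial(n_bulk, p_carry) with p_carry from the backcross model
  above (½ on non-causal chromosomes), pooled frequency
  f = carriers/(2·n_bulk) (carriers are heterozygous), site depth ~
  Poisson(coverage) and alt reads ~ Binomial(depth, f(1−e) + (1−f)e).
  Defaults n_bulk = 80 and coverage = 10 are the study design; the
  per-read miscall rate e defaults to 0.001 (post-filter short-read
  scale). Carrier states are drawn independently per variant
  conditional on the causal-bearing gamete, which reproduces the
  correct marginal co-segregation with the causal site but not the
  full joint crossover structure between non-causal variants — nothing
  downstream consumes that joint structure. Phenotyping is perfect by
  default; a misphenotyping-rate parameter exists (default 0).
- **Expression** — a configured fraction of genes (default 0.625,
  matching the mapped interval's 5-of-8 expressed genes) receives
  FPKM > 1; values are log-normal with small sample noise, clipped so
  the table and the truth labels agree exactly. The causal gene is
  always placed in the expressed set: a mutant phenotype presupposes
  the causal gene acts in the sampled tissue, and without this the
  dataset would contradict its own ground truth.
- **DAP-seq peaks** — per factor, each gene receives a proximal peak
  (midpoint within 800 bp of the TSS, signed along the strand) with
  probability 0.5 or a decoy (1.5–5 kb away) with probability 0.3.
  Decoys are resampled until they are > 1 kb from *every* TSS, so the
  planted truth coincides exactly with the 1-kb assignment rule.
- **qPCR / decay fixtures** — Ct tables with known per-group relative
  quantities, and decay series S(t) = S₀·2^(−t/τ) with multiplicative
  log-normal noise.

Identical config + seed reproduces byte-identical output files. The
truth record (causal identity and gene, per-variant spectrum/panel
labels and recombination fractions, expressed genes, planted peak
offsets) is sufficient to score every downstream stage without
re-simulation.

## Parameters that matter

| parameter | default | units | rationale |
|---|---|---|---|
| window_size | 500,000 | bp | scan resolution; windows tile [kW, (k+1)W) 0-based |
| min_depth | 4 | reads/bulk | frequencies from fewer reads are flagged and excluded from windows; unstated upstream, chosen as a minimal floor at 10× |
| threshold | 0.25 | distance | interval detection: half the theoretical causal signal (0.5) |
| min_variants | 3 | count | a window must have enough variants for its mean to be meaningful |
| f_mut_min / f_wt_max | 0.25 / 0.05 | frequency | "bulk-specific" predicate; exposed as flags since only the qualitative rule is given upstream |
| fpkm_min | 1 | FPKM | expressed-gene filter, strict inequality |
| max_dist | 1,000 | bp | peak-midpoint-to-TSS rule, inclusive boundary |
| padj / lfc thresholds | 0.05 / 0.5 | — | DE sets, strict inequalities exactly as printed |
| flank | 5,000 | bp | upstream/downstream annotation window (SnpEff convention) |

## Numerical and design choices

- **Coordinates.** Variant positions and gene-model intervals are
  1-based inclusive (VCF/GFF3); peaks and windows are 0-based
  half-open (BED). The conversion happens exactly once, inside the
  window and TSS arithmetic, and both directions are covered by
  boundary tests at position 1.
- **Windows.** Mean and s.e.m. (sample s.d./√n) are over depth-passing
  records only; the s.e.m. is reported as missing for n < 2, the mean
  for n = 0. Interval detection takes the maximal run of consecutive
  qualifying windows with the highest peak mean; ties break toward the
  longer run, then the lower coordinate.
- **Marker refinement.** The refined interval is bounded by the
  nearest markers with recombinants > 0 flanking the longest block of
  zero-recombinant markers; a missing flank leaves that side open.
- **Effect classifier.** SNP-only, deliberately small: CDS codon
  lookup is strand-aware; splice sites are the first/last 2 intronic
  bases; start-loss is checked against the annotated ATG only; when
  several transcripts are hit the most severe consequence wins, ties
  to the lexically lowest gene id. Impact tiers follow the SnpEff
  convention (HIGH: stop gained/lost, start lost, splice site;
  MODERATE: missense; LOW: synonymous; MODIFIER: everything else).
  The classifier is verified against an independent full-CDS
  translate-and-diff oracle rather than against any external tool.
- **Cascade.** Stage order follows the narrative logic of a mapping
  study; order affects intermediate counts only, never the final set
  (tested by permutation). Replicate-level rationale: the expression
  filter acts at gene level and exempts variants with no annotated
  gene. Panel membership is presence/absence of the (chrom, pos, alt)
  site — read-support thresholds in the panel are out of scope.
- **ΔΔCt.** Replicate Ct values are averaged before differencing
  (standard practice; the alternative order is not distinguishable on
  the published description), then
  RQ = 2^−[ΔCt_sample − mean ΔCt_calibrators]. No efficiency
  correction: the pure base-2 form is implemented.
- **Half-life.** Ordinary least squares of log₂(signal) on time;
  τ = −1/slope, exact on noiseless exponentials. A non-negative slope
  is reported as non-decaying (infinite half-life sentinel) rather
  than a negative τ. Log-linear (not nonlinear) fitting is adequate
  for ratio series normalized to t₀ and keeps the estimator exact and
  dependency-free.
- **Problem sizes.** Monte-Carlo checks use 50 full pipeline
  replicates at the 3 × 10-Mbp design and 400 light-weight replicates
  for the closed-form signal checks; these sizes give standard errors
  comfortably below the asserted tolerances while keeping a full
  validation run in the tens of seconds.

## What passing tests do and do not show

The simulator validates the *inference arithmetic*: frequency
estimation, window aggregation, interval logic, consequence
classification and the cascade's set algebra, against exact ground
truth. It does not exercise alignment or variant-calling error modes
(mapping bias, paralog collapse, indel realignment), non-uniform
genomes, structural variants, or imperfect phenotyping beyond a simple
mislabeling rate. Quantitative recovery rates measured on simulated
data therefore bound what the arithmetic can do, not what a real
experiment will achieve.

Two stochastic limits are worth knowing. At 10× Poisson coverage per
bulk, the causal site's estimated MUT frequency falls below the 0.25
bulk-specificity threshold in ~6% of datasets and low-depth exclusion
costs another ~2% — irreducible read-sampling noise at the stated
design, visible in the recovery rates the acceptance script reports.
And on 10-Mbp chromosomes at 1 cM/Mbp the entire causal chromosome
lies within ~10 cM of the lesion, so window-level localization
saturates at chromosome resolution; the marker-refinement step exists
precisely because scan resolution ends there.

## Known limitations

SNPs only (no indel or frameshift consequences); biallelic sites only;
no smoothing or confidence intervals on the scan; no canonical-
transcript selection; backcross designs only (no F2 selfing); the
panel is a site list, not genotype calls.
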