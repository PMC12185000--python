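# Methods

This note documents the models behind `f2map`, the defaults and why they
were chosen, what the synthetic-data generator does and does not emulate,
and the numerical decisions that matter when reproducing results.

## Study design being modelled

A biparental F2 population is derived from two inbred parents (call their
alleles A and B).  Each F2 plant is genotyped by very shallow whole-genome
sequencing (~0.1–0.2× — most marker sites see zero or one read), so
genotypes must be reconstructed from read counts pooled along
chromosomes.  Phenotypes are flowering-time traits (days to flowering,
rosette/cauline leaf numbers) plus, for replicated mutant collections,
vernalization response, relative expression from qPCR and projected
rosette area over time.

## Genome model

`GenomeSpec` holds chromosome sizes, excluded regions and a constant
cM/Mb rate.  The default genome has five chromosomes of 30/20/23/19/27 Mb
at 4 cM/Mb — Arabidopsis-like scale with a realistic genome-wide map
length of 476 cM per gamete — with 2-Mb centromeric and 100-kb telomeric
exclusion regions.  A constant recombination rate is a simplification:
real pericentromeric suppression and hotspots are not modelled, so map
distortion along a chromosome does not appear in synthetic data.

## Variant filtering

Two tiers, mirroring common GATK-based practice for biparental marker
extraction:

- **Hard filter**: `QD < 5.0 || FS > 60.0 || MQ < 50.0 ||
  MQRankSum < −12.5 || ReadPosRankSum < −8.0`.  The inequalities are
  strict as written, so boundary values pass; a missing annotation cannot
  trigger its clause.
- **Corrected filter**: region exclusion first (a variant inside a
  centromere/telomere/TE interval fails regardless of annotations; BED
  intervals are 0-based half-open, variant positions 1-based), then
  Gaussian retention intervals fitted on the surviving records: QD
  two-component EM (dominant peak ± 2.5 SD), FS and MQRankSum
  single-Gaussian (± 2.5 SD and ± 4 SD), MQ at the fixed threshold 50.
  FS is fitted on its raw scale (configurable; no Phred transform is
  applied).  A missing annotation is retained for that metric.

EM details (the fit itself is not standardized anywhere): k-means
initialisation, ≤ 100 iterations, tolerance 1e−6, SD floor 1e−6 for
degenerate components.  When the two fitted components are separated by
less than one component SD the data are effectively unimodal and the fit
collapses to moment estimates — without this, EM splits a single peak
into two overlapping halves with understated SDs and the retention
interval becomes arbitrarily narrow.

Idempotence: the filter with *fixed* fitted intervals is idempotent.
Refitting on its own output is not, because truncation at ± k SD shrinks
the re-estimated SD by a known factor; callers who need to reapply the
filter should pass the returned `fits`.

The ALT-source parent is the one contributing more biallelic SNPs (ties
to parent1, deterministically); indels and multiallelic records are
excluded and counted.

## Genotype HMM

States AA/AB/BB are 0/1/2 copies of the ALT-parent allele.

- **Emissions**: ALT count *k* of depth *n* is Binomial(*n*, *p*) with
  *p* = ε, ½, 1 − ε.  ε defaults to 0.01 (a per-read error rate typical
  of aligned short reads after filtering).  Zero-depth sites emit
  uniformly.  Depths above 50 are rescaled to 50 — an overdispersion
  guard so a single pathological pileup cannot dominate a chromosome.
- **Transitions**: for a physical gap Δbp, d = Δbp·(cM/Mb)/10⁶ and
  r = ½(1 − e^(−2d/100)) (Haldane); the F2 two-locus matrix
  [(1−r)², 2r(1−r), r²; r(1−r), (1−r)²+r², r(1−r); r², 2r(1−r), (1−r)²]
  follows from independent maternal and paternal gametes.
- **Prior**: (¼, ½, ¼), the F2 expectation.  All recursions run in log
  space; Viterbi ties break toward staying in the current state, which
  favors paths with fewer crossovers.

Sample QC before fitting: organellar contigs dropped; sites with depth
outside mean ± 5 SD removed (moments over all retained sites — the
zero-depth class anchors the scale at shallow coverage so that rare
pile-ups stand out); samples with fewer than 7,000 informative
(depth > 0) sites rejected.  Zero depth variance degenerates the
interval to a point and the rule is skipped rather than removing
everything.

Crossovers are called at Viterbi state changes; the breakpoint interval
is bracketed by the nearest informative sites on either side and reported
at its midpoint; confidence is the smaller flanking-segment mean
posterior.  An AA↔BB change is a collapsed double crossover and is
flagged non-canonical rather than split.

This is a single-pass HMM by design: the multi-stage sliding-window
refinement used by trained-reconstruction pipelines is replaced by one
forward–backward/Viterbi pass, validated directly against ground truth
(≥ 99% site-level accuracy at 0.2× coverage on the default genome, and
exact agreement with exhaustive path enumeration on small fixtures).

## Cross assembly

Every crossover midpoint observed in the population splits its
chromosome; the resulting intervals are the markers, each placed at its
interval midpoint.  An individual's genotype at a marker is its segment
state there, set to missing when the segment's mean posterior falls
below 0.95.

QC runs in a fixed order and every removal is logged:

1. individuals called at too few markers — below half the population
   median called count by default (the threshold is otherwise
   unquantified in common practice);
2. pairs at ≥ 90% genotype identity over shared called markers — the
   member with fewer called markers is dropped (ties to the later sample
   id).  Unrelated F2 individuals share ≈ 37.5% of genotypes
   (Σ frequencies² = 6/16), so the 0.9 cutoff only catches duplicates
   and cross-contamination;
3. individuals with more than 25 genome-wide crossovers (about twice
   the expected median under the default genome's ~9.5 per plant);
4. markers missing in more than 10% of individuals;
5. markers failing a 1:2:1 χ² goodness-of-fit (df = 2, no continuity
   correction, expected counts from called individuals only) at
   p < 1e−7.

The genetic map is re-estimated from adjacent-marker recombination
fractions by a two-locus EM (the double-heterozygote class mixes
parental and double-recombinant gamete pairs; EM resolves it), capped at
r = 0.49 to keep the Haldane inverse finite, and accumulated per
chromosome.

The cross file is a rotated CSV: an `id` row, one row per phenotype, one
row per marker (`id, chromosome, cM, A/H/B codes, '-' missing`).  The
physical position travels in the marker id (`<chrom>_<bp>`), keeping the
format standard while making the file self-contained.

## QTL mapping

- **Conditional genotype probabilities** at markers and a 2-cM
  pseudomarker grid come from a forward–backward pass over observed
  marker codes with genotyping-error probability 1e−4; missing genotypes
  emit uniformly and are thereby summed over with prior weights.  The
  2-cM step is the conventional default for F2 scans; it is configurable.
- **Haley–Knott regression**: phenotype on intercept, additive predictor
  P(BB) − P(AA) and dominance predictor P(AB);
  LOD = (n/2)·log₁₀(RSS₀/RSS₁).  RSS₁ is floored at 1e−12·TSS so
  noiseless fixtures stay finite.  Position bases are computed by
  rank-revealing SVD, so collinear designs (e.g., a monomorphic marker)
  cannot manufacture spurious explained variance.
- **Permutation thresholds**: the phenotype vector is permuted against
  the intact genotype matrix — marker correlation is preserved and no
  stratification is applied (single population); the threshold is the
  empirical (1 − α) quantile of per-permutation genome-wide maximum LOD.
  Production settings are 1,000 permutations at α = 0.05 (100 for the
  two-dimensional scan); tests and the acceptance script use 100, which
  the calibration experiment shows is already well calibrated.
- **Two-QTL scan**: for distinct grid-position pairs, the full model
  adds the four products of additive/dominance predictors; interaction
  LOD = LOD_full − LOD_add, with significance from permutation of the
  pairwise maxima.  Same-position pairs are excluded.
- **Stepwise additive model**: forward steps add the position maximizing
  model LOD (computed incrementally via residualized candidate columns);
  backward elimination then removes QTL; the returned model maximizes
  pLOD = LOD − penalty·(#QTL) over everything visited, ties to fewer
  QTL, the empty model being a valid winner.  The penalty is the trait's
  own single-scan permutation threshold — the classical choice that
  controls the genome-wide rate of adding a spurious additive QTL.  The
  model space is additive-only; interactions are assessed separately by
  the two-QTL scan.  `max_qtl` defaults to 8.
- **Effects and explained variance**: the additive effect is half the
  fitted homozygote difference, signed so that a positive value means
  the early parent's allele reduces the trait (promotes flowering);
  per-QTL PEV is the drop-one RSS share of TSS, model PEV is
  100·(1 − RSS_full/TSS).
- **95% Bayes interval**: 10^LOD is integrated over genetic distance
  with trapezoidal spacing weights — the evaluation grid is irregular
  because markers cluster near crossovers, and unweighted sums would
  concentrate mass where sampling is dense.  The smallest contiguous run
  holding ≥ 95% of the mass is taken, each end extended by its
  half-spacing cell and snapped outward to the flanking marker
  positions, reported in bp.  In simulation (planted QTL, PEV 50%,
  n = 200, 50 replicates) these intervals cover the true position in
  well over 90% of replicates with a median width of ~0.5 Mb.
- **Window summaries**: LOD summed over non-overlapping 100-kb windows,
  reported at window centers; the window totals conserve the positional
  total exactly.

## Phenotype statistics

- **Broad-sense heritability**: one-way random-effects method of
  moments, H² = σ²_line/(σ²_line + σ²_error) with
  σ²_line = (MSB − MSW)/k₀ and k₀ = (N − Σnᵢ²/N)/(g − 1) for unbalanced
  designs, clipped to [0, 1].  Invariant to affine trait rescaling.
- **Vernalization sensitivity**: per line,
  log₂(mean DTF without vernalization / mean DTF with), the vernalized
  arm having had the 60-day cold period subtracted on ingestion.  Lines
  missing an arm are skipped and logged.
- **KO/KD classification**: line mean relative expression < 5 a.u. is a
  knockout; exactly 5 is assigned to knockdown (the published dividing
  line describes knockouts as below the cutoff).
- **Contrasts**: Student's t (two-sided) or Mann–Whitney U (mid-rank
  ties; exact for small samples without ties, normal approximation with
  continuity correction otherwise), adjusted by Benjamini–Hochberg or
  Bonferroni.  Zero-variance t inputs: equal means give p = 1, unequal
  give p = 0 with a warning.
- **ΔΔCt**: relative expression 2^(−ΔΔCt) against a reference gene, the
  calibrator being biological replicate 1 of the reference accession by
  convention.
- **Growth**: plants below 500 px on any day, or below 5,000 px in the
  late stage (the final third of the measured days — the exact window is
  configurable since the rule's reference period is a judgment call),
  are excluded; RGR = (ln A₁₈ − ln A₁₁)/7; per-mutant daily
  log₂(mutant/wild-type) trajectories are interpolated only inside the
  measured range and clustered by Ward linkage on Euclidean distance
  into k = 3 groups by default.
- Censored DTF values (recorded as 130 when flowering passed 125 days or
  never happened) enter means as-is, matching common reporting practice;
  `censor_dtf` applies the recoding on export.
- Group summaries compute line means first and average those, so lines
  with unequal replication weigh equally.

## Synthetic-data generator

What it emulates: annotation mixtures with a planted outlier mode
(inlier QD ~ N(25, 3), outlier ~ N(3, 1), half-normal FS, MQ point mass
at 60 for inliers — chosen so the corrected filter has one well-defined
dominant peak); Poisson crossovers with mean = Morgans per gamete
(Haldane-consistent, no interference); Poisson(coverage) depths with
binomial ALT sampling; additive QTL phenotypes (−a, d, +a for AA, AB,
BB) with Gaussian residuals and a default baseline of 30 DTF-like days;
replicated lines with Gaussian line effects and a multiplicative
vernalization shift (0.5 by default, i.e., log₂ sensitivity 1);
log-linear rosette growth with per-line slopes.

What it does not emulate: mapping/alignment artifacts, reference bias,
depth autocorrelation along the genome, crossover interference,
segregation distortion, genotype–environment interaction, non-Gaussian
phenotype noise, and censoring mechanisms other than the fixed DTF rule.
Passing tests therefore demonstrate algorithmic correctness under the
stated generative models, not robustness to every artifact of real
sequencing data.

All generators are bit-reproducible under a fixed seed.

## Problem sizes used in validation

The acceptance script and test suite run: 20 individuals × 20,000
markers at 0.2× coverage for reconstruction accuracy; 50 replicates of
n = 200 with a PEV-50% QTL for localisation and interval coverage (QTL
model fits on a 10-replicate subset); 200 null trials × 100 permutations
for threshold calibration; 10,000 variants for the filter operating
point; 60 lines × 12 replicates for heritability.  These sizes give
binomial/Monte-Carlo error well inside the asserted margins while
keeping a full run at about 90 seconds on one CPU.

## Known limitations

- Marker order is taken from physical positions; no order re-estimation.
- No composite-interval mapping, kinship correction or multi-trait scan.
- The two-QTL interaction test can show leakage when a strong main-effect
  QTL sits between grid positions (interaction products partially absorb
  the unmodelled main effect); interaction calls should be read jointly
  with the single-scan profile, as is standard for this scan family.
- The HMM assumes a known, constant per-read error rate and no
  overdispersion beyond the depth cap.
- Heritability uses the method of moments, not REML; for heavily
  unbalanced designs the two differ slightly.
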