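# Methods

## The genetic model

`wgsmap` simulates a two-strain cross: a mutagenized laboratory strain
(ancestry label `mut`) carrying the mutation(s) of interest, and a
polymorphic mapping strain (label `map`) — or, in the marked designs, the
wild-type backcross parent. The F1 is heterozygous everywhere; F2s arise by
F1 self-fertilization, as in hermaphrodite genetics. Every chromosome is
treated as an autosome; X hemizygosity, males, and multi-generation
backcrossing schemes are not modelled.

Chromosomes are ancestry-labelled segment lists over 1-based inclusive bp
coordinates. A genetic map assigns each chromosome a physical and a genetic
length, with a piecewise-linear (Marey-map) cM↔bp conversion; the default is
a single linear segment, since marker-level map functions add nothing to the
questions the simulator answers.

### Meiosis

Two interference models are available:

- **complete** (default): exactly one crossover per bivalent, placed
  uniformly on the *genetic* map; the transmitted chromatid is recombinant
  with probability 1/2, otherwise a uniformly chosen parental chromatid.
  This matches the strong interference of *C. elegans* meiosis and yields a
  recombinant fraction of exactly d/100 for loci d cM apart — the relation
  the screening-effort arithmetic assumes.
- **none**: the transmitted product receives a Poisson(L/100) number of
  crossovers placed uniformly in cM, reproducing the Haldane map function
  r = (1 − e^(−2d/100))/2.

Both are verified against their closed forms by Monte-Carlo tests
(10⁵ gametes, 3-binomial-SD tolerance).

### Phenotype and selection

`MutationSpec` covers recessive, dominant and semidominant single-locus
mutations and two-locus synthetic interactions (mutant only when homozygous
at both loci, which must lie on different chromosomes). Penetrance < 1 flips
a would-be mutant to wild type; picker misclassification is deliberately
folded into penetrance rather than modelled separately.

Pools are assembled by rejection sampling from an endless F2 stream, with an
attempt cap of 100 × pool_size / (expected eligible fraction) so an
impossible selection fails loudly rather than spinning. Per-individual RNG
streams are derived from the root seed with `numpy.random.SeedSequence`, so
pool membership is bit-reproducible regardless of consumption order.

Design-specific selection predicates:

- recessive / two-gene: phenotypically mutant F2s;
- dominant reverse: phenotypically **wild-type** F2s;
- dominant F3: phenotypically mutant F2s (2:1 het:hom), then an F3 screen
  keeping only F2s whose n selfed progeny are all mutant. A heterozygote
  survives the screen with probability (3/4)^n; the default n = 20 puts that
  at 0.3%, and n is configurable because real screens score broods of
  varying size;
- semidominant F3: heterozygotes (intermediate phenotype) and homozygotes
  both enter the picked set — the design exists precisely because the two
  classes are often not reliably distinguishable at picking time — and the
  F3 screen separates them;
- marked designs: F2s homozygous for the mutant-strain allele at both the
  mutation locus and the marker locus (one flanking marker per pool in the
  reciprocal design).

Optional segregation distortion models strain-incompatibility loci: F2s
homozygous for the mapping-strain allele at the distortion locus are removed
with probability 1 − viability before selection.

## Read-count simulation

Sequencing is simulated at the allele-count level; there are no reads,
alignments, indels, or base qualities, because the analysis consumes only
per-site ref/alt counts. Per site:

- raw depth ~ Poisson(mean_depth), independent across sites (no positional
  autocorrelation);
- with a finite `library_complexity` C, the retained depth is the number of
  *distinct* fragments among the raw draws-with-replacement from C — i.e.
  counts are post-duplicate-removal, mirroring a standard WGS pipeline. The
  expected duplicate fraction is 1 − C(1 − (1 − 1/C)^N)/N;
- alt count ~ Binomial(depth, f′), f′ = f(1−e) + (1−f)e, where f is the
  pool's true allele fraction at the site and e a symmetric per-base error
  rate. The symmetric two-allele error model (a flipped base becomes *the*
  other allele rather than one of three) keeps ref + alt = depth exact;
  third alleles are irrelevant to frequency mapping.

One modelling caveat: with a scalar per-site library complexity, duplicate
removal *contracts* the post-dedup depth distribution (depth is bounded by
C), so a smaller library shows a larger duplicate fraction and lower
retained depth but **not** a larger post-dedup depth variance. Reproducing
the amplification-driven coverage unevenness of real low-input libraries
would need per-site complexity heterogeneity, which is out of scope; tests
assert the duplicate-fraction and depth-loss contrasts only.

Panel sites (default density 1/kbp, emulating the annotated Hawaiian SNP
subset) carry the mapping-strain allele; background sites — causative
lesion, mutagenesis passengers, and marker-strain variants — ride on the
mutant-strain haplotypes. Background sites flagged `shared_with_reference`
are present in both parents (common deviations from the reference assembly)
and appear at fraction 1 in every sample; these are what background
subtraction removes.

## Mapping analysis

### Filters

- variant call: ≥ 3 supporting reads (configurable);
- frequency floor: alt fraction below the floor is flagged out; the default
  floor is the detection limit 1/mean-depth (5% at 20×), the filter that
  produces the characteristic 0–5% discontinuity in filtered SNP plots;
- homozygous call: depth ≥ 15 and alt fraction strictly > 0.8, with calls at
  exactly 100% additionally marked. The 80% cut tolerates sequencing errors
  and occasional mis-picked F2s;
- background subtraction: sample calls whose (chromosome, position, alt)
  occur among the reference sample's passing calls are dropped (optional
  positional tolerance).

All filters are monotone: tightening any threshold can only shrink the
surviving set (property-tested).

### Frequency series

Panel positions are known a priori, so a covered panel site that fails the
call filters is evidence of *absence* of the mapping allele: the series
records it at frequency 0 rather than dropping it. This is the convention of
panel-based mapping pipelines, and it is what lets the smoothed curve fall
to ~0 inside the mapping gap instead of interpolating across a hole in the
scatter. Zero-depth sites are always excluded; non-panel sites never enter.

### LOESS

Local polynomial regression with tricube weights over the k = ⌈span·n⌉
nearest points, evaluated on a uniform 10-kbp grid spanning each chromosome,
clipped to [0, 1]. Defaults: span 0.1, local quadratic — the common choices
for pooled-SNP mapping plots; both are configurable and recorded in the run
report. The predictor is centred and scaled per evaluation point for
conditioning; a window of tied x-values degrades the local degree gracefully.
The implementation is local-quadratic-capable (the available library
implementation is local-linear only) and is cross-checked against the
statsmodels LOWESS at degree 1 in the test suite. Fits require ≥ 10 points
per chromosome and fail explicitly otherwise.

### Interval detection

- **gap** (recessive-style pools): per chromosome, the longest contiguous
  region with LOESS curve < 0.1; endpoints are linear interpolations of the
  threshold crossings; score = length × mean depression below the threshold.
  The curve, not the raw spacing of surviving SNPs, defines the gap, because
  raw gap width confounds local panel density. All chromosomes are scanned,
  so two-gene crosses yield two intervals; multiple qualifying chromosomes
  are always all reported, ranked by score.
- **peak** (reverse mapping): homozygous panel calls (fraction ≥ 0.95) are
  binned in 0.5-Mbp windows and normalized by the panel sites per bin
  (guarded denominator); the interval is the maximal run of bins within 20%
  of the peak that contains the argmax, ties broken toward the longer run
  then leftmost. A plateau covering a whole chromosome is flagged
  degenerate. The 0.95 homozygosity cut for binning is this package's
  reconstruction of the published normalization, exposed as a flag.
- **cluster** (marked single pool): on the chromosome holding the plurality
  of novel homozygous calls, the largest chain in which consecutive calls
  are ≤ 2 Mbp apart, with ≥ 3 members; score = chain share of all
  homozygous calls (the "73 of 87" style enrichment fraction). The chaining
  rule is this package's operational definition of a visually evident
  cluster; max-gap 2 Mbp chains comfortably under ~1 variant/100 kbp
  backgrounds and is configurable.
- **reciprocal** (two flanking-marker pools): over the union of the two
  samples' homozygous sites, each sample contributes its observed fraction
  at every site (its full call set is consulted for sites where it made no
  homozygous call; a site entirely absent after filters contributes 0 — a
  choice flagged in the report, since truly uncovered sites are
  indistinguishable from reference-homozygous ones). The averaged profile
  is LOESS-smoothed (local linear, wider span 0.3 — the union site set is
  sparse) and the longest region with curve ≥ 0.75 is returned; 0.75 is the
  midpoint between the one-sample-homozygous level (0.5) and the
  both-homozygous level (1.0). The region is clipped to the span of observed
  sites because the fit carries no evidence beyond the outermost variant.

Candidate variants are the homozygous-passing novel calls inside the closed
top interval, ordered by position; when an effect-annotation table is
supplied, protein-altering classes sort first.

## Synthetic data and what the tests show

The default closed-loop conditions are pools of 40–100 selected F2s, 25×
mean coverage, error rate 0.002, ~1 panel SNP/kbp, and (for marked designs)
150 mutagenesis passengers plus 30 shared strain variants — chosen to match
the published experiments' scale (pools of 50–120, >20×, ~87 novel variants
genome-wide). The test genome is miniaturized to 3 chromosomes × 2 Mbp at
50 cM each so that a full simulate→map replicate runs in ~0.2 s; genetic
distances per chromosome are preserved, so selection, linkage decay and
interval recovery behave as at full scale, but *physical* interval sizes do
not transfer — on a 2-Mbp/50-cM chromosome everything is tightly linked in
bp terms, so marked-design clusters legitimately span most of the
chromosome. Locus-recovery acceptance runs 100 seeded replicates per design
and requires the true locus inside the called interval in ≥ 95.

The generator emulates Mendelian segregation, linkage, pooled sampling,
binomial read noise and duplicate removal. It does not emulate alignment
artifacts, repeat-driven coverage holes, GC bias, indels, panel annotation
errors, or modifier segregation from the mapping strain's genetic
background; passing tests therefore validate the designs' genetics and the
detectors' logic, not robustness to those real-data pathologies.

## Numerical and degenerate-input choices

- Coordinates: 1-based inclusive bp internally; BED export is 0-based
  half-open. Intervals are closed on both ends.
- Crossover positions are rounded to integer bp and clamped to
  [1, length−1]; recombination between identical haplotypes is short-cut to
  the identity.
- Zero-depth sites carry NaN fractions and are excluded everywhere
  downstream; empty chromosomes in a frequency series are flagged, not
  fatal; all-zero bins, unchainable variant sets, and curves that never
  reach threshold raise typed, named errors.
- Determinism: a single root seed per run; identical configs and seeds
  reproduce byte-identical output files.

## Known limitations

- The F3-screen default of 20 scored progeny per F2 is a modelling choice,
  not a measured brood size.
- Semidominant reverse mapping (pooling wild-type against heterozygote
  phenotypes) is not implemented beyond the penetrance knob.
- The acceptance computations use the miniaturized genome (3 × 2 Mbp); the
  analytic targets they verify are scale-free (allele fractions and ratios
  at the selected locus), so genome size does not enter.
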