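# Methods

`partho` analyses mother-offspring SNP trios for evidence of facultative
parthenogenesis (FP) and, when FP is supported, discriminates among the
automictic mechanisms that could have restored diploidy. It also contains a
chromatid-level simulator of those mechanisms, so every statistic in the
pipeline has a known-answer test against simulator ground truth.

## The biological model

In automictic parthenogenesis an unfertilised egg develops after meiosis,
with diploidy restored from the mother's own meiotic products. The candidate
mechanisms leave distinct genomic fingerprints in the offspring:

| mechanism | diploidy restored by | expected offspring heterozygosity |
|---|---|---|
| terminal fusion (TF) | egg + its second polar body (meiosis-II sister) | low; retained only **distal** to crossovers (toward telomeres) |
| central fusion (CF) | egg + a first-polar-body product (non-sister) | near-maternal; retained proximal to crossovers |
| gametic duplication (GD) | one gamete genome doubled | exactly zero |
| apomixis | no meiotic reduction | identical to mother (clone) |
| sexual | egg + sperm | ~half of loci heterozygous where parents differ; parent-offspring relatedness ≈ 0.5 at polymorphic loci |

The pipeline therefore measures (i) individual heterozygosity — observed
heterozygosity OH and homozygosity by loci HL, where HL weights each locus
by its expected heterozygosity `E = 1 − p² − q²` from sample allele
frequencies, `HL = ΣE_hom / (ΣE_hom + ΣE_het)`; (ii) pairwise relatedness —
the shared-alleles index B_xy and genotype-sharing index M_xy (on biallelic
genotypes the two coincide locus-wise; both are computed from their own
definitions and the equality is asserted in tests); (iii) the fate of each
maternally heterozygous locus in each offspring (0/0, 0/1 retained, 1/1);
and (iv) second-order patterns — inheritance bias between the two
homozygous fates (exact two-sided binomial test at expectation 0.5,
two-sidedness by summing outcomes whose point probability does not exceed
the observed one), overlap of retained-heterozygosity loci between
siblings (Jaccard index with a permutation null), and GC content of the
sequence flanking retained vs lost loci (recombination-associated GC-biased
gene conversion predicts elevated GC near crossover-adjacent regions).

## Site filtering

Statistics are computed on a filtered, complete-case set of biallelic SNPs.
The cascade, in order: indels removed; per-sample calls with depth < 5 set
missing; SNPs within 3 bp of an input indel removed; site quality < 30
removed; GATK-style INFO hard filters (`QD < 2, FS > 60, MQ < 40,
MQRankSum < −12.5, ReadPosRankSum < −8`) applied where those annotations
exist, skipped with a logged warning where absent; total-depth outliers
(outside 0.5×–2× the mean total depth) removed; non-biallelic sites
removed; finally any site with a missing call in any trio member removed.

Two numerical choices deserve note. The depth bounds are expressed as
multipliers of the *observed* mean total depth rather than absolute counts,
so the rule transfers across datasets with different coverage. Because the
mean shifts as sites drop out, the cascade is iterated until no further
site is removed; this makes `apply_site_filters` idempotent by
construction, which downstream code and tests rely on. Thinning to one
variant per 50-kb window uses fixed, zero-anchored bins and a seeded
uniform choice per occupied bin — the simplest reproducible convention.

RAD-locus footprints are derived from per-base depth tracks: a base passes
when all samples cover it at depth ≥ 5 (and per-base quality ≥ 30 where a
quality track exists); passing runs merge across ≤ 10 bp gaps (gap bases
included in the span); merged intervals < 100 bp are dropped. The
implementation is validated against a brute-force per-base oracle on
random tracks, including the exact gap-10/gap-11 and 99/100-bp boundaries.

## The simulator

`simulate_mother` draws marker positions uniformly per chromosome and makes
each marker independently heterozygous with probability
`maternal_het_fraction`. `simulate_meiosis` replicates each haplotype into
sister chromatids, draws the crossover count (1 obligate + Poisson extras
by default), and for each crossover picks a uniform position and one
chromatid per homolog, physically exchanging the segment distal to the
position relative to the centromere. Chromosomes are telocentric by default
(centromere at coordinate 0), so "distal" means larger coordinates,
matching the telomeric-retention geometry of TF; a metacentric centromere
is configurable and flips distality per arm. Crossover interference is not
modelled — positions are independent, the simplest model producing the
correct tract geometry. Segregation assigns one homolog's sister pair to
the egg lineage uniformly per chromosome. `form_offspring` then fuses the
egg chromatid with its sister (TF), a polar-body chromatid (CF), itself
(GD), copies the mother (apomixis), or adds an independent paternal
haplotype drawn at a configurable allele frequency (sexual; default 0.5 at
every marker, i.e. an unrelated outbred father at polymorphic sites).

Defaults emulate the study design the pipeline targets: 20,562 markers on
18 chromosomes, maternal heterozygous fraction 278/20,562 ≈ 0.0135,
per-sample negative-binomial depth with mean 17 (trio total ≈ 50,
dispersion 5), 1% missingness, reference background GC 0.41. Chromosome
lengths are scaled to 2 Mb: every statistic in the pipeline depends only on
*relative* positions of markers and crossovers, so physical length is a
pure scale factor, and 2 Mb keeps the emitted reference FASTA a practical
text file. What the simulator does **not** emulate: genotyping error,
allele-specific mapping bias (the reference-allele inheritance bias seen in
real data has no simulated counterpart), linkage between markers within a
RAD locus, sex chromosomes and WW inviability, mutation, and crossover
interference. Passing tests therefore demonstrate correctness of the
estimators and the geometric logic of the mechanisms, not robustness to
those real-data artefacts.

## Inference details

* Bootstraps resample loci (not individuals — there is only one family),
  with replacement to the original locus count, 100 replicates by default;
  HL's allele frequencies are recomputed inside each replicate. Replicates
  on which a metric is undefined are redrawn and logged.
* The Jaccard permutation null preserves each offspring's retained-locus
  count and draws locus identities uniformly from the maternal-HET set —
  the minimal null for "more shared than chance". Empirical p-values use
  the add-one estimator `(1 + k)/(1 + n)` so they are never zero. The
  alternative sharing proportion `|A∩B|/min(|A|,|B|)` is reported alongside.
  The null mean is validated against the exact hypergeometric expectation
  `E[I/(|A|+|B|−I)]`, `I ~ Hypergeom(N, |A|, |B|)`.
* The GC flank window defaults to ±5 kb and is always reported with the
  result; both a Mann-Whitney rank test and a label-permutation test on the
  difference of class means are reported, since "indistinguishable GC"
  claims should not hinge on one test's assumptions. The permutation test
  is calibrated (≤ 10% false positives at α = 0.05 over 100 null
  simulations) and detects a constructed 10-point GC contrast.
* `diagnose_mechanism` is deliberately a transparent rule set, not a
  likelihood model, because the discriminating signals are qualitative:
  relatedness in `[0.25, 0.90]` → SEXUAL; relatedness ≥ 0.95 with retained
  fraction ≤ 0.5% (or ≤ 2 loci, tolerating genotyping error) → GD; with
  retained fraction ≥ 0.8 → central-fusion-like (flagged as a clone when
  the genotypes match the mother exactly, since apomixis and CF are not
  distinguishable from a single offspring's genotypes alone); otherwise →
  TF. The sexual band is wide because, with a mostly monomorphic marker
  panel and a paternal allele frequency of 0.5, parent-offspring
  relatedness sits near 0.75 rather than the textbook 0.5; all thresholds
  are configurable and echoed in the evidence payload. On simulated trios
  (5,000 markers, 1% heterozygosity, 50 replicates per mechanism) the rules
  recover the generating mechanism with ≥ 95% accuracy.

## Degenerate inputs and tie-breaks

The Jaccard index of two empty sets is defined as 0 and logged. OH, HL and
the relatedness indices raise on inputs with no informative loci rather
than returning a silent NaN. Flank windows truncate at contig edges; N
bases are excluded from both numerator and denominator of GC fractions.
Multi-allelic VCF records are read and flagged, then removed by the filter
stage; the VCF writer emits biallelic-state genotypes only. The pipeline's
single global seed fans out to stages by fixed offsets (simulate +0,
thin +1, stats +2, Jaccard +3, GC +4), so any stage can be reproduced in
isolation.

## Problem sizes used in the test suite

Unit tests run on hundreds of markers; acceptance-level properties use
5,000-marker trios with 50 replicates per mechanism, 2,000 permutations
for the Jaccard null, 100 simulations for GC calibration, and 2,000
Monte-Carlo meioses for the TF retention expectation — sizes at which the
Monte-Carlo standard errors are small enough for 3-SE checks while the
whole suite stays fast.

## Known limitations

Z-linked loci are not treated specially (male ZZ offspring are expected
under FP in snakes, so their Z dosage matches an autosome's; a chromosome
exclusion list is available in the filter config for users who want to
drop them). The reference-allele inheritance bias observed in real trios
is quantified by the binomial test but not mechanistically modelled. The
mechanism classifier assumes exactly one offspring-mother comparison at a
time and does not pool evidence across siblings.
Central fusion is the weakest call: under a single obligate crossover its
retained fraction is distributed around 0.75 and straddles the 0.8
threshold, so roughly half of simulated CF offspring are labelled
TERMINAL_FUSION. The genuinely discriminating CF signature is the
*location* of retained heterozygosity (proximal to crossovers, including
centromere-adjacent markers) rather than its amount; the verdict is named
CENTRAL_FUSION_LIKE to flag this limit, and the recovery accuracy quoted
above covers TF, GD, apomixis and sexual reproduction.
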