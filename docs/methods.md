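# Methods

`popvar` assesses whether rare variants genotyped on a SNP array are real
(analytical validity), whether they matter clinically (phenome-wide
association), and how strongly (effect size and age-dependent
penetrance), in a population cohort whose participants were not recruited
for disease.  Because the cohorts this kind of analysis targets are
access-controlled, the package pairs every analysis stage with a
synthetic biobank generator that has known ground truth, so the whole
pipeline is testable end to end.

## The synthetic biobank

### Genotypes and batches

A panel of biallelic variants is drawn with minor-allele frequencies
(MAF) log-uniform over a configurable range (default 0.001%–1%, the rare
regime the pipeline is about).  Truth genotypes are Binomial(2, MAF) per
sample — exactly Hardy-Weinberg equilibrium (HWE) proportions — so that
real variants pass the HWE filter at the filter's own operating
characteristics.  Samples are assigned to genotyping batches in
contiguous blocks (default 106 near-equal batches, emulating biobank
plating); batch sizes are configurable.

### Quality classes and intensity geometry

Each variant belongs to one of three analytical-validity classes, drawn
from a MAF-bin-dependent mixture:

* `true_poly_good` — a real variant with a clean assay;
* `true_poly_noisy` — a real variant with a fuzzy assay;
* `monomorphic_smear` — no variation at all; the "variant" is an array
  artifact.

The default mixture follows the empirical pattern of published manual
evaluations (artifacts dominate below 0.005% MAF and vanish above 0.1%),
smoothed so the true false-positive fraction is monotone in MAF.  The
smoothing zeroes the small noisy/smear probabilities in the two highest
MAF bins; the handful of high-MAF artifacts a real panel contains is a
feature the generator deliberately omits.

Two-channel intensities place the three genotype clusters on an arc of
radius 2 (hom-ref near the A axis, het on the diagonal, hom-alt near the
B axis); `d` denotes the adjacent-center distance.  Per class:

* good: isotropic clusters with SD `d/8`;
* noisy: clusters elongated along the radial (total-intensity) direction
  with largest-axis SD `d/2.5` and tangential SD `d/8` — the radial
  orientation is what keeps a noisy-but-real variant callable, mirroring
  how real intensity noise mostly scales total brightness;
* smear: a single tight cluster at the hom-ref position plus, with
  probability `tail_mass = 2 x (binned MAF)` per sample, a point strung
  along the A=B diagonal (radius 0.8–5.0, small cross jitter).  Those
  tail points fall in the heterozygote calling region, so the artifact's
  apparent allele frequency matches the MAF bin it was planted in.

Per-batch multiplicative channel scalings, log-normal with SD 0.05,
model plate/chemistry variation.

The good-class separation default is 8 (adjacent centers eight SDs
apart).  A separation of ~6 would put the caller's decision boundary
only ~3 SD from the hom-ref cloud, creating a spurious-heterozygote
floor of ~10^-3 per sample that would swamp the observed MAF of every
ultra-rare variant at biobank scale; 8 keeps that floor below 10^-5
while remaining comfortably inside the rubric's "clear separation" band.

### The caller

Observed genotypes come from an array-style caller: per-batch median
normalisation of each channel (plate normalisation), then classification
by the affine coordinate along the hom-ref→het and het→hom-alt center
axes.  Decision boundaries sit at 0.58 of the inter-center distance —
shifted toward the rare classes, encoding the prior that a rare variant's
heterozygote cluster must be well clear of the bulk before a call is
believable — with a no-call band of half-width 0.05 around each
boundary, plus class-specific random missingness (good 0.05%, noisy and
smear 0.5%).  Under the defaults this yields >99.9% concordance with
truth for good variants, a few tenths of a percent of het-miscalls for
noisy ones, and spurious heterozygote calls (observed MAF > 0 with true
MAF = 0) for smears.

### Phenotypes and onset

Covariates emulate a recruitment window of ages 37–73 (uniform), 54%
female, ten assessment centers, two genotyping chips (6% on the
secondary chip) and ten standard-normal ancestry principal components.
Every trait receives small random covariate loadings (age, sex, center,
chip, PCs), so covariate adjustment is genuinely load-bearing in tests.
Continuous traits add planted per-variant betas and unit Gaussian noise;
binary traits follow a logistic model anchored at the trait's target
prevalence (default 5%, 10 binary + 10 continuous traits).  The default
trait panel size is a pragmatic stand-in for the hundreds of curated
traits a real phenome scan uses; nothing in the machinery depends on it.

Age of onset is drawn from piecewise-linear cumulative incidence curves:
non-carriers reach 0.5% by age 40 and 6% by 73 (a late-onset common
disease), carriers of any `hazard_scale`-flagged variant reach 10% by 40
and 28% by 73 — the regime in which a reportedly highly penetrant
dominant variant shows ~10% penetrance in a population sample.
Censoring is at the simulated age at assessment.

### Determinism

All randomness flows from one master seed through labeled child streams
(one per stage, and per variant within the intensity/calling stages), so
identical configurations give byte-identical outputs and each stage can
be regenerated independently.

## Variant QC

MAF is folded minor-allele count over called alleles; missingness is the
fraction of no-calls; the HWE test is the exact conditional two-sided
test (sum of the probabilities of all heterozygote counts no likelier
than the observed one), computed in log space so biobank-scale counts
are stable and verified against an integer-arithmetic enumeration
oracle.  The filter cascade retains variants with 0 < MAF < 1%, HWE
p > 0.05 and missingness < 0.01 — all strict inequalities, so boundary
values are excluded — and records the first failing rule in the fixed
order common → monomorphic → HWE → missingness.

The batch-skew diagnostic asks whether a variant's rare genotype calls
pile up in one batch: an upper binomial tail for the fullest batch under
size-proportional allocation, Bonferroni-multiplied by the number of
batches.  A variant is flagged below adjusted p 0.05 or when every rare
call comes from a single batch.  X-linked variants can have HWE computed
on females only (hemizygous males never enter the het count); the
generator itself ships autosomal panels only.

## Cluster-plot quality scoring

Rare variants cannot be reviewed batch-by-batch (too few carriers), so
all batches are pooled into one intensity plot per variant and scored on
the 1–5 visual rubric: 1–2 no discernible clusters (low quality, likely
array false positives), 3 unclear, 4–5 separable clusters (high
quality).  The automated surrogate summarises each plot by per-called-
class Gaussian moments (classes under 5 points shrink toward spherical;
singletons fall back to a pooled spherical estimate) and maps three
statistics onto the rubric:

* **separation** — the minimum, over *adjacent* genotype-class pairs, of
  the center distance divided by the *larger* of the two classes'
  largest-eigenvalue SDs.  Governing the pair by its wider member is the
  deliberate design choice here: after a caller has partitioned the
  plane, a smear's spurious het calls always form a far-away sliver, and
  only their diffuseness betrays them.  For the equal-SD two-cluster
  case this reduces to the textbook d/sigma.
* **noise** — mean within-class RMS dispersion over the mean class
  center magnitude (scale-free fuzziness).
* **silhouette** — mean silhouette of called points under call labels,
  by the O(n^2) definition (majority class subsampled), reported for
  review rather than used in scoring.

Scores: separation ≥ 3 gives 5 (or 4 if noise > 0.5); 1.5–3 gives 3;
below 1.5 gives 2 (noisy) or 1.  A variant with no rare calls scores 1,
and below 5 rare calls the score is capped at 2 — with one to four
points there is no geometry to judge, the same convention a human
reviewer applies to ultra-rare variants.  Thresholds are configurable;
the defaults place the generator's good class (realised separation
~5–7) at score 5, the noisy class (~2.4) at 3, and smears (~1.2–1.9) at
1–2.  Smears with many spurious calls occasionally land at 3 (unclear)
rather than 1–2; this honest ambiguity is visible in the synthetic
quality tables and does not disturb the monotone FPR-versus-MAF shape.

Manual reviewer scores can be ingested alongside: multi-reviewer scores
are averaged, a variant is retained for association only above an
average of 4 (strict), and averaged scores group as low < 2.5,
high > 4, else unclear — whereas single integer scores group as
{1,2}/3/{4,5}.  Reviewer agreement is summarised as Pearson r^2 plus
percent low-vs-high agreement over decisively scored variants.

MAF binning uses half-open percent bins
[0, 0.0005), ..., [0.5, 1] (final bin closed); the false-positive rate
above a MAF cutoff is FP/(FP+TP) with unclear variants excluded; the ROC
of MAF as a predictor of high quality is the empirical pairwise
concordance (ties at one half) with a seeded, class-stratified bootstrap
CI.  The empirical AUC was chosen over a parametric ROC fit because it
is reproducible and has an exact O(n^2) oracle; on the bundled reference
counts (binned at midpoints) it gives 0.9213, slightly below the ~0.95 a
model-based fit on per-variant MAFs reports for the same data.

## Prioritization

Variants enter the analysis set either with at least one
pathogenic/likely-pathogenic ClinVar-style assertion (conflicting
records count when one assertion was pathogenic; records since
reclassified benign are dropped) or, irrespective of database presence,
as protein-truncating variants (stop-gain, frameshift) in curated
disease gene panels — plus nonsynonymous/in-frame-indel panel variants
that carry a pathogenic classification.  The final set intersects
prioritization, QC and the high-quality cluster group, with a provenance
row per variant recording which gates passed.

## Association scan

Binary traits use the two-sided Fisher exact test on the carrier
(dosage ≥ 1) by outcome table; the reported odds ratio is the sample
cross-product with the Haldane-Anscombe 0.5 correction when any cell is
zero, and a Woolf logit-method 95% CI.  Continuous traits use OLS of the
trait on additive dosage adjusted for age, sex (dropped for sex-specific
traits), center and chip (as indicator sets) and ten principal
components, complete-case, with Wald t intervals.  A z-score option
standardises continuous traits so betas come out in SD units.
Significance uses a single Bonferroni gate, alpha over the number of
attempted tests; untestable pairs (no carriers, empty margins,
monomorphic in the analysis set) are recorded with an explicit status
rather than dropped.

Conditional analysis refits each significant pair with the
most-associated other variant for the same trait within a centered 1 Mb
window (ties: smallest p, then largest |effect|, then smallest position)
as an extra covariate — logistic refit for binary traits.  If the
conditional p rises above the Bonferroni threshold the pair is marked
`explained_by_regional_variant`.  A perfectly collinear proxy makes the
refit degenerate; the implementation treats that as conditional p = 1,
i.e. explained, since the variant carries no information beyond its
proxy.

Because the exact test is discrete, its attainable size at alpha = 0.05
is below 0.05 (about 0.044 at a few hundred carriers).  Calibration
checks therefore compare the simulated Fisher type-I error against the
exact attainable size computed by hypergeometric enumeration
(`fisher_achieved_size`), and the OLS branch against nominal; the
calibration experiments run at 0.5–1% MAF and 50% prevalence, where the
exact test's discreteness is mild enough for its size to be meaningfully
estimated with 10^4 tests.

## Penetrance

Penetrance at age a is 1 minus the Kaplan-Meier product-limit estimate
among carriers, with Greenwood variance and log(−log) confidence
intervals (which stay inside [0, 1] for rare events).  Ties resolve
events-first.  Subjects enter at birth — no left truncation — so in a
healthy-volunteer cohort the estimate is a floor, which is why outputs
are framed as minimum penetrance.  Cohort curves (population, population
carriers, clinically ascertained probands and relatives) can be aligned
on a common age grid, differenced, and compared with a log-rank test
(verified against an independent survival library).

## Problem sizes and numerical choices

Simulation-based checks run at sizes chosen to make their Monte Carlo
error small relative to the tolerance being asserted: 10,000 null tests
for type-I error (20 cohorts of 20,000 samples x 25 variants x 20
traits), 200 replicates at n = 100,000 for odds-ratio recovery, 200
generator replicates at n = 20,000 for beta recovery, 50 seeds x 500
carriers for penetrance recovery, and 100 seeded panels of 400 variants
x 10,000 samples (MAF 0.01–1%) for the FPR-versus-MAF shape.  Scoring
subsamples the majority class to 800 points for the silhouette only;
separation and noise use all points.  Exact-test p-values accumulate
tails with a 1 + 1e-12 relative guard against float ties; covariance
fits floor eigenvalues at machine-scale values.

## Limitations

* The generator's cluster geometry is stylised (three fixed centers on
  an arc); it reproduces the failure modes that matter for scoring but
  not the full zoo of real array artifacts (off-target probes, CNV
  overlap, sex-chromosome intensity shifts).
* X-chromosome simulation is omitted; the QC module accepts X-linked
  flags for female-only HWE, but panels are autosomal.
* Smears with large spurious-call counts can score "unclear" rather than
  "low"; a human reviewer with batch-level context would likely do the
  same, but it means automated low/high groups are slightly conservative
  about calling false positives at higher MAF.
* Passing synthetic recovery tests shows the machinery is calibrated
  under the generator's assumptions (independent samples, Gaussian
  intensity noise, logistic/linear trait models, independent censoring);
  it cannot certify behaviour under population structure, relatedness,
  or informative missingness in real cohorts.
* Penetrance estimates ignore left truncation and competing risks by
  design, hence "minimum penetrance".
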