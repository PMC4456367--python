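# Methods

This note documents the models behind `armcna`, the parameters that matter,
what the synthetic cohorts do and do not emulate, and the numerical choices
made where the design was genuinely open.

## Signal model and ratio scale

Paired SNP-array intensities are summarized per SNP and allele as the
tumor/normal relative ratio. When replicate probe intensities are present
(≥ 3 per SNP and allele), each side is first collapsed by a trimmed median
— the median after removing one maximum and one minimum — before the ratio
is formed; otherwise the plain intensity ratio is used.

The ratio scale is affine in allele copy number: 0, 1 and 2 copies map to
0.5, 1.0 and 1.5. A tumor of purity φ (fraction of tumor cells in the
section) containing an allele at c copies therefore shows

    E[r] = (1 − φ)·1 + φ·(1 + c)/2.

No purity or ploidy correction is applied downstream; the detection
thresholds are interpreted on the observed, admixed scale. At the default
purity of 0.8 a single-copy gain sits at ratio 1.4 and a single-copy loss
at 0.6.

## Caller

1. **Smoothing.** Running median per allele along each chromosome, window
   15 probes (odd, centred, truncated at chromosome ends; a chromosome
   shorter than the window falls back to its whole-chromosome median with
   a warning). The median is robust to single-probe outliers and preserves
   step edges of events at least half a window long.
2. **State calling with hysteresis.** The detection thresholds are strict:
   ratio > 1.3 (1.6 copies) for gain, < 0.7 (0.4 copies) for loss. At
   realistic noise a true single-copy gain (1.4 at purity 0.8) sits only
   ~1.6 smoothed standard deviations above the 1.3 cut-off, so plain
   per-probe thresholding shreds long events into fragments whenever the
   smoothed track grazes the cut-off. The caller therefore uses
   two-threshold hysteresis: a run must contain at least one probe beyond
   the detection threshold, but extends over all contiguous probes beyond
   a weaker extension threshold (defaults 1.15 / 0.85, the midpoints
   toward the diploid ratio). Measured on simulated cohorts at purity 0.8
   and noise 0.1 this lifts whole-arm event recovery from ~0.5 to > 0.98
   without creating false segments (a spurious segment would need a ≥ 10
   probe run beyond the extension threshold *and* a probe beyond the
   detection threshold in a diploid region — jointly ≪ 10⁻³ per
   chromosome at these noise levels). Setting the extension thresholds
   equal to the detection thresholds disables hysteresis and recovers
   plain strict thresholding.
3. **Segments.** Maximal runs of a constant (A-state, B-state) pair with
   ≥ 10 probes are emitted; runs of ≤ 2 discordant probes inside an
   otherwise constant run are absorbed (configurable). Categories:
   (loss, loss) → homozygous deletion; (loss, gain) → copy-number-neutral
   LOH; exactly one allele lost → hemizygous loss; any gain without loss
   → gain. A region where one allele is gained and the other lost is
   mapped to CNN-LOH — no separate amplified-LOH class is defined.
4. **Span classes.** Segments crossing the centromere are split at the arm
   boundary (the probe-count floor is re-applied to the parts, since
   smoothing bleeds about half a window of signal across the centromere
   and would otherwise leave sub-minimal slivers on the neighbouring
   arm). A segment's span fraction is the genomic length of its probe
   span divided by the span between its arm's first and last probe —
   probe coverage, not band coordinates, defines what is observable at
   arm tips. Strictly greater than 0.98 → whole-arm; exactly 0.98 →
   focal.

**Calibration of the thresholds.** The 1.3/0.7 cut-offs, the 98% whole-arm
rule, the CIN boundaries (≥ 9 / 1–8 / 0 altered arms) and the expression
filter (max ≥ 100, mean ≥ 10, CV ≥ 0.3 after scaling arrays to mean 100)
are the published operating points of this workflow and are exposed, not
re-fit.

## Arm-level profiling

Each altered (sample, arm) pair contributes exactly one event, classified
whole-arm if any single segment on that arm is whole-arm. This "a tumor
contributes its arm once" unit is a design choice: the source workflow
never states whether, e.g., a gain and a CNN-LOH on one arm count once or
twice. All categories, including CNN-LOH, count toward the CIN arm total.

CNA-profile clustering encodes each arm ordinally (none = 0, focal = 1,
whole-arm = 2) and applies agglomerative clustering with Euclidean
distance and complete linkage. The encoding is a documented choice; the
workflow being reproduced clusters "the SNP array data" without specifying
a feature matrix.

Tumor-suppressor LOH status is read off segment overlap (any overlap
counts): hemizygous loss or homozygous deletion → LOH, otherwise CNN-LOH
segment → CNN LOH, otherwise nl. Physical loss takes precedence when both
overlap. The built-in locus table (TP53, NF1, BRCA1, RB1, BRCA2; GRCh37
coordinates) can be overridden with a BED file.

## Synthetic cohorts

The simulator plants, per histology archetype, a Poisson number of altered
arms (sampled without replacement, optionally weighted toward
archetype-specific recurrent arms), each whole-arm with the archetype's
probability, with allele-copy pairs drawn from a configurable category mix
(gain 0.40, hemizygous loss 0.35, CNN-LOH 0.18, homozygous deletion 0.07).
Default archetypes mirror the published clear-cell vs serous contrast:
~7 events at 47% whole-arm vs ~18 events at 22% whole-arm, with an
optional joint 17p/17q/13q hemizygous loss (probability 0.85) in the
serous-like archetype reproducing the BRCA1–NF1–TP53 / BRCA2–RB1
co-occurrence pattern. Probe signals carry multiplicative log-normal noise
(sd 0.1 per signal by default, hence √2 × 0.1 on the ratio); normals
fluctuate around a constant diploid level. Default density is 200 probes
per arm — a desk-scale stand-in for a 250K array that keeps a 30-sample
cohort under a few seconds.

Expression matrices plant k = 3 clusters with 100 disjoint marker genes
each, shifted by 2 log2 units over a log-normal baseline (per-gene mean
log2 6 ± 1, residual sd 0.5), 2000 genes total. Clinical tables draw
progression-free survival from an exponential proportional-hazards model
(baseline 0.02 events/month; per-cluster multipliers, default protective
0.2 for cluster 2) with administrative censoring at 60 months, plus stage
/ chemoresponse / mutation flags from per-cluster Bernoulli proportions
taken from the published contingency tables.

**What the simulator does not emulate:** probe-level GC waves and
hybridization artifacts, germline CNVs, subclonal (fractional-copy)
events, correlated noise along the genome, probe-specific affinities,
non-exponential survival, and informative censoring. Passing recovery
tests therefore demonstrates correctness of the machinery under the
stated noise model, not performance on raw clinical arrays.

## Expression workflow

Normalization scales every array to mean 100 (idempotent,
scale-invariant). The probe filter runs on the normalized linear scale —
CV on the linear scale matches how array-filtering thresholds of this
vintage were stated. Clustering operates on log2(signal + 1) (configurable
to linear); Euclidean/complete for hierarchical subtyping.

Consensus k-means, per candidate k in 2..10: 1000 runs by default (the
pipeline and tests scale to 100, which is already stable at the planted
effect size), each on 3000 genes sampled without replacement (all genes if
fewer are available) and a shuffled sample order, k-means with
random-partition initialization and ≤ 100 Lloyd iterations. The literal
sample-order shuffle is retained because the procedure being reproduced
lists it as an explicit step, although k-means is order-insensitive given
fixed initial centroids. Final labels cut an average-linkage tree of
1 − consensus at k.

Rank selection factorizes each k's consensus matrix at rank k
(multiplicative-update NMF, Frobenius loss, 10 random restarts, tolerance
1e-6) and picks the k with the lowest relative Frobenius reconstruction
error, smallest k on ties (within 1e-9). This works because the consensus
matrix at the true k is near-binary block structure (rank-k almost
exactly), while over- or under-partitioned consensus matrices are blurred
by unstable co-clustering and factorize worse at their own rank. The
error values are data-dependent; no published error magnitudes are
targeted.

## Association statistics

Fisher's exact test uses the two-sided point-probability rule — the sum of
hypergeometric probabilities of all tables with the observed margins no
more likely than the observed table — which reproduces the published
p-values exactly; a table with an empty margin returns p = 1 with a flag.
Survival times are in months. The log-rank test is the k-sample chi-square
with k − 1 degrees of freedom; Kaplan–Meier curves are exported with
at-risk counts. The Cox model maximizes the Efron partial likelihood and
reports hazard ratios with Wald 95% CIs; constant covariates are rejected,
and coefficients beyond |β| > 10 are flagged as monotone likelihood with
estimates suppressed. No multiple-testing correction is applied — each
test is reported marginally, matching the workflow being reproduced.

## Problem sizes and determinism

Recovery guarantees are exercised at: 30 simulated samples (≈ 380 planted
events) for caller sensitivity/FDR/category accuracy and whole-arm
fraction recovery; 20 replicate 30-sample expression cohorts at 100
consensus iterations for subtyping and rank selection; 500 replicates for
log-rank null calibration (KS against uniform) and power at hazard ratio
6 with groups of 12/13; 200 replicates of n = 500 for Cox CI coverage of
a planted hazard ratio 2. All generators draw from
`numpy.random.default_rng` seeded from a single master seed; pipeline
reports are byte-identical across re-runs with the same config and seed.

## Known limitations

- The caller assumes integer-copy events in a single dominant clone;
  purity is a global constant and subclonality is out of scope.
- Arm-level counting hides multiple independent focal events on one arm.
- The whole-arm rule is probe-span based; arrays with very sparse arm
  tips will under-call whole-arm events.
- The published per-arm serous column sums (51 whole-arm / 232 total)
  disagree slightly with the accompanying text (50/231); the reference
  module tallies the table as printed and keeps the text totals available
  separately, without forcing either number.
- CNA-profile clustering against histology labels is only weakly
  determined even at the published per-arm frequencies — histology
  archetypes overlap on chromosome 8 — so cluster-recovery tests plant
  explicitly separable arm signatures via archetype arm weights.
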