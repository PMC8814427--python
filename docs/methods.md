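# Methods

## Arm-level copy-number calls and the aneuploidy score

The coordinate frame is a genome model of 22 autosomes with a centromere
position each; the p arm is [1, centromere] and the q arm
[centromere+1, length], so the 44 arms tile the autosomes.  Sex
chromosomes are accepted on input but never scored: the methylation layer
excludes allosomal probes, and arm calls are reported for autosomes only.
Acrocentric p-arms are ordinary arms here; a configurable exclusion list
can remove them.

Segments spanning a centromere are split at it, each half keeping the
parent's copy number, so total covered length is conserved.  The arm copy
number is the **lower weighted median** of the overlapping segments'
copy numbers, weighted by within-arm overlap length: the smallest value
whose cumulative weight reaches half the total.  The lower-median tie
rule (rather than a midpoint) keeps the arm value inside the set of
observed segment values, so the comparison against an integer baseline is
always well defined; with ABSOLUTE-style integer segment copy numbers the
two conventions differ only on exact weight ties.

The neutral baseline is the sample ploidy rounded half-up
(2.5 → 3; the convention is documented because "round to integer" is
otherwise ambiguous).  An arm is +1/−1 when its copy number is
above/below the baseline, and AS is the count of non-neutral arms.  Arms
with zero segment coverage get a missing call and count as neutral, with
a logged warning — dropping the sample instead is a caller-side choice.
Per-segment calls against the same baseline are emitted as a by-product
table.

## The synthetic cohort

The generator emulates the joint structure the analysis assumes, with a
mandatory seed fixing every byte of output.

* **Copy number.**  Each tumor draws an integer ploidy from
  {2: 0.85, 3: 0.10, 4: 0.05} plus uniform jitter within ±0.3 (so
  rounding recovers the integer), and purity from Beta(8, 3)
  (mean ≈ 0.73).  Each of the 44 arms independently receives an event
  with probability 0.1 (amplification or deletion with equal odds),
  shifting every segment on the arm by one copy from the rounded ploidy;
  neutral arms sit exactly at it.  Arms are fragmented into
  1 + Poisson(1) segments, and adjacent p/q segments with equal copy
  number are merged across the centromere 30% of the time so the
  splitting rule is exercised.  Event probability 0.1 gives a mean AS of
  4.4 and >95% aneuploid samples — an event-rich regime chosen so that
  recovery statistics are estimable from 200 tumors.  Because no noise is
  added to copy numbers, arm scoring must reproduce the planted AS
  exactly; this is asserted for 100% of samples.

* **Methylation.**  Gene-level signal for a planted driver is
  baseline 0.10 + 0.01·AS + N(0, 0.02); null genes have a fixed baseline
  in [0.15, 0.6] plus the same noise.  With sd(AS) ≈ 2 this puts the
  true driver Spearman ρ near 0.7 and the tumor-vs-normal log₂ fold
  change near 0.5 — clearly past the 0.3 gates without being noiseless.
  Each gene gets two probes inside the ±1,000 bp TSS window and one
  outside, plus SNP-flagged, multi-hit and X/Y probes carrying extreme
  beta values, so skipping any filter visibly distorts gene means.

* **Expression.**  Counts are negative binomial (dispersion 0.02,
  log-normal base means around 300, log-normal library sizes,
  sd 0.15 on the log scale).  A planted driver's tumor log₂ mean is
  shifted by −1 plus −15·(its own methylation deviation), so expression
  is coupled to AS *through* methylation, mirroring repressive promoter
  methylation; the realized tumor-vs-normal log₂ fold change is about
  −1.7.  The coupling of −15 log₂ units per beta unit was set once so
  that the planted expression–AS correlation (ρ ≈ 0.5–0.6) clears the
  0.3 selection gate with margin even for low-expressed genes, where
  counting noise is largest; weaker coupling leaves marginal drivers
  whose recovery would measure sampling luck rather than the method.  A
  50-gene co-expression module rises by 0.1 log₂ per AS unit — a
  proliferation-program stand-in used as the positive gene set for
  enrichment checks.

* **Mutation.**  Background genes mutate at per-gene rates in
  [0.005, 0.05] independent of AS; a TP53-like gene mutates with
  probability logistic(−3 + 0.3·AS), recoverable in sign and
  significance at n = 400.

* **Clinical.**  Progression and disease-free times are exponential with
  log-hazard 0.05 per AS unit over baselines of 5·10⁻⁴ and 3·10⁻⁴ events
  per day, censored by an independent exponential (5·10⁻⁴/day) capped at
  ten years; 2% of samples get a survival time ≤ 30 days to exercise the
  cohort filter.  T stage and Gleason pattern scores follow
  ordered-logit models and N/M stage logistic models with slope 0.3 per
  AS unit, anchored so marginal frequencies resemble a localized
  prostate-cancer cohort; age is N(61, 7), uncoupled from AS by default.

* **Confounding switch.**  By default purity and leukocyte fraction are
  independent of AS, so covariate adjustment can be tested against a
  known-null confounder; a confounded mode couples leukocyte fraction to
  AS and methylation to leukocyte fraction, making adjustment change
  coefficients in a predictable direction.

What the generator does **not** emulate: realistic 450K probe densities,
linkage between neighboring genes, tumor subclonality, copy-number
noise, or batch structure.  Passing recovery tests therefore shows the
pipeline's statistics behave as designed under their own model — not
that the thresholds are optimal for any real cohort.

## Preprocessing

Cohort filter: samples must appear in every omics layer and survive
strictly more than 30 days (a sample at exactly 30 days is dropped).
Probe filter: SNP-flagged, multi-hit and sex-chromosome probes are
removed; gene methylation is the mean beta over probes with
|TSS distance| ≤ 1,000 bp (inclusive; the distance is treated as
unsigned).  Expression is normalized by median-of-ratios size factors —
the size factor of a sample is the median, over genes positive in all
samples, of count / geometric mean — implemented directly rather than
through a full differential-expression framework, since only the factors
and the log₂(x+1) matrix are consumed downstream.  Note the factors are
scale-equivariant only up to a common constant: scaling one of n samples
by c moves every per-gene geometric mean by c^(1/n), so factor *ratios*
scale by exactly c while absolute factors drift by c^(−1/n).
TMB is total mutations divided by 38 Mb of captured exome; stroma = 1 −
purity; non-leukocyte stroma = stroma − leukocyte fraction, clamped at 0
with a warning; the SCNA score counts recurrent genes (an externally
supplied list) with non-zero gene-level CNA calls inherited from their
arm.

## Association and selection

Gene-wise models are fitted independently (no moderation or shrinkage):
OLS with an intercept and a two-sided t test on the AS coefficient for
continuous layers, maximum-likelihood logistic with a Wald test for the
mutation layer.  The design matrix is shared across genes, so the normal
equations are solved once and applied to all rows; agreement with a
reference implementation is asserted in tests.  Mutation-layer genes need
≥ 3 mutated and ≥ 3 wild-type samples; perfect separation and
non-convergence are flagged, and flagged genes never reach selection.
Spearman uses average ranks, a t approximation for n > 10 and exact
permutation enumeration for n ≤ 10.  BH adjustment runs within each
layer × covariate-set family.  The covariate set is an explicit
parameter recorded in every output, since composition adjustment
(purity, leukocyte or non-leukocyte stroma, singly or combined) is an
analysis choice, not a constant.  A degenerate cohort with constant AS
flags every record rather than fitting a singular design.

## Enrichment

Preranked GSEA is re-implemented because the ranking — covariate-adjusted
AS coefficients — is the analysis' own construction and must be testable
end to end.  The statistic is the classic weighted running sum with
weight 1: hits add |score|/Σ|scores in set|, misses subtract 1/(N−k),
and ES is the extremal deviation (positive on an exact |max| = |min|
tie).  A hit with score 0 contributes no mass; a set with zero total hit
mass is flagged non-evaluable.  The null permutes gene labels (set
membership), not phenotypes, since the input is a preranked list; the
permutation ES is computed from hit positions alone (the running sum has
local extrema only adjacent to hits), which tests verify against the
full running sum.  p is the same-sign tail with add-one correction, NES
divides ES by the mean |same-sign null ES|, and BH runs across sets.
Ties in the ranking are broken lexicographically by gene id for
reproducibility.  Over-representation of discrete gene lists uses the
upper-tail hypergeometric test.

## Driver discovery

Differential testing is a per-gene Welch t test on the layer's working
scale (beta values; log₂-normalized counts) with fold changes computed
on the positive scale (beta means; normalized-count means with a
pseudocount of 1).  This replaces moderated-variance frameworks
deliberately: at the simulated group sizes (≥ 50 per group) variance
moderation changes little, and the package's contribution is the
intersection logic, which is independent of the test engine.  Direction
(up/down) is assigned only when both the fold-change and q gates pass.

A driver is a gene in the methylation intersection (differential AND
AS-related) whose expression record is in the expression intersection
with the **opposite** direction.  The reverse-direction rule is on by
default — promoter methylation represses — but is a switch
(`require_reverse=False` degrades to a plain intersection) because an
intersection-only variant is a legitimate sensitivity analysis.  The
mutation layer intersects an externally supplied recurrent-mutation list
with AS-associated mutated genes; a frequency-rank fallback exists for
synthetic runs only.  Validation ranks all genes by Spearman correlation
with each driver's expression, tests the ranking against supplied
cell-cycle sets by permutation GSEA, and fits univariable Cox models of
the driver's methylation and expression against each endpoint.

## Survival and clinical tests

Univariable Cox fits require ≥ 10 events and a finite, non-constant
covariate; HR = exp(β) with Wald CI and p.  The Kaplan–Meier median
split assigns ties to the lower group (≤ median), with group sizes
logged; the two groups are compared by log-rank and by a Cox fit on the
group indicator.  Two-sided Fisher 2×2 tests use the probability-mass
ordering convention (sum over tables no more probable than the observed
one); R×C tables use seeded Monte-Carlo sampling under fixed margins
(10⁵ draws by default) with the same ordering convention and an add-one
correction — simpler and directly testable against exhaustive
enumeration on small tables, at the cost of a 1/(draws+1) p floor.  The
clinical battery dispatches by variable type: Spearman plus a
median-split ANOVA for continuous variables (the ANOVA is computed from
per-group n/mean/SD so printed summary tables can be checked directly),
Wilcoxon rank-sum for two-level categories, Kruskal–Wallis for
multi-level ones, and the Fisher test on the score-group × category
table in all categorical cases.  Empty category levels are dropped with
a warning.

## Numerical and reproducibility notes

All randomness flows through numpy Generators keyed on explicit seeds;
the generator derives independent per-stage streams from its seed, and
two pipeline runs with identical configuration produce byte-identical
result tables.  Monte-Carlo p-values carry add-one corrections so they
are never zero.  The reciprocal-covariate Cox invariance and the
log-rank/Wald agreement hold to optimizer tolerance (asserted at 10⁻⁶
and 15% respectively).  Problem sizes in the test suite and the
acceptance script (cohorts of 60–500 samples, 300–2,000 genes, 5–10
replicate seeds, 10³–10⁵ permutations/draws) were chosen as the smallest
scales at which the planted effects are estimable with comfortable
margins.

## Known limitations

Arm calls assume the supplied purity/ploidy and absolute copy numbers
are correct; no recurrence-peak detection (GISTIC-style), no
hotspot-clustering mutation recurrence, no deconvolution, and no
multivariable or competing-risk survival models.  Methylation is modeled
on beta values directly (no M-value transform), matching the selection
recipe the pipeline implements.  The exact-permutation Spearman branch
enumerates up to 10! orderings and is meant for screens of tiny cohorts,
not matrices.
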