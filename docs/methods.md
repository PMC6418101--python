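# Methods

## Scope and model overview

`fibroscreen` models the quantitative chain of an arrayed RNAi screen in
primary dermal fibroblasts with an immunofluorescence readout (ASMA per
nucleus), plus the companion transcriptomic question of how much of a
disease expression signature survives in-vitro passaging. Two analysis
paths share the well-score currency `S = D × A / N`:

1. screen path: well images or score tables → plate QC → percent
   inhibition → cross-donor hit tiers;
2. signature path: log2 expression matrix → batch correction → moderated
   differential expression → retention and fold-change correlation.

## Synthetic data generators

No public data accompany the study design this package targets, so all
inputs are simulated with recorded ground truth. The generators' defaults
are the study conditions, not tuning knobs.

**Well scores** (`simulate_screen`). Negative-control wells have mean score
1.0; positive-control wells `1/fold_separation` (default 3, the middle of
the 2–4-fold window a usable ASMA assay shows); a test shRNA with true
knockdown efficacy `e` has mean `1 − e(1 − 1/fold_separation)`, scaled by a
per-donor lognormal random effect (sd 0.1) representing donor-to-donor
differences in responsiveness. Well noise is multiplicative lognormal with
unit mean and CV `cv_noise` (default 0.10, which places Z′ near 0.4 at
120 wells per arm — inside the reported 0.3–0.6 band without per-donor
tuning). The lognormal parameterisation `σ² = ln(1 + CV²)`, mean-corrected,
makes `cv_noise = 0` exactly noise-free. Each well also carries a
density/area/nuclei decomposition consistent with its score (nuclei ~
Poisson(180) per well-field, density in normalized AU) so table-based and
image-based pipelines interoperate. The optional additive transduction
offset (viral transduction itself can raise ASMA) defaults to 0: no
magnitude is available to calibrate it.

**Knockdown efficacies** (`EfficacyMixture`). shRNA efficacy is a
two-component mixture: with weight 0.8 an efficacious shRNA drawn from
Normal(0.84, 0.10) truncated to [0, 1]; with weight 0.2 a poor silencer
drawn Uniform(0, 0.6). The closed-form tails of this mixture are ≈79%
above 0.60 and ≈64% above 0.75 — the generator is calibrated so a large
panel reproduces the reported "~80% of shRNAs over 60% knockdown, ~65%
over 75%" behaviour. Observed relative expression is `(1 − e)` times
lognormal measurement noise (CV 0.05 by default; 0 disables it).

**Well images** (`render_well_image`). DAPI nuclei are radial Gaussian
spots (σ = r/2.5) truncated at radius r (default 6 px) — compact support
plus a minimum center separation (default 16 px > 2r) guarantees disjoint
connected components, which is what makes exact count recovery a testable
contract rather than a statistical one. ASMA is one elongated anisotropic
Gaussian stroke per cell (stress-fibre bundle) with amplitude proportional
to the requested stain level, so integrated above-background signal is
linear in the level. Noise is shot (Poisson) plus Gaussian read noise
(sd 8 AU) on a 400 AU background, 16-bit range. These images emulate only
what the quantifier consumes: spot-like nuclei, elongated stain, additive
background, sensor noise. They do not emulate cell morphology, illumination
fields, staining heterogeneity within cells, or focus artefacts — passing
tests demonstrate correctness of the quantification contract, not
performance on real micrographs.

**Expression study** (`simulate_expression_study`). Log2 intensities are
`baseline + disease effect + γ(probe, batch) + δ(probe, batch)·ε`. Baseline
means are Uniform(5, 12) (so the average-intensity gate is non-binding by
default); 200 of 2000 probes carry a disease effect with |log2FC| ~
Uniform(0.6, 2.0) and random sign; at passage 4 a fraction ρ = 0.77 keep
the full effect and the rest shrink to 25% of it — attenuated rather than
zeroed, so non-retained probes fail the significance thresholds yet still
correlate weakly, reproducing a strong-but-imperfect baseline/follow-up
fold-change correlation. Batch terms follow the location/scale model the
correction assumes (shift ~ N(0, 0.3), scale ~ Uniform(0.8, 1.25));
replicate samples (default 9, bridging both batches) share their source
sample's biology and differ only in batch terms and residual noise
(sd 0.25). Groups default to 8 SSc vs 8 healthy per passage. Batches
alternate within groups, so batch is never confounded with disease.

Determinism: every generator consumes a single seed, expanded into
independent per-stage streams via `numpy.random.SeedSequence.spawn`, so a
stage can be re-run without disturbing the others.

## Image quantification

Thresholds are Otsu by default (fixed thresholds available); nuclei are
8-connected components above threshold with components under
`min_nucleus_area` (9 px) discarded as debris. A constant channel has no
Otsu threshold: it yields zero nuclei / zero stained area rather than an
error. Touching nuclei merge — under-segmentation is accepted behaviour;
no watershed splitting is attempted. Density is defined as the mean ASMA
intensity **over the suprathreshold stain mask**, not the whole field, so
`D × A` is the integrated suprathreshold intensity and the score is robust
to field size; this is one of two defensible readings of a density × area
product and is flagged for sensitivity analysis. No background subtraction
is applied by default (thresholding absorbs a constant background). Wells
with zero detected nuclei have an undefined score and are excluded (logged
at WARNING) from downstream statistics.

## Screen statistics

- Z′-factor: `1 − 3(σ_neg + σ_pos)/|μ_neg − μ_pos|` with n−1 sample sds —
  the universal screening definition. Invariant to common affine transforms
  of both arms; 1 in the noiseless limit; undefined when arm means coincide.
- Assay window: ratio of negative-control to positive-control mean score;
  the conventional fold-change reading of "assay window".
- Percent inhibition uses means of well replicates (a median variant is
  behind a flag) to stay coherent with Z′, which is mean/sd-based.
- Knockdown summaries count shRNAs *strictly above* each threshold
  ("more than 60%" is read literally).
- Endpoint group differences use Welch's unequal-variance two-tailed t;
  two identical constant groups return p = 1 by convention.

## Hit tiers

Tier definitions count shRNAs crossing per-gene inhibition thresholds
(defaults t_hi = 35%, t_mid = 30%, t_lo = 25%): very_strong ≥ 8 shRNAs
> t_hi; strong ≥ 2 shRNAs > t_hi; moderate ≥ 1 shRNA > t_hi and ≥ 1 in the
open interval (t_lo, t_mid); weak ≥ 3 shRNAs in (t_lo, t_hi); else none.
Decisions made where the tier language was descriptive rather than
definitional:

- precedence is very_strong → strong → moderate → weak, so a gene gets its
  best-supported label (a gene with 8 high shRNAs satisfies "strong" too
  but is reported very_strong);
- "more than"/"less than" are strict inequalities; (25, 30) and (25, 35)
  are open intervals;
- the very-strong count (8) is configurable — it matches the one described
  exemplar rather than a stated rule;
- a gene with one shRNA > 35% and nothing in (25, 30) — e.g. [36, 24] — is
  *none*: the moderate tier's mid-low witness is required. This makes the
  moderate tier non-monotone by design (raising the mid shRNA past t_mid
  destroys the witness); the monotonicity property is asserted only for
  the monotone tiers.
- cross-donor averaging is unweighted even under unequal well counts, and
  ranking ties break lexicographically by shRNA id (stable, documented).

The classifier is verified against an independently coded brute-force
predicate evaluator on random vectors (hypothesis + a 10,000-vector sweep).

## Batch correction

Parametric ComBat: per-probe OLS with batch indicators and the disease
covariate; standardisation by the size-weighted grand mean and pooled
residual variance; per-(probe, batch) location/scale estimates shrunk with
moment-matched priors (normal on γ, inverse-gamma on δ²) via the iterative
posterior solution (tolerance 1e-8, ≤ 200 iterations); adjustment and
rescaling with covariate effects restored. Batch perfectly confounded with
the covariate raises an error; a single batch is a no-op. The test suite
pins the output against `sva::ComBat` values (frozen from R 4.3 /
sva 3.50) at ~1e-7 on a seeded fixture, and checks the behavioural
contracts: additive shifts removed, cross-batch replicate distances
strictly reduced, contrast estimates unbiased (mean log2FC shift < 0.05).

## Moderated differential expression

Per-probe two-group fit (pooled two-sample variance) or paired one-sample
fit on within-donor differences. The variance prior (d0, s0²) is fitted by
moment matching on log sample variances (digamma/trigamma moments, Newton
trigamma inverse); homogeneous variances give d0 = ∞ (complete pooling),
and all-constant data degrade to a positive floor prior so shrunken
variances never vanish. Moderated t uses d0 + residual df; p-values are
two-sided; q-values are Benjamini–Hochberg over all probes (via
statsmodels). The log-odds statistic uses the standard posterior-odds form
with the coefficient-variance hyperparameter estimated from the top-|t|
fraction of genes, bounded so the prior coefficient sd stays within
(0.1, 4) residual-sd units; the prior DE proportion defaults to 0.01 —
it is nowhere specified for this assay, and the lods > 0 gate mainly trims
marginal calls. All of d0, s0², the coefficient prior, per-probe t/p/lods
and the significant-set size are pinned against `limma::eBayes` (frozen
from R 4.3 / limma 3.58) on the same fixture.

The composite significance rule is conjunctive with strict inequalities:
lods > 0, |log2FC| > log2 1.5, q < 0.01, mean log2 intensity > 4. Whether
the lods gate is evaluated before or after FDR adjustment does not change
the intersection; it is applied jointly.

## Signature retention

Retention is `100 × |baseline ∩ follow-up| / |baseline|` over probe sets
(probes are the computable unit; reporting rounds to integer percent), and
the fold-change correlation is Pearson's r over the union of the two DEG
sets using each analysis's full fold-change vector. An empty baseline set
makes retention undefined (error). Probe-to-gene collapsing (max-|log2FC|
probe per gene) is applied only when a probe→gene map is supplied.
Replicate bridge samples are used for the batch fit and then dropped before
DE, as is an explicit exclusion list in the pipeline config — outlier
removal is a deliberate input, never automatic.

## Problem sizes and verification

The default study (2000 probes, 200 signature, 8 + 8 per passage, ρ = 0.77)
gives ≥ 90% baseline signature recovery at noise sd 0.25, and the measured
retention tracks the planted ρ: over 20 seeds the mean absolute deviation
from 77% is ~2 points (asserted within ±7). Null data (no planted effects,
6 vs 6) yield ≤ 0.2% of probes past the composite rule. The screen QC
simulation uses 12 donors × (120 + 120) control wells; the knockdown panel
1000 shRNAs. These sizes run the whole suite in seconds while keeping the
law-of-large-numbers checks (window within 10% of truth at n = 120)
meaningful.

## Known limitations

- Per-field quantification only: no per-cell ASMA assignment, watershed
  splitting, or illumination correction; vendor-software behaviour is not
  reproduced.
- The image generator's simplicity means image-path results validate the
  scoring contract, not segmentation robustness on real data.
- Hit tiers are descriptive classifications; no significance testing or
  multiple-testing control is applied to hits, mirroring rank-and-tier
  practice.
- The expression generator draws batch effects from the same family the
  correction assumes; it cannot reveal ComBat's behaviour under model
  misspecification.
- No raw-array (CEL/GCRMA) processing, array QC, PCA outlier detection,
  GSEA or pathway enrichment: the pipeline starts at normalised log2
  matrices and ends at DEG-set comparisons.
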