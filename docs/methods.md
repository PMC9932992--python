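# Methods

## Dosage-response model

Per-gene expression (median-of-ratios-normalized counts, untransformed) is
fit by OLS against inactive-X count, Y count, and batch. Model classes and
sample subsets:

| class    | subset              | predictors                         | intercept represents |
|----------|---------------------|------------------------------------|----------------------|
| NPX_PAR  | all samples         | #Xi, #Y, batch                     | 45,X                 |
| NPY      | y ≥ 1               | #Xi, #Y − 1, batch                 | 46,XY                |
| CHR21    | 46,XX / 46,XY / +21 | #21 − 2, sex(XY), batch            | 46,XX                |
| XIST     | x ≥ 2               | #Xi, #Y, batch                     | one Xi               |

`ΔE_X = β_X/β₀_avg` with `β₀_avg` the batch-averaged intercept, weighting
each batch *level* equally (the reference level's offset is zero); this is a
switchable convention — a per-sample weighting would differ only under
unbalanced batches. `ΔE_21` divides by `β₀_avg/2` (one chromosome's share of
a disomic baseline) and the XIST variant divides by `β₀_avg + β_X`
(expression at one Xi). Significance of a ΔE is the two-sided t test of its
regression coefficient — not of the ratio — BH-adjusted across genes with
FDR < 0.05 as the significance rule.

**Standard errors.** The reported `se` is the exact delta-method SE of the
coefficient ratio, using the full OLS coefficient covariance including
Cov(β_X, β₀_avg). The covariance-free product form
`(β_X²/β₀²)(S_X²/β_X² + S_0²/β₀²)` — a ratio-of-independent-estimates
propagation, interpreted as a variance — is also reported (`se_product`).
In parametric experiments (40 replicate cohorts, escape gene f = 0.45) the
empirical sd of `ΔE_X` was 0.049 vs 0.052 predicted by the exact delta
method and 0.041 by the product form; the product form understates the SE
for positive-response genes because slope and intercept are negatively
correlated, which would anticonservatively narrow the 1.96·SE exclusion
interval in the modulation test. The exact form is therefore used
downstream. Per-gene OLS is vectorized closed-form least squares
(normal-equations solve); tests verify equality with brute-force normal
equations to 1e-8.

Bootstrap intervals resample samples with replacement (redrawing a
resample, up to a retry cap, when it loses a dosage level or design rank)
and take percentile bounds; 200 resamples are used in the standard checks.
Saturation analysis subsamples the cohort without replacement (100
replicates per size by default) and counts FDR < 0.05 genes. Sex-stratified
fits drop the Y term within the y = 0 and y = 1 strata; note that a genuine
additive per-Y effect is then absorbed into the male baseline, so the male
stratified `ΔE_X` equals `(f+m)/(1+y_eff)` by construction (on real data,
Y effects on X-linked genes are near zero and the strata agree).

## Normalization and expression filter

Size factors are median-of-ratios: reference genes are those with strictly
positive counts in every sample; each sample's factor is the median (even
counts: midpoint average) of count/geometric-mean ratios, rescaled to
geometric mean 1. This rescale means a global rescaling of one sample
redistributes a factor `c^(1/n)` across all samples; normalized values are
invariant up to that single constant. TPM uses caller-supplied gene lengths
(`10⁶·(count/length)/Σ(count/length)`); which transcript length defines a
gene is the caller's responsibility. A gene is expressed in a cell type
when its median TPM in 46,XX *or* 46,XY samples is ≥ 1 (boundary
inclusive); an explicit allow-list represents externally rescued borderline
genes; the cross-cell-type union is also reported.

## Linearity

Per-gene values are normalized to the single-copy reference (one X for NPX,
45,X for PAR, one Y for NPY) and fit by Levenberg–Marquardt to
`y* = 1 + b(copies−1)^a` from the start (b, a) = (0.5, 1), with `0^a := 0`
for a > 0 and `0^0 := 1`. Non-convergence is reported as a flag, never an
exception; two distinct copy levels leave (a, b) jointly unidentifiable and
are reported as such. Classification uses artifact-defined thresholds
(configurable): flat if |b| ≤ 0.05 or |a| ≤ 0.1, linear if |a − 1| ≤ 0.25,
else nonlinear. On noiseless model data the fitter recovers
(a, b) ∈ [0.25, 3] × [0.05, 1.5] to better than 1e-6; with NB dispersion
0.05 the exponent estimate has sd ≈ 0.18 for weak escape (f ≈ 0.3) and
≈ 0.08 for strong escape, so near-perfect linear classification is expected
only in the strong-escape regime.

## Allele-specific analysis

Informative SNPs: in an expressed gene, total coverage ≥ 10, each allele
≥ 3 reads, not in a configured artifact-gene list, and PAR SNPs dropped in
samples carrying a Y. Xa-only genes (prior XCI status Subject, ΔE_X < 0.05,
FDR > 0.5) calibrate per-sample skew: the coefficient is the median
dominant-allele fraction over their SNPs (exact ties contribute 0.5);
samples at ≥ 0.8 are skewed. Samples with ≤ 5 Xa-only SNPs but ≥ 20 SNPs
overall ("many", quantified here since no number is stated in the source
annotations) are interpreted as fully skewed (coefficient 1) — complete
skew leaves Xa-only genes monoallelic and hence filtered out. A Monte-Carlo
null (balanced binomial alleles) bounds the false skew-call probability;
at depth 50 with 100 SNPs no false call is observed in 10⁶ replicates, and
the single-SNP case equals the closed-form binomial tail 2·P(Bin(10,½) ≥ 8)
= 0.109.

Per SNP, AR = min/max of allele counts; the skew adjustment
`(AR − AR·t − t)/(1 − t − AR·t)` with `t = 1 − coefficient` is the exact
algebraic inverse of the two-population mixture (verified to 1e-12 on an
(ar, t) grid). Adjusted values below zero are retained, not clamped, so the
t tests stay unbiased; genes need ≥ 3 informative skewed samples. Xi
expression is a one-sided t test of mean AR > 0 (zero-variance, zero-mean
genes get p = 1), BH-adjusted, FDR < 0.05.

## Modulation calls

Per gene, a two-sided one-sample t test of per-sample ARs against
μ = ΔE_X; BH across tested genes within a cell type; `ar_ne_dex` requires
adjusted p < 0.1, mean AR outside ΔE_X ± 1.96·SE, and not both ΔE_X and AR
individually non-significant. `discordant_with_prior` flags significantly
positive ΔE_X on a gene annotated Subject, or any significantly negative
ΔE_X. The modulated set is the union of the two flags; categories
(silent_additive, escape_additive, modulated_no_escape,
escape_and_modulated) follow AR significance and the divergence flag, with
"≈ 0" meaning FDR ≥ 0.05.

The consensus XCI annotation applies Subject rules before Escape rules:
all-Subject; majority-Subject with average AR < 0.1; majority-Escape;
minority-Escape with more than one escaping study or average AR ≥ 1 (a
nearly vacuous bound — AR is capped at 1 — kept verbatim and warned on);
then the rodent-hybrid fallback (< 0.22 → Subject, ≥ 0.22 → Escape, absent
→ NoCall). The printed rules do not cover every informative pattern (e.g.
one Subject + one Escape study with intermediate average AR); such patterns
return NoCall so the function is total, verified by exhaustive enumeration.
Per-study calls consume pre-extracted numeric summaries (AR with CI lower
bound; bulk/single-cell significance flags; per-sample Xa fractions
converted via AR = 1/frac − 1 with the 0.0526 per-sample threshold;
adjusted p with the 0.01 rule).

## Constraint and drivers

Metric orientations: LOEUF and RVIS low = constrained; pHI and P_CT high =
constrained. Percentiles are average-rank/n × 100 within group (NPX vs
autosomal + PAR ranked separately), after removing ampliconic genes and
LOEUF entries with < 10 expected LoF variants; the aggregate score is the
unweighted mean over ≥ 2 available metrics. NPX candidates need
|ΔE_X| ≥ 0.1 with FDR < 0.05 in *either* cell type (union); the top ten by
aggregate percentile are reported. PAR1 candidates need an aggregate
percentile ≥ 50 in the autosomal + PAR group.

## Synthetic data

The generator is the forward model the analysis inverts. Defaults, chosen
once as study conditions:

- **Cohort designs**: the 106-sample LCL and 99-sample fibroblast
  karyotype tables; batches assigned round-robin within karyotype
  (4 batches), per-batch multiplicative effects lognormal(sd 0.15),
  per-sample library-size factors lognormal(sd 0.3).
- **Counts**: negative binomial (Gamma–Poisson), mean
  `depth·batch·L·(1 + (f+m)·#Xi + y_eff·#Y)`, gene dispersion 0.05 (a
  typical bulk-RNA-seq biological CV of ~22% at high expression; the source
  analysis states no count noise model, so this is the package's choice).
  Dispersion 0 yields rounded noiseless means, so exact-recovery tests are
  possible. An XIST-like gene has baseline 0 and mean proportional to Xi
  count. True ΔE_X is additive (f + m); interactions are not simulated.
- **Background**: 4000 dosage-inert autosomal genes accompany the X panel
  so that size-factor estimation sees a transcriptome in which responsive
  genes are a few percent, as in real data; with an X-only panel the
  median-of-ratios factors absorb part of the dosage signal and bias ΔE_X
  downward.
- **Skew**: two-X samples draw skew from a 50/50 mixture of U(0.5, 0.65)
  (unskewed) and U(0.8, 1.0) (skewed), exercising both branches of the
  caller.
- **Allelic reads**: every SNP heterozygous, thinned by a 0.2 dropout to
  emulate homozygous-site ascertainment loss; 5 SNPs per gene at fixed
  depth 100; allele weights `s(1+m) + (1−s)f` vs `sf + (1−s)(1+m)`.
  Inter-individual escape variability is modeled by drawing each sample's
  Xi output as f·LogNormal(−cv²/2, cv) with cv = 0.25 (escape is known to
  vary between individuals; without it per-sample ARs are unrealistically
  noiseless and the divergence t test over-fires on tiny estimation gaps).
- **Modulation panel**: for trans-modulation studies, 70% of genes are
  silenced (f = 0) and 30% escape with f ~ U(0.1, 0.5), mirroring the
  observed X landscape (most genes silenced; escape mostly partial); half
  the genes carry |m| ∈ [0.2, 0.3] with random sign, constrained so
  expected counts stay positive at three Xi.
- **Constraint metrics**: synthetic LOEUF/RVIS/pHI/P_CT tables with planted
  extreme-constraint genes for recovery tests; real analyses consume
  published tables.

What the simulator does **not** capture: gene-specific batch interactions,
isoform structure, mosaicism beyond the two-population mixture, read-level
artifacts, correlated noise between the count and allelic layers, and
genuine biological escape distributions beyond the simple mixtures above.
Passing recovery tests therefore demonstrates estimator correctness under
the stated model, not robustness to every real-data pathology.

## Problem sizes and measured behavior

The standard checks use the 106-sample design with 200-gene panels,
dispersion 0.05, depth 100, 200 bootstrap resamples, and 10⁶ Monte-Carlo
replicates for the skew null; the modulated-gene operating characteristics
are pooled over four independent cohorts (the per-cohort estimate of a
~0.07 rate over 100 negatives is binomially noisy). All quantities reported
in `results/acceptance.json` are computed fresh at run time by
`scripts/acceptance.py`.

## Known limitations

- OLS on untransformed normalized counts (the fitted procedure) is
  heteroskedastic under NB noise; coefficient SEs are classical, so
  per-gene SEs for strong responders are mildly optimistic even with the
  exact ratio propagation.
- The per-SNP min/max allelic ratio folds noise downward near AR = 1 and
  carries a small positive Jensen bias (~0.01 at depth 100) from the ratio
  transform; both are properties of the printed estimator.
- Highly skewed samples assume coefficient exactly 1; if their true skew is
  slightly lower, their ARs are slightly overestimated.
- One library per sample row is assumed; technical-replicate collapsing is
  out of scope.
- p values for ΔE come from the coefficient t test; a model-comparison test
  would differ slightly. The choice is isolated in one function.
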