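# Methods

This note documents the statistical models implemented in `dpscore`, the
estimation choices behind them, what the synthetic-cohort generator does
and does not emulate, and the known limitations.

## Progression model

### Model and assumptions

Biomarker *j* on subject *i* at time *t* (years from study entry, starting
at 0) follows

    Y_ij(t) = g_j(t + γ_i) + α0_ij + α1_ij·t + ε_ij(t),

with a monotone population curve `g_j` per biomarker, a subject time shift
`γ_i` shared across biomarkers (the disease progression score), a subject
random intercept and slope per biomarker, and i.i.d. Gaussian noise. The
substantive assumptions are: (i) every subject traverses the same
long-term trajectory, differing only in where along it they are observed
and in a small linear offset; (ii) the trajectories are monotone —
appropriate for markers like amyloid burden (rising) and hippocampal
volume (falling) over the course of a neurodegenerative disease; (iii)
biomarkers are made comparable by Z-normalization against the healthy
controls, `Z_ij = (Y_ij − μ_j)/σ_j` with control-only moments.

### Identifiability

The likelihood is invariant under `γ → γ + c, g(·) → g(· − c)` and nearly
invariant under the time rescaling `γ → cγ, g(u) → g(u/c)` (the latter is
broken only by the fixed within-subject visit spacing). The per-subject
linear effects are confounded with the local slope of the curve. Three
devices resolve this: shifts are re-centred to mean zero after each
iteration with the curve knots translated accordingly (curves anchored at
t = 0); a ridge penalty (default 0.1 in squared Z-units) shrinks the
random effects toward zero; and an explicit line search over the global
time scale is part of each iteration (below).

### Curve representation

Each `g_j` is a cubic B-spline with 15 interior knots spaced **uniformly**
over the current support (the range of shifted observation times), with
monotonicity enforced through ordered spline coefficients — a
non-decreasing (non-increasing) coefficient vector yields a monotone
spline, and the fit is a bounded linear least-squares problem solved
exactly (`scipy.optimize.lsq_linear`) with a tiny ridge (1e-8) on the
coefficient increments for conditioning. Uniform knots matter: quantile
placement starves the sparsely observed plateau tails of resolution, and a
curve error of 1e-3 Z-units where the slope is 1e-2 Z/year displaces a
subject by a tenth of a year. Outside its support a curve evaluates to its
boundary value (constant extrapolation), which preserves monotonicity and
keeps shift searches finite.

### Estimation

Fitting alternates, per iteration:

1. **Curve refit** per biomarker on shift- and effect-adjusted points;
   the old curve is retained when the new knot layout fits worse.
2. **Shift re-estimation** per subject: a coarse grid (0.25-year steps
   over ±25 years) followed by bounded scalar refinement (tolerance
   1e-5 years) of the alignment error Σ_j Σ_t (Z − g_j(t+γ))², with ties
   broken toward the smallest |γ| and a no-worsening safeguard.
3. **Random-effect update**: exact ridge regression of the residual on
   [1, t]; single-visit subjects get slope 0.
4. **Global time-scale line search**: the objective is evaluated along
   `γ → cγ, g(u) → g(u/c)` for c near 1 and the best rescaling applied.
   Without this step the alternating scheme creeps along the near-symmetry
   and converges to a time-compressed solution.
5. **Re-centring** of shifts to mean zero.

Every step either minimizes its block exactly or is guarded by an explicit
comparison, so the penalized objective (residual sum of squares plus the
ridge penalties) is non-increasing across iterations; the model records
this trace (`objective_trace`, with the unpenalized `rss_trace`
alongside). Convergence is declared when no shift moves more than 1e-3
years (default; the scale step does not count toward this measure), with a
400-iteration cap.

**Initialization.** Starting from all-zero shifts converges to a
compressed local optimum. Instead, the within-subject regression slope as
a function of the subject's mean level traces `g'` as a function of `g`
along the curve; integrating the reciprocal of the (level-binned,
median-smoothed, floor-clamped) slope over level reconstructs the
long-term time axis up to an additive constant, and each subject's mean
level then maps to a scale-correct starting shift. The start is anchored
to the mean observation time so that translating all visit times by c
shifts the fit by −c.

**Tail polish.** The curve beyond the second-outermost subject is shaped
almost entirely by the outermost subject's own points, so an early
misplacement can co-adapt with the curve tail into a self-consistent local
optimum. After convergence, the most extreme 8% of subjects are
re-estimated against curves refit *without* them (leave-one-out), for up
to 30 rounds. Because a slightly compressed configuration can have a
marginally *lower* penalized objective than the decompressed truth (a
shorter support is easier for the spline), the polish is accepted if the
objective rises by less than 1e-5 per observation — enough to admit the
de-biasing (~1e-8/observation in practice) while rejecting noise-driven
tail instability (~1e-2/observation), which triggers a full revert.

### Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `gamma_bounds` | ±25 y | shift search interval; must exceed the plausible shift range or extreme subjects are censored at the boundary |
| `coarse_step` | 0.25 y | first-stage grid resolution |
| `ridge` | 0.1 | shrinkage of (α0, α1); 0 lets intercepts absorb the shift signal |
| `n_interior_knots` | 15 | curve flexibility; fewer knots bias the tails |
| `tol` / `max_iter` | 1e-3 y / 400 | convergence; noisy cohorts may reasonably use 5e-3 |
| `polish_tail_fraction` | 0.08 | share of extreme subjects polished |

## Synthetic cohorts

The generator draws `γ ~ N(0, 5 y)`, random effects `α0 ~ N(0, 0.2)`,
`α1 ~ N(0, 0.05/y)`, noise 0.3 Z-units, and observes two shifted sigmoids
— amyloid-SUVR-like rising early (inflection +2 y, rate 0.30/y) and
hippocampal-volume-like falling later (inflection +5 y, rate 0.40/y) — at
six visits over four years with 10% missingness. These were chosen once as
a plausible cartoon of an aging/dementia imaging cohort: trajectories
overlap heavily across subjects, and a four-year window sees only a small
arc of a ~30-year process. Genotypes are Hardy-Weinberg draws in
five-variant LD blocks (block members copied from the block seed with 10%
per-subject redraw); one causal variant (MAF 0.3) adds 2 years per minor
allele to γ. Covariates (age 74 ± 7.5, 45% female, education 16 ± 2.7,
two standard-normal ancestry PCs, APOE-ε4 count binomial with allele
frequency 0.25) are independent of γ unless confounding is switched on.
Diagnosis labels come from γ-quantile bands (35% / 50% / 15%) with 10%
label noise. Conversion and death are exponential (0.08/y and 0.04/y) with
administrative censoring at 10 years and a carrier hazard ratio of 0.6 on
conversion.

One global seed feeds a splittable generator with a fixed stream per
sub-simulation, so identical configurations reproduce byte-identical
outputs and adding variants never perturbs the trajectories.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: realistic visit schedules and dropout
processes, scanner and site effects, genome-wide LD maps and allele
frequency spectra, ancestry structure correlated with phenotype,
non-sigmoid or non-monotone biomarkers, and informative censoring.

## Imaging measures

The SUV of a region is the weighted **mean** of PET intensities — weights
are voxel-wise grey-matter probabilities for the cortical target,
uniform for the composite reference region (white matter, whole
cerebellum, brainstem, pons) — normalized by the total weight so the SUVR
is independent of region size and of any weight rescaling; a `raw_sum`
mode provides the unnormalized reading. Amyloid positivity is SUVR
strictly greater than 0.7585. Hippocampal volume is normalized by total
intracranial volume. No registration, segmentation or smoothing is
performed here; inputs are assumed voxel-aligned.

## Genotype QC

Hard calls require a genotype posterior ≥ 0.9 (boundary inclusive).
Variant filters (MAF < 5%, call rate < 90%, Hardy-Weinberg exact p
< 5.7e-7) apply before subject filters (missingness ≥ 10%), in that
order. The Hardy-Weinberg test is the exact conditional test computed by
the stable heterozygote-count recurrence; a chi-square variant is
deliberately not offered since the exact test is uniformly preferable at
these sample sizes. Relatedness pruning computes the genetic relationship
matrix from standardized dosages and greedily drops, from each pair above
the 0.1 cutoff, the member with the larger total relatedness (ties by
subject id). The GRM assumes approximately independent variants; on
LD-dense panels it should be computed on an LD-thinned subset.

## Association

Each variant is tested by OLS of the phenotype on [1, dosage, covariates]
with a two-sided t-test on the dosage coefficient (residual degrees of
freedom, not a normal approximation). Subjects with missing dosage are
dropped per variant. The scan uses a residualization (Frisch–Waugh) fast
path that is numerically identical to the per-variant fit. Thresholds:
genome-wide 5e-8, suggestive 1e-5. The sex-stratified test fits each
stratum separately (male X dosages coded {0, 2}) and combines signed
Z-statistics with √n Stouffer weights. Genomic λ is the median association
chi-square over the null median chi-square.

## Risk scores

Scores sum effect-allele dosage × external effect size over variants
selected by p-value thresholding (15 log-spaced thresholds, 1e-5–0.95)
after exclusion of the extended APOE region (chr19:44,400,000–46,500,000,
closed interval, hg19) and greedy LD clumping (r² ≥ 0.2 within ±1000 kb,
smallest p first). Missing dosages are mean-imputed; effect alleles are
reconciled to the dosage coding, flipping to `2 − dosage` when the effect
allele is the other allele. The effective number of independent tests is
the smallest k whose top-k eigenvalues of the correlation matrix reach
99.5% of the total variance.

## Competing risks

The cumulative incidence of conversion with death competing is the
Aalen–Johansen estimator, computed so that CIF(conversion) + CIF(death) +
overall survival ≡ 1 at every step by construction. The carrier effect
(minor-allele heterozygotes plus homozygotes versus non-carriers — a
dichotomization chosen for low-MAF variants) is estimated by Fine–Gray
subdistribution-hazard regression: subjects with a competing event remain
in the risk set with inverse-probability-of-censoring weights
G(t−)/G(T_i−) from the Kaplan–Meier estimate of the censoring
distribution, and the weighted partial likelihood (Breslow tie handling)
is maximized by Newton–Raphson. Coefficients agree with `cmprsk::crr` to
numerical precision; the reported Wald standard errors use the inverse
observed information, which is slightly anti-conservative relative to the
sandwich variance that also accounts for the estimated weights. With no
competing events the estimator reduces exactly to Cox regression. Cohen's
d uses the (n−1)-weighted pooled SD with a normal-approximation 95% CI
(noncentral-t available); group comparisons use one-way ANOVA with Tukey's
range test.

## Numerical conventions and degenerate inputs

Shift ties (flat curves) resolve to the smallest |γ|. Subjects missing a
biomarker entirely are scored from the remaining biomarkers. All-missing
variants get undefined MAF/HWE and zero call rate. Logistic risk-score
fits flag separation with p = NA rather than failing. The amyloid cutoff
is exclusive at the boundary; the hard-call threshold is inclusive. The
APOE exclusion interval is closed on both ends.

## Limitations

- A subject whose entire observation window lies beyond every other
  subject's shifted window has no overlap with the cohort; their shift is
  only bounded, not identified, and lands at the boundary of the
  informative region. No non-parametric method can do better without
  extrapolating the curve shape.
- No uncertainty intervals on γ are produced; the model is a fixed-effects
  alternating least-squares fit, not a marginal-likelihood mixed model.
- The per-iteration monotone-descent guarantee applies to the penalized
  objective; the tail polish is a separately-guarded de-biasing stage.
- The GWAS assumes an externally QC'd, unrelated cohort; mixed-model
  association and dosage (non-hard-call) data beyond pass-through are out
  of scope.
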