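# dpscore

Multimodal disease-progression scores and their genetic analysis, in one
testable Python package.

Neurodegenerative diseases such as Alzheimer's unfold over decades, while a
study observes each participant for only a few years. `dpscore` estimates,
from short-term longitudinal biomarker measurements, both the population's
long-term biomarker trajectories and each subject's position along them.
That position — a time shift in years, the *disease progression score*
(DPS) — is then usable as a quantitative phenotype. Around this core the
package provides the full analysis stack a genetic study of such a
phenotype needs: amyloid-PET SUVR computation, genotype quality control,
additive-model GWAS with inflation diagnostics, genetic risk scores with
LD clumping, effect-size summaries, and competing-risks conversion
analysis. A seeded synthetic-cohort generator makes every stage testable
end to end without access-controlled data.

It is written for quantitative researchers in imaging genetics and
biostatistics who want a transparent, scriptable implementation rather
than a pipeline of opaque binaries.

## The model

Each biomarker *j* observed on subject *i* at time *t* (years from study
entry) is modelled by self-modelling regression:

```
Y_ij(t) = g_j(t + γ_i) + α0_ij + α1_ij · t + ε_ij(t)
```

where `g_j` is a monotone long-term curve shared by the population (fit as
a cubic B-spline with ordered coefficients), `γ_i` is the subject-specific
time shift (the DPS), `(α0_ij, α1_ij)` are a per-subject random intercept
and slope shrunk toward zero by a ridge penalty, and `ε` is observation
noise. Biomarkers are first Z-normalized against the healthy controls,
`Z_ij = (Y_ij − μ_j)/σ_j`. Fitting alternates curve refits, per-subject
shift searches, and effect updates; the shifts are re-centred to mean zero
each iteration so the curves stay anchored at t = 0. Identification,
initialization and the tail-polish stage are documented in
[docs/methods.md](docs/methods.md).

Downstream, the DPS (or SUVR, or normalized hippocampal volume) enters an
additive-model GWAS `phenotype ~ dosage + covariates`, genetic risk scores
`GRS_i = Σ_k dosage_ik · β_k` over LD-clumped summary statistics, and a
Fine–Gray subdistribution-hazard regression of conversion risk with death
as a competing event.

## Worked example

```bash
python examples/02_fit_progression_model.py
```

```
converged              : True after 242 iterations
penalized RSS          : 207.9 -> 187.9
corr(true, estimated)  : 0.938
DPS range              : -11.1 to 11.8 years (mean 4.74e-17)
  subject_id  dps_years
0      S0000  -1.002678
1      S0001   6.098745
...
```

On a 150-subject synthetic cohort (two biomarkers: an amyloid-SUVR-like
sigmoid rising early and a hippocampal-volume-like sigmoid falling later;
observation noise 0.3 Z-units), the fitted shifts correlate at 0.94 with
the latent shifts used to generate the data, and the per-iteration
penalized residual sum of squares decreases monotonically. The mean-zero
DPS column is the quantitative phenotype passed to the association stages.

The other scripts in `examples/` walk through each capability — cohort
simulation, genotype QC, GWAS, risk scores, competing risks, and SUVR —
each printing the numbers it computes and a line on how to read them.

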