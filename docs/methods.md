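# Methods

## Model and notation

Two-sample summary MR treats each of J independent genetic variants as an
instrumental variable.  Variant j carries an instrument–exposure
association γ̂_j with standard error σ_Xj (estimated in the exposure GWAS
sample) and an instrument–outcome association Γ̂_j with standard error
σ_Yj (estimated in a different sample).  Under the instrumental-variable
assumptions, the structural relation is

    Γ_j = β γ_j + α_j,

where β is the causal effect of the exposure on the outcome and α_j is
variant j's direct (pleiotropic) effect on the outcome.  The per-variant
ratio estimate β̂_j = Γ̂_j/γ̂_j is assigned the first-order variance
σ²_Yj/γ̂²_j, which ignores σ_Xj — the NOME (no measurement error)
approximation.  All estimator weights derive from this variance.

A note on conventions: γ̂ always denotes the exposure side and Γ̂ the
outcome side, so the IVW weight is w_j = γ̂²_j/σ²_Yj throughout.

## Estimators

**IVW.**  β̂ = Σ w_j β̂_j / Σ w_j.  The point estimate is invariant to the
inference model.  Default inference is *multiplicative random effects*:
the fixed-effect SE 1/√(Σ w_j) is scaled by max(1, √(Q/(J−1))) — Cochran's
Q about the IVW estimate — with a t(J−1) reference.  Over-dispersion
widens the interval, under-dispersion never narrows it below the
fixed-effect width.  A fixed-effect variant (unscaled SE, normal
reference) is available.  At J = 1 the estimator is the ratio estimate and
random-effects scaling is undefined, so it falls back to fixed with a
warning.

**MR-Egger.**  Weighted least squares of Γ̂_j on γ̂_j, weights 1/σ²_Yj,
free intercept.  Default inference mirrors IVW: residual scale
max(1, √(RSS/(J−2))), t(J−2) reference; `fixed_se=True` forces unit scale
and a normal reference.  The fit is closed-form (2×2 normal equations)
rather than delegated to a regression library because SIMEX refits the
same model tens of thousands of times and the vectorized closed form makes
that cheap; the test-suite cross-checks coefficients and standard errors
against statsmodels WLS.  Unlike IVW/median/mode, the Egger fit is not
invariant to per-variant allele recoding (joint sign flips), so the
orientation of the data is part of the model: the default fits the data
as supplied (`orient="as_is"`), and `orient="positive_exposure"` recodes
all exposure associations to be non-negative first — under that option
the fit is recoding-invariant.  At least 3 variants are required.

**Median.**  Ratios are sorted; with normalized weights w_(j) and partial
sums s_j, ratio j sits at percentile p_j = 100(s_j − w_j/2); the estimate
interpolates the (p_j, β̂_j) polyline at the 50th percentile, clamping to
the extreme ratios when 50 falls outside [p_1, p_J].  Weights: 1/J
(simple) or w_j = γ̂²_j/σ²_Yj (weighted — the NOME-form ratio precision).
The penalized variant first computes the weighted median, forms each
variant's Q contribution about it, converts it to an upper-tail χ²₁
probability q_j, multiplies each weight by min(1, 20·q_j) and re-computes
the weighted median once.  The penalty constant 20 is the established
choice for this estimator and is exposed as a parameter; if every variant
is fully penalized (a degenerate configuration) the penalization is
dropped rather than returning an undefined estimate.

**Mode.**  The estimate maximizes a Gaussian-kernel density of the
ratios, evaluated on a 10 000-point grid spanning the ratio range padded
by two bandwidths; ties break to the smallest grid value (first argmax).
Bandwidth h = φ · 0.9 · min(SD, MAD/0.6745) · J^(−1/5) with φ = 1 by
default; MAD falls back to SD when zero (and vice versa), and when both
vanish the common ratio is returned directly.  `weighted=True` weights
each kernel by the variant's normalized inverse ratio variance.  The mode
is consistent under zero modal pleiotropy — the largest group of variants
sharing a ratio value must be the valid ones — which is weaker than the
median's majority condition but makes the estimate bandwidth-sensitive:
when a minority of valid variants forms a sharp spike against a broad
invalid continuum, φ well below 1 (e.g. 0.25) is needed for the spike to
win, and inverse-variance weighting can favour strong invalid instruments;
the robustness test therefore uses the unweighted mode at φ = 0.25.
The density plot and the estimator share one code path, so the plotted
argmax always equals the returned estimate.

**Bootstrap standard errors (median, mode).**  Parametric bootstrap:
resample γ̂*_j ~ N(γ̂_j, σ²_Xj) and Γ̂*_j ~ N(Γ̂_j, σ²_Yj), recompute the
full estimator (including penalization / bandwidth / grid), and take the
SD over n_boot replicates (default 1000; a seed is required — there is no
silent clock seeding anywhere in the package).  Inference for these
estimators uses a normal reference with the bootstrap SE.  P-values are
two-sided throughout.

## Diagnostics

**Cochran's Q.**  Q = Σ w_j(β̂_j − β_ref)² with the IVW weights, df = J−1,
p from χ²_{J−1}; I² = max(0, (Q − df)/Q), truncated at zero and reported
in [0, 1).

**I²GX.**  Q_GX = Σ (γ̂_j − γ̄_w)²/σ²_Xj about the 1/σ²_Xj-weighted mean,
returning max(0, (Q_GX − (J−1))/Q_GX).  Interpreted as the expected
relative attenuation of the Egger slope under NOME violation (0.9 ⇒ ~10%
bias toward the null).  The weighted-mean centering is used; an
alternative formulation centers on Egger residuals and can differ
slightly in small panels.

**SIMEX.**  For each λ in the grid (default 0, 0.25, …, 2.0) and each of
n_sim_per_lambda replicates (default 500), perturb γ̂_j by
√λ · σ_Xj · Z_jb and refit Egger; average the coefficients per λ; fit a
quadratic (default) or linear polynomial in λ through the means (the λ=0
point is the unperturbed fit) and evaluate it at λ = −1, the error-free
state.  Corrected standard errors come from a delete-one jackknife over
simulation replicates and quantify extrapolation stability, not full
sampling variability — they are labelled approximate in the result.  When
every perturbation is numerically zero the corrected fit equals the
uncorrected fit exactly.  Identical seeds give bit-identical results.

## Synthetic data

The generator draws γ_j ~ U(0.05, 0.15) (GWAS-significant-scale effects),
per-variant SEs uniform in [0.5, 1.5] × scale with default scales
σ_X = 0.005 and σ_Y = 0.01, and observed associations
γ̂_j ~ N(γ_j, σ²_Xj), Γ̂_j ~ N(βγ_j + α_j, σ²_Yj).  The defaults describe
a strong-instrument panel: I²GX ≈ 0.97, so the NOME approximation is
nearly exact and estimator-recovery studies probe the estimators rather
than instrument weakness.  Pleiotropy regimes set α_j for an
`invalid_fraction` of variants (chosen by seeded permutation):
`balanced` ~ N(0, σ_α²); `directional_inside` ~ N(μ_α, σ_α²) independent
of γ; `directional_inside_violated` adds 0.5·γ_j, correlating direct
effects with instrument strength.  Study conditions used by the recovery
tests and the acceptance script: true β = 0.1, J = 100; directional
regimes use invalid_fraction 0.3, μ_α = 0.01, σ_α = 0.005; the
attenuation/SIMEX condition uses σ_X scale 0.03 with σ_Y scale 0.002
(I²GX ≈ 0.5).  Monte-Carlo sizes are 500 replicates in the test-suite's
recovery checks (200 in the acceptance script's reports) and 200 for the
SIMEX improvement rate, with median/mode point-recovery loops run at
n_boot = 2 since only point estimates enter those summaries.

One integer seed drives a single `numpy` Generator stream; ground truth
(γ, α, validity mask, true SEs) is attached to the dataset's metadata for
recovery studies and is never read by estimators.

What the generator does **not** emulate: linkage disequilibrium between
instruments, allele-frequency structure (variants are effect-size-only),
sample overlap between the two GWAS, winner's-curse selection of
instruments, and non-Gaussian estimation error.  Passing recovery tests
therefore demonstrate correctness of the estimators under the stated
structural model, not robustness to those real-data complications.

## Numerical choices

- Weighted-median interpolation clamps to β̂_1/β̂_J outside the percentile
  range; ties in ratio order are broken stably by input order.
- Mode grid size 10 000 (configurable); the documented tie-break is the
  smallest grid value among density maxima.
- Residual scales in IVW/Egger random-effects inference are floored at 1,
  never deflating SEs below their fixed-effect value.
- Palindromic (A/T, G/C) variants are dropped during harmonization by
  default; optional EAF-based resolution keeps them only when both sides'
  frequencies are outside (0.42, 0.58), the conventional decisiveness
  band, with the threshold configurable.
- A zero exposure association makes the ratio undefined: it raises a
  named error rather than silently dropping the variant; explicit
  `drop_null_instruments()` (or the `--drop-null-instruments` flag)
  converts it to a warning-plus-drop.
- Table reads use round-trip float parsing so read → write → read is
  bit-exact.
- SVG figures embed no timestamps and use a fixed hash salt, making them
  byte-reproducible for regression testing.

## Known limitations

- The ratio-variance and all weights use the NOME first-order form;
  the full delta-method variance including σ_Xj is not currently offered.
- SIMEX corrected SEs are approximate (see above); for publication-grade
  intervals a full bootstrap of the SIMEX pipeline would be needed.
- Harmonization resolves strand/swap cases from alleles and (optionally)
  EAFs only; no reference panel is consulted, and indels or multi-allelic
  variants are not classified.
- The applied-example reproduction tests require the original per-SNP
  supplementary tables, which are not redistributable with this package;
  without them those tests report the missing files.
- No multivariable MR, bidirectional MR, Steiger filtering, or
  outlier-removal schemes.
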