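# Methods

## Growth model

Nodule volume is modelled by the power-law (von Bertalanffy) ODE
dV/dt = α V^β with V in mm³ and t in months since the nodule's first scan.
α has units mm^{3(1−β)}·month⁻¹ and is positive for growing nodules; β is
dimensionless. The closed-form solution,

    V(t)^(1−β) = V0^(1−β) + (1−β) α t      (β ≠ 1)
    V(t)       = V0 e^{αt}                 (β = 1),

is used everywhere; no numerical integration occurs in the package itself
(numeric ODE integration appears only in the test suite, as an independent
oracle). For β > 1 and α > 0 the solution diverges at the finite blow-up time
t* = V0^(1−β)/((β−1)α); the forward solver refuses any requested time ≥ t*
rather than returning a complex or infinite volume.

Growth categories follow upper-inclusive exponent bins: decelerated
β ≤ −0.1, linear −0.1 < β ≤ 0.1, subexponential 0.1 < β ≤ 0.9, exponential
0.9 < β ≤ 1.1, accelerated β > 1.1. The bins partition the real line, so
every finite fitted exponent gets exactly one label.

## Fitting

**Exact three-point fit.** With scans at (t0, t1, t2) and strictly increasing
volumes, substituting the closed form at the three points and eliminating α
gives, in c = 1 − β with a_i = ln(V_i/V0),

    f(c) = expm1(c·a1) / expm1(c·a2) = (t1 − t0)/(t2 − t0).

For 0 < a1 < a2, f decreases strictly from 1 (c → −∞) to 0 (c → +∞), so the
root is unique and bracketed for any time ratio in (0, 1). Brent's method on
c (bracket β ∈ [−10, 10] by default, xtol 1e−13) recovers β; α follows from
either interval. A root at the bracket edge raises a convergence error —
never a silent clamp. |c| < 1e−8 switches to the exponential closed form
(α = a1/t1) to avoid catastrophic cancellation. The fit is exact: the RMS
log-volume residual is numerically zero.

**Least-squares fit** (series longer than three scans) minimises the sum of
squared log-volume residuals over (α, β) with V0 fixed at the first observed
volume, initialised from the exact fit on the (first, middle, last) points.
The log-volume objective corresponds to a multiplicative error model,
consistent with the perturbation protocol below. Leaving the positive domain
during optimisation is handled by a soft penalty; non-convergence is
reported through a `converged` flag. For exactly three scans the exact fit
is returned unchanged. The default pipeline fits the first three scans
exactly even when more are available, mirroring the three-measurement
protocol; the least-squares variant is an explicit option.

## Kinetic features

All rates use the natural logarithm, so VDT = ln2/λ is exact under pure
exponential growth. From the first three scans the package computes pairwise
linear rates ν₀₁, ν₀₂, ν₁₂ (mm³/month), pairwise exponential rates λ₀₁, λ₀₂,
λ₁₂ (month⁻¹), their three-point OLS counterparts ν_ls and λ_ls (slopes of V
and ln V against t — the estimator behind the three-point rows was left
open, and OLS is the standard choice), the modified Schwartz doubling time
VDT_exp = ln2/λ₀₁ (first two scans, per its definition) plus a variant from
λ_ls, and the scaling-law doubling time

    VDT_β = ((2V0)^(1−β) − V0^(1−β)) / ((1−β) α).

Degenerate kinetics yield signals, not crashes: λ = 0 gives an infinite VDT,
negative λ a negative (shrinkage) VDT; a fitted α < 0 makes doubling
unreachable and VDT_β is recorded as missing. Baseline features are V0, the
mean attenuation HU0 and the "mass" product V0·HU0 (mm³·HU, typically
negative in lung). Missing attenuation propagates as NaN, never as zero.

**Numerical seam at β = 1.** vb_solve_forward and the fitters switch to the
exponential branch at |1−β| < 1e−8. VDT_β uses a wider window, |1−β| ≤
~1e−6: the exact formula's value drifts from the ln2/α limit by
|1−β|·|ln V0 + ln2/2| (about 5e−6 relative at V0 = 100 and |1−β| = 1e−6), so
inside the window the limit is reported. The representation error this
introduces is orders of magnitude below the β resolution attainable from
noisy volumetry, and it makes the estimator numerically flat across the
singular point.

## Perturbation robustness protocol

Segmentation error is modelled as independent multiplicative noise: each
volume is multiplied by 1 + u with u ~ Uniform(−ε, +ε), ε = 0.05 by default
(a bounded ±5% range read literally as uniform; the distribution was not
otherwise specified). All three volumes are perturbed, including V0. Each of
n_reps = 200 replicates is refitted with the exact three-point solver;
replicates whose perturbed volumes are no longer strictly increasing, or
whose root leaves the search bracket, are counted as failures and excluded
from the median rather than redrawn (redrawing would bias the distribution
toward easy configurations). The nodule is robust when
|median(β*) − β| < 0.5. Outcomes are exactly reproducible given (series,
n_reps, ε, threshold, seed); cohort-level runs spawn per-nodule seeds from a
single SeedSequence.

## Discrimination

AUC is the tie-aware concordance probability
P(score_mal > score_ben) + ½P(equal), computed by a full threshold sweep
(all distinct cut-points, no intermediate-point dropping) and trapezoid
integration; the test suite verifies the sweep against brute-force pair
counting. Each feature's orientation is chosen so the reported AUC ≥ 0.5 and
recorded (doubling times come out lower-is-malignant). Operating points
maximise Youden's J = sensitivity + specificity − 1, with ties broken toward
higher specificity — screening economics penalise false positives; J ties
are detected with a 1e−12 tolerance because complementary rate fractions
(e.g. 1/3 vs 1 − 2/3) differ in floating point.

The multivariable score is a binomial GLM (logit link) on the candidate
terms, with CT morphology encoded as two indicators (part-solid, non-solid;
solid reference). Backward elimination removes the highest-Wald-p term until
all remaining terms have p ≤ 0.05. With a binary benign/malignant outcome
and no event times, a proportional-hazards formulation is not identified, so
the stepwise-Wald idea is carried out on the logistic model instead.
Evaluation is in-sample by default. (Quasi-)separation — likely when a
morphology level occurs in one class only — triggers an L2-penalised
fallback fit, flagged, with no elimination step.

Group comparisons use the Kruskal–Wallis omnibus test; with more than two
groups, pairwise Mann–Whitney post-hocs are Holm-adjusted (uniformly more
powerful than Bonferroni, no independence assumption). A Kolmogorov–Smirnov
normality screen is available for reporting but never gates which test runs:
comparisons are always rank-based.

## Synthetic cohort generator

The generator emulates the group-level structure of a screening population of
180 nodules (40 benign, 140 malignant, three scans each):

- **Growth-pattern mixture** — exact per-category counts (benign
  20/0/8/1/11, malignant 37/1/13/6/83 for decelerated/linear/subexponential/
  exponential/accelerated); β is drawn uniformly inside each category's bin
  (decelerated down to −2.0, accelerated up to 2.5).
- **Baseline volume** — log-normal per group, least-squares calibrated in
  log space to the reference quartiles (benign 49.5/103.5/414.3, malignant
  64.3/179.3/527.2 mm³). Two parameters cannot match three asymmetric
  quantiles exactly; the calibration keeps the generated median inside the
  reference IQR.
- **Scan schedule** — t1 and t2 from triangular distributions least-squares
  fitted to the reference interval quartiles (6.2/12.2/13.9 and
  14.37/24.3/30.8 months). No triangular distribution matches these
  asymmetric quartiles exactly (verified against the global optimum); the
  fitted quartiles are within ~2 months of the targets. Draws with
  t2 ≤ t1 + 1 month are redrawn.
- **Growth magnitude** — each nodule receives a target fold-change FC at t2,
  drawn uniformly from a per-(group, category) range increasing with
  category; ranges are calibrated once so the group median fold-changes
  match the reference group volume trajectories (≈1.85 benign, ≈3.0
  malignant). α is then derived analytically so V(t2) = FC·V0 exactly —
  guaranteeing increasing, finite trajectories (no β > 1 draw can reach its
  blow-up time) and making the drawn (α, β) exactly recoverable at zero
  noise. This recoverability is what turns the generator into a
  ground-truth oracle for the pipeline tests.
- **Attenuation** — group-level three-point HU trajectories (benign stable
  around −146/−156/−131; malignant rising around −314/−291/−233) plus a
  per-nodule offset (sd 120 HU, reflecting the large between-nodule spread
  of mean attenuation across morphologies) and per-scan jitter (sd 15 HU).
- **Morphology and stage** — malignant morphology 81/28/31
  solid/part-solid/non-solid; benign defaults to all solid (no reference mix
  is available; it is configurable); malignant stage labels 112/12/15/1 for
  I–IV are carried for grouping only.
- **Volumetry noise** — optional multiplicative ε (default 0).

What the generator does **not** emulate: per-nodule correlation between β
and growth magnitude beyond the category coupling, measurement error
heteroscedasticity (small nodules are harder to segment), attrition,
inter-observer segmentation variability, and any within-morphology
attenuation structure. Consequently, pipeline results on synthetic cohorts
validate the machinery (fitting, categorisation, feature computation,
evaluation bookkeeping) and qualitative orderings, not clinical effect
sizes: generated AUCs should not be read as reproductions of any particular
study's discrimination estimates.

## Problem sizes and determinism

Default analyses use the 180-nodule cohort, 200-replicate perturbation runs
and 200-permutation sanity checks; these sizes keep the full test suite and
the acceptance script in the tens-of-seconds range on a single core while
leaving Monte-Carlo standard errors (e.g. ~0.03 on a median of 200 refitted
exponents) far inside the decision thresholds. All randomness flows through
numpy Generators seeded explicitly; cohort generation, the perturbation
protocol and the CLI are bit-reproducible under a fixed seed, and report
JSON rounds floats to 6 significant digits for hash stability.

## Known limitations

- The exact fit uses only the first three scans by design; information in
  later scans is used only by the least-squares variant.
- In-sample ROC evaluation overstates out-of-sample discrimination;
  cross-validation is not wired into the default pipeline.
- The robustness criterion's 0.5 threshold is a convention inherited from
  the protocol it implements, not an estimated quantity.
- Times are months as floats (1 month = 30.4375 days for conversion);
  calendar-date arithmetic is out of scope.
- DICOM ingestion, segmentation and any image-level processing are out of
  scope; the package starts from segmented volumes.
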