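# nodulegrowth

Growth-law fitting, doubling-time estimation and benign-vs-malignant
discrimination for longitudinal CT lung-nodule volumetry.

Lung-cancer screening programs follow incidentally detected pulmonary nodules
over repeated low-dose CT scans. Management guidelines usually assume the
nodule volume grows exponentially and summarise growth by a volume doubling
time (VDT), but real nodules deviate from exponential kinetics in both
directions. This package is for biostatisticians and imaging researchers who
want to characterise those kinetics from segmented volumes and to compare
growth-based malignancy classifiers.

## The model

Nodule volume V(t) (mm³, t in months since the first scan) is modelled by the
von Bertalanffy power-law ODE

    dV/dt = α V^β

whose closed form is `V(t)^(1−β) = V0^(1−β) + (1−β) α t` for β ≠ 1 and
`V(t) = V0 e^{αt}` for β = 1. The dimensionless exponent β indexes the growth
pattern — decelerated (β ≤ −0.1), linear (−0.1 < β ≤ 0.1), subexponential
(0.1 < β ≤ 0.9), exponential (0.9 < β ≤ 1.1) or accelerated (β > 1.1, faster
than exponential with a finite blow-up time). Three scans (V0, V1, V2)
determine (α, β) exactly; the fit reduces to a one-dimensional root-find with
a provably unique root for increasing volumes.

On top of the fit the package computes the classical discriminators:
pairwise linear rates ν = ΔV/Δt, exponential rates λ = Δln V/Δt, the modified
Schwartz doubling time VDT_exp = ln2/λ₀₁, its scaling-law generalisation

    VDT_β = ((2V0)^(1−β) − V0^(1−β)) / ((1−β) α),

baseline volume, mean attenuation (HU) and the volume×attenuation "mass".
Each feature is scored as a malignancy classifier by tie-aware ROC-AUC with a
Youden operating point, and features can be combined with CT morphology
(solid / part-solid / non-solid) in a backward-eliminated logistic score.
A Monte-Carlo protocol quantifies how robust the fitted exponent is to
volumetry error (±5% perturbations, 200 refits, median-deviation criterion).

Because screening datasets are rarely shareable, a calibrated synthetic
generator produces cohorts (default: 40 benign / 140 malignant nodules, three
scans each) with reference group-level characteristics — growth-pattern
mixtures, baseline-volume quartiles, scan-interval quartiles, attenuation
trajectories, morphology mix — and exact recoverable ground truth at zero
noise.

## Worked example

```python
from nodulegrowth import ScanObservation, vb_fit_exact3, vb_solve_forward

v0, beta = 100.0, 1.4
c = 1.0 - beta
alpha = v0**c * (4.0**c - 1.0) / (c * 24.0)   # V(24 months) = 400 mm3

times = [0.0, 12.0, 24.0]
volumes = vb_solve_forward(v0, alpha, beta, times)
fit = vb_fit_exact3([ScanObservation(t, v) for t, v in zip(times, volumes)])
print(fit.beta, fit.category.value)
```

Running `python examples/03_sensitivity.py` prints

```
4-fold growth  beta=  1.400  median(beta*)=   1.393  |dev|=  0.007  failed=  0/200  robust=True
near-flat      beta= -0.000  median(beta*)=  -1.290  |dev|=  1.290  failed=192/200  robust=False
```

i.e. on a nodule that quadruples over 24 months the exponent is insensitive
to 5% volumetry error (median refitted β within 0.007 of the truth), whereas
on a near-flat nodule the exponent is unidentifiable — most perturbed
replicates either break monotonicity or land far from the reference. The
other scripts in `examples/` cover fitting, doubling times, cohort I/O and
full-cohort classification; `examples/04_synthetic_cohort_classification.py`
prints the growth-category table (accelerated growth dominating the
malignant group) and the AUC ranking of all 16 discriminators.

A thin CLI wraps the same pipeline:

```
nodulegrowth simulate --spec default --seed 7 --out cohort.csv
nodulegrowth fit --cohort cohort.csv --out-dir fit/
nodulegrowth evaluate --features fit/features.csv --out-dir eval/ \
    --multivariable nu_02,morphology
```

## Layout

- `src/nodulegrowth/cohort.py` — domain types, CSV/TSV I/O, inclusion filter
- `src/nodulegrowth/growth.py` — forward solution, exact 3-point fit,
  least-squares fit, growth categorisation
- `src/nodulegrowth/kinetics.py` — rates, doubling times, baseline features
- `src/nodulegrowth/sensitivity.py` — perturbation robustness protocol
- `src/nodulegrowth/discrimination.py` — ROC/AUC, operating points, group
  tests, multivariable score
- `src/nodulegrowth/synthetic.py` — calibrated cohort generator and fixtures
- `src/nodulegrowth/pipeline.py`, `cli.py` — orchestration and the CLI

See `docs/methods.md` for the modelling assumptions, calibration choices and
known limitations.
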