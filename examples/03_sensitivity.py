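"""Robustness of the growth exponent to segmentation error.

Volumetry is noisy: the protocol perturbs every volume by independent uniform
errors in [-5%, +5%], refits the exponent 200 times, and accepts the nodule
as robust when the median refitted exponent stays within 0.5 of the
unperturbed one. A well-conditioned (4-fold growth) nodule passes easily; a
near-flat one does not.
"""

from nodulegrowth import (
    NoduleSeries,
    ScanObservation,
    sensitivity_analysis,
    vb_solve_forward,
)


def series_from(volumes):
    return NoduleSeries(
        "n", "malignant",
        tuple(ScanObservation(t, v) for t, v in zip([0.0, 12.0, 24.0], volumes)),
        "solid",
    )


c = 1.0 - 1.4
alpha = 100.0**c * (4.0**c - 1.0) / (c * 24.0)
strong = series_from(vb_solve_forward(100, alpha, 1.4, [0, 12, 24]))
flat = series_from([100.0, 101.0, 102.0])

for name, series in (("4-fold growth", strong), ("near-flat", flat)):
    out = sensitivity_analysis(series, n_reps=200, epsilon=0.05, seed=1)
    print(
        f"{name:14s} beta={out.beta_ref:7.3f}  median(beta*)={out.beta_median:8.3f}  "
        f"|dev|={abs(out.beta_median - out.beta_ref):7.3f}  "
        f"failed={out.n_failed:3d}/200  robust={out.robust}"
    )
# The near-flat nodule's exponent is essentially unidentifiable under 5%
# volume noise: most replicates fail or land far from the reference.
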