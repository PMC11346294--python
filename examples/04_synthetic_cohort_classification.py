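"""Generate the default synthetic screening cohort, fit every nodule and
rank the candidate malignancy discriminators by ROC-AUC.

The cohort (40 benign / 140 malignant, three scans each) reproduces the
reference growth-pattern mixture exactly at zero volumetry noise; the AUC
ordering is qualitative — growth over two scan intervals discriminates
better than baseline volume alone.
"""

from nodulegrowth import (
    default_cohort_spec,
    evaluate_all_features,
    feature_table,
    generate_cohort,
    inclusion_filter,
    multivariable_score,
)

cohort = generate_cohort(default_cohort_spec(), seed=7)
kept, log = inclusion_filter(cohort)
print(f"retained {len(kept)} / {len(cohort)} nodules ({len(log.excluded)} excluded)")

features = feature_table(kept)
counts = features.groupby(["malignancy", "category"]).size()
print("\ngrowth categories (accelerated dominates the malignant group):")
print(counts.unstack(fill_value=0))

print("\ntop discriminators by AUC:")
evals = sorted(evaluate_all_features(features), key=lambda e: -e.auc)
for e in evals[:6]:
    print(
        f"  {e.feature_name:12s} AUC={e.auc:.3f} ({e.direction}) "
        f"sens={e.sensitivity:.2f} spec={e.specificity:.2f}"
    )

model = multivariable_score(features, ["nu_02", "morphology"])
print(
    f"\nmultivariable nu_02 + morphology: AUC={model.eval.auc:.3f} "
    f"(terms kept: {', '.join(model.included_features)})"
)
# Adding CT morphology (solid / part-solid / non-solid) to the linear growth
# rate improves on either alone, mirroring how compactness complements growth.
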