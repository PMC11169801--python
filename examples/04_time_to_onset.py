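"""Time-to-onset analysis: medians, Weibull shape-parameter test, KM incidence.

Onset = event date minus therapy start, kept only when both dates have full
day precision and the event does not precede the start. The Weibull shape
parameter beta classifies how risk evolves with time on drug: CI below 1 ->
early failure (risk falls), CI containing 1 -> random failure, CI above 1
-> wear-out failure (risk rises).
"""
from faerspv import (
    DrugQuery,
    assemble_reports,
    compute_tto,
    deduplicate,
    default_config,
    generate_quarter,
    km_at,
    km_curve,
    select_ps_cohort,
    tto_summary,
    weibull_mle,
)

config = default_config(n_background_reports=3000, seed=9)
quarter, truth = generate_quarter(config)
reports = deduplicate(assemble_reports(quarter))

for drug, synonyms in (
    ("patisiran", {"ALN-TTR02", "onpattro", "patisiran sodium"}),
    ("vutrisiran", {"amvuttra", "vutrisiran sodium"}),
    ("inotersen", {"inotersen sodium", "tegsedi"}),
):
    cohort = select_ps_cohort(reports, DrugQuery(drug, frozenset(synonyms)))
    records = compute_tto(cohort)
    median, q1, q3 = tto_summary(records)
    fit = weibull_mle(records)
    curve = km_curve(records)
    true_shape = truth.drugs[drug]["weibull_shape"]
    print(f"{drug}: {len(records)} usable onset records "
          f"(of {len(cohort)} cohort reports)")
    print(f"  median onset {median:.0f} days (IQR {q1:.0f}-{q3:.1f})")
    print(f"  Weibull beta {fit.shape_beta:.2f} "
          f"(95% CI {fit.beta_ci[0]:.2f}-{fit.beta_ci[1]:.2f}), true {true_shape}"
          f" -> {fit.profile}")
    print(f"  cumulative incidence: {100 * km_at(curve, 30):.1f}% by day 30, "
          f"{100 * km_at(curve, 180):.1f}% by day 180\n")

print("Shape estimates should track each drug's planted beta; records are fewer")
print("than cohort reports because partial or inverted dates are excluded.")
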