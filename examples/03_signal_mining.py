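"""ROR disproportionality screening: top terms, signal criteria, expectedness.

For each candidate term a 2x2 table is built against the rest of the
database, ROR = (a*d)/(b*c) with a Wald 95% CI; a term is a significant
signal when ROR_025 > 1 and N >= 2, and a significant signal absent from
the drug label is an *unexpected* signal.
"""
from faerspv import (
    DrugQuery,
    assemble_reports,
    comparator_background,
    cross_drug_overlap,
    deduplicate,
    default_config,
    generate_quarter,
    select_ps_cohort,
    signals_to_frame,
    top_terms,
)

config = default_config(n_background_reports=6000, seed=5)
quarter, truth = generate_quarter(config)
reports = deduplicate(assemble_reports(quarter))

queries = {
    "patisiran": DrugQuery("patisiran", frozenset({"ALN-TTR02", "onpattro", "patisiran sodium"})),
    "vutrisiran": DrugQuery("vutrisiran", frozenset({"amvuttra", "vutrisiran sodium"})),
    "inotersen": DrugQuery("inotersen", frozenset({"inotersen sodium", "tegsedi"})),
}

per_drug = {}
for drug, query in queries.items():
    cohort = select_ps_cohort(reports, query)
    background = comparator_background(reports, cohort)
    label = truth.drugs[drug]["label_pts"]
    results = top_terms(cohort, background, k=50, label_terms=label)
    per_drug[drug] = results

print("patisiran: top 8 terms by report count")
frame = signals_to_frame(per_drug["patisiran"]).head(8)
print(frame.round(2).to_string(index=False))

print("\nPlanted signals vs detected (significant = ROR_025 > 1 and N >= 2):")
for drug, results in per_drug.items():
    planted = {s["pt"]: s["target_ror"] for s in truth.drugs[drug]["signals"]}
    for r in results:
        if r.term in planted:
            print(f"  {drug:10s} {r.term:25s} true ROR {planted[r.term]:4.1f}  "
                  f"estimated {r.ror:5.2f} ({r.ci_low:.2f}-{r.ci_high:.2f})  "
                  f"{r.expectedness}")

labeled, unexpected = cross_drug_overlap(per_drug)
print(f"\nsignals shared by all three drugs: labeled={sorted(labeled)}, "
      f"unexpected={sorted(unexpected)}")
print("Drug-specific signals are recovered near their planted RORs. 'malaise'")
print("is planted for two drugs, so each drug's comparator contains the other's")
print("excess and its estimated ROR is attenuated - the same contamination a")
print("whole-database comparator has in real disproportionality screening.")
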