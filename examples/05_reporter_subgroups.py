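"""Reporter-type subgroup analysis: signals common to and unique per stratum.

The cohort (and, by default, the comparator background) is split into
reports filed by medical vs non-medical professionals; the same top-k ROR
screening runs in each stratum, and the significant term sets are compared.
"""
from faerspv import (
    DrugQuery,
    DrugSpec,
    SignalSpec,
    assemble_reports,
    comparator_background,
    deduplicate,
    default_config,
    generate_quarter,
    select_ps_cohort,
    subgroup_signals,
)

config = default_config(
    n_background_reports=5000,
    drug_specs=(DrugSpec(
        name="patisiran",
        synonyms=("onpattro",),
        n_ps_reports=600,
        signal_pts=(
            SignalSpec("fatigue", 8.0, 0.01, stratum="all"),
            SignalSpec("muscle spasms", 8.0, 0.02, stratum="non_medical"),
            SignalSpec("pleural effusion", 8.0, 0.02, stratum="medical"),
        ),
    ),),
    seed=17,
)
quarter, truth = generate_quarter(config)
reports = deduplicate(assemble_reports(quarter))
cohort = select_ps_cohort(reports, DrugQuery("patisiran", frozenset({"onpattro"})))
background = comparator_background(reports, cohort)

comparison = subgroup_signals(cohort, background, k=50)
for stratum, results in comparison.stratum_results.items():
    n_sig = sum(r.significant for r in results)
    print(f"{stratum}: {n_sig} significant signals among top {len(results)} terms")
print(f"\ncommon significant signals:        {sorted(comparison.common)}")
print(f"unique to medical reporters:       {sorted(comparison.unique_medical)}")
print(f"unique to non-medical reporters:   {sorted(comparison.unique_non_medical)}")
print("\n'fatigue' was planted in both strata, 'pleural effusion' only among")
print("medical and 'muscle spasms' only among non-medical reporters; the")
print("recovered sets should reflect that assignment.")
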