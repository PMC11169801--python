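"""Generate a synthetic FAERS-like quarter and inspect its ground truth.

The generator writes the four quarterly sub-tables (DEMO/DRUG/REAC/THER,
'$'-delimited) plus a truth manifest recording everything that was planted:
cohort caseids, signal PTs with their target reporting odds ratios, Weibull
onset parameters, and injected duplicate case versions.
"""
import tempfile
from pathlib import Path

from faerspv import DrugSpec, SignalSpec, default_config, simulate

config = default_config(
    n_background_reports=2000,
    drug_specs=(
        DrugSpec(
            name="patisiran",
            synonyms=("ALN-TTR02", "onpattro", "patisiran sodium"),
            n_ps_reports=400,
            signal_pts=(SignalSpec("fatigue", 8.0, 0.01),),
            label_pts=("vitamin a decreased", "muscle spasms"),
            weibull_shape=0.81,
            weibull_scale=325.0,
        ),
    ),
    seed=1,
)

with tempfile.TemporaryDirectory() as tmp:
    paths = simulate(config, Path(tmp) / "quarter")
    for table, path in paths.items():
        n_lines = sum(1 for _ in open(path)) if path.suffix == ".txt" else "-"
        print(f"{table:5s} -> {path.name:10s} ({n_lines} lines)")
    truth_text = paths["TRUTH"].read_text()

print()
print("Planted truth for patisiran (excerpt):")
import json
truth = json.loads(truth_text)
drug = truth["drugs"]["patisiran"]
print(f"  cohort size          {len(drug['cohort_caseids'])}")
print(f"  planted signals      {[(s['pt'], s['target_ror']) for s in drug['signals']]}")
print(f"  onset Weibull        shape {drug['weibull_shape']}, scale {drug['weibull_scale']} days")
print(f"  duplicate versions   {len(truth['duplicates'])} caseids appear twice")
print()
print("Line counts exceed report counts because duplicate case versions are")
print("planted on purpose: deduplication has a known right answer here.")
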