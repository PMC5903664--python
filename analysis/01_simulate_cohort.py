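"""Simulate the study cohorts used by the downstream analysis scripts.

Generates (a) an infant-style cohort of ever-wheezers (n=657) with the
seven risk-factor covariates, a distal hospitalization outcome,
covariate-dependent missingness, and two assessment waves, and (b) a
larger single-wave cohort (n=4,000) used for the invariance ladders, where
per-group ordered-probit fits with seven covariates need more children per
cell.  Writes coded CSVs plus the generating truth under results/cohort/.
"""

import json
import sys
from pathlib import Path

from wheezesev import OutcomeSpec, cohort1_config, generate_cohort, write_item_table

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path(__file__).resolve().parents[1] / "results" / "cohort"
OUT.mkdir(parents=True, exist_ok=True)


def main() -> None:
    cfg = cohort1_config(
        n=657,
        seed=SEED,
        waves=2,
        outcome=OutcomeSpec(name="hospitalization", beta=0.7, marginals=(0.85, 0.15)),
        missing={
            "episodes": (0.03, {"medicaid": 0.02}),
            "sleep": (0.03, {"medicaid": 0.02}),
            "speech": (0.03, {"medicaid": 0.02}),
            "exercise": (0.02, {}),
        },
    )
    study = generate_cohort(cfg)
    for wave, tab in study.tables.items():
        write_item_table(tab, OUT / f"infant_{wave}.csv")
    write_item_table(study.joint_table, OUT / "infant_joint.csv")
    (OUT / "infant_truth.json").write_text(json.dumps(study.truth, indent=1))

    big = cohort1_config(n=4000, seed=SEED + 1)
    write_item_table(generate_cohort(big).table, OUT / "ladder_cohort.csv")

    n1 = study.tables["w1"]
    print(f"infant cohort: n={n1.n}, waves=2, outcome=hospitalization")
    for v in n1.item_names:
        if v == "hospitalization":
            continue
        print(f"  {v:<10} counts {n1.category_counts(v).tolist()}")
    print(f"ladder cohort: n=4000 written to {OUT}")


if __name__ == "__main__":
    main()
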