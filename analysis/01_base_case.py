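"""Base-case analysis: outpatient costs, expected cost per case, national burden.

Writes results/outpatient_costs.csv (per-item antenatal costs by group),
results/cost_per_case.csv (outpatient / mother / infant / total per group
and the GDM-euglycemia difference) and results/burden.json.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from gdmburden import (
    GROUPS,
    OUTPATIENT_GROUPS,
    cost_per_case,
    default_parameters,
    group_outpatient_cost,
    load_parameters,
    national_burden,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--params", type=Path, default=None, help="optional YAML parameter config")
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()

    params = load_parameters(args.params) if args.params else default_parameters()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    outpatient = {g: group_outpatient_cost(params, g) for g in OUTPATIENT_GROUPS}
    rows = [
        {"item": item.name, **{g: round(outpatient[g].per_item[item.name], 1) for g in OUTPATIENT_GROUPS}}
        for item in params.resource_items
    ]
    rows.append({"item": "total", **{g: round(outpatient[g].total, 1) for g in OUTPATIENT_GROUPS}})
    pd.DataFrame(rows).to_csv(args.out_dir / "outpatient_costs.csv", index=False)

    bd = cost_per_case(params)
    table = []
    for name, gc in (("euglycemia", bd.euglycemia), ("gdm", bd.gdm), ("delta", bd.delta)):
        table.append(
            {
                "group": name,
                "outpatient": round(gc.outpatient, 1),
                "mother_inpatient": round(gc.mother_inpatient, 1),
                "infant_inpatient": round(gc.infant_inpatient, 1),
                "inpatient_total": round(gc.inpatient_total, 1),
                "total": round(gc.total, 1),
            }
        )
    pd.DataFrame(table).to_csv(args.out_dir / "cost_per_case.csv", index=False)

    burden = national_burden(params, bd)
    with open(args.out_dir / "burden.json", "w") as fh:
        json.dump(
            {
                "gdm_cases": burden.gdm_cases,
                "incremental_cost_eur": round(burden.incremental_cost, 0),
                "incremental_cost_million_eur": round(burden.incremental_cost / 1e6, 1),
                "relative_increase_pct": round(100 * burden.relative_increase, 1),
            },
            fh,
            indent=2,
        )

    print("Antenatal outpatient cost per case (EUR):")
    for g in OUTPATIENT_GROUPS:
        print(f"  {g:12s} {outpatient[g].total:8.1f}")
    print("\nCost per case (EUR):")
    for row in table:
        print(
            f"  {row['group']:10s} outpatient {row['outpatient']:7.1f}  "
            f"mother {row['mother_inpatient']:7.1f}  infant {row['infant_inpatient']:7.1f}  "
            f"total {row['total']:7.1f}"
        )
    print(
        f"\nNational burden: {burden.gdm_cases:,} GDM cases, "
        f"EUR {burden.incremental_cost / 1e6:.1f} million extra "
        f"(+{100 * burden.relative_increase:.1f}% per case)"
    )


if __name__ == "__main__":
    main()
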