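"""One-way (+/-20%) sensitivity analysis of the inpatient cost per case.

Varies the literature-derived neonatal probabilities and the inpatient
costs one at a time and writes results/one_way_sensitivity.csv, ranked by
the width of the impact on the GDM-euglycemia cost difference (tornado
order).
"""

import argparse
from pathlib import Path

import pandas as pd

from gdmburden import (
    default_parameters,
    dsa_parameter_ids,
    load_parameters,
    one_way,
    tornado,
)

# the parameters singled out for the headline table: the big cost drivers
# and the neonatal probabilities with visible leverage
HEADLINE_IDS = [
    "cost:hypoglycemia",
    "cost:respiratory_distress",
    "cost:caesarean_with_cc:gdm",
    "cost:caesarean_without_cc:gdm",
    "cost:vaginal_without_cc:gdm",
    "cost:caesarean_without_cc:euglycemia",
    "cost:vaginal_without_cc:euglycemia",
    "prob:hyperbilirubinemia:gdm:no_macrosomia",
    "prob:hypoglycemia:gdm:no_macrosomia",
    "prob:respiratory_distress:gdm:no_macrosomia",
    "prob:hyperbilirubinemia:euglycemia:no_macrosomia",
    "prob:respiratory_distress:euglycemia:no_macrosomia",
]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--params", type=Path, default=None)
    ap.add_argument("--change", type=float, default=0.2)
    ap.add_argument("--all", action="store_true", help="vary every model parameter")
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()

    params = load_parameters(args.params) if args.params else default_parameters()
    ids = dsa_parameter_ids() if args.all else HEADLINE_IDS

    base = one_way(params, ids[0], 0.0)
    rows = [
        {
            "parameter": "base_case",
            "direction": "",
            "cost_per_case_euglycemia": round(base.cost_per_case_euglycemia, 1),
            "cost_per_case_gdm": round(base.cost_per_case_gdm, 1),
            "delta": round(base.delta, 1),
        }
    ]
    pairs = tornado(params, ids, args.change)
    for pair in pairs:
        for direction, r in (("-", pair.low), ("+", pair.high)):
            rows.append(
                {
                    "parameter": pair.parameter_id,
                    "direction": f"{direction}{args.change:.0%}",
                    "cost_per_case_euglycemia": round(r.cost_per_case_euglycemia, 1),
                    "cost_per_case_gdm": round(r.cost_per_case_gdm, 1),
                    "delta": round(r.delta, 1),
                }
            )
    args.out_dir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(args.out_dir / "one_way_sensitivity.csv", index=False)

    print(
        f"Base case: euglycemia {base.cost_per_case_euglycemia:.1f}, "
        f"GDM {base.cost_per_case_gdm:.1f}, delta {base.delta:.1f} EUR"
    )
    print(f"\nTornado ranking (+/-{args.change:.0%}), delta range in EUR:")
    for pair in pairs:
        print(
            f"  {pair.parameter_id:50s} "
            f"[{pair.low.delta:7.1f}, {pair.high.delta:7.1f}]  width {pair.delta_range:6.1f}"
        )


if __name__ == "__main__":
    main()
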