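"""Extract model parameters from discharge records and close the loop.

Runs the full extraction (delivery identification, GDM flagging with
90-day look-back, delivery-mix estimation, LOS-adjusted tariff costing
with 99th-percentile outlier exclusion, neonatal event cost means) on the
CSVs produced by 04_simulate_cohort.py, writes the recovered parameter set
as a YAML config usable by 01_base_case.py --params, and compares the
recovered delivery-side quantities with the packaged model inputs.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from gdmburden import (
    DELIVERY_CATEGORIES,
    GROUPS,
    default_parameters,
    extract,
    mother_inpatient_cost,
    parameters_from_extraction,
    read_records,
    write_parameters,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--records", type=Path, default=Path("scratch/mother_records.csv"))
    ap.add_argument("--infant-records", type=Path, default=Path("scratch/infant_records.csv"))
    ap.add_argument("--tariffs", type=Path, default=Path("scratch/tariffs.json"))
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()

    mothers = read_records(args.records)
    infants = read_records(args.infant_records) if args.infant_records.exists() else []
    tariffs = json.loads(args.tariffs.read_text())

    result = extract(mothers, tariffs, infant_records=infants)
    recovered = parameters_from_extraction(result)

    args.out_dir.mkdir(parents=True, exist_ok=True)
    write_parameters(recovered, args.out_dir / "extracted_params.yaml")

    base = default_parameters()
    rows = []
    for g in GROUPS:
        for d in DELIVERY_CATEGORIES:
            rows.append(
                {
                    "group": g,
                    "drg": d,
                    "prob_recovered": round(result.delivery_mix.probability(g, d), 4),
                    "prob_model": round(base.delivery_mix.probability(g, d), 4),
                    "cost_recovered": round(result.delivery_mix.cost(g, d), 1),
                    "cost_model": base.delivery_mix.cost(g, d),
                }
            )
    pd.DataFrame(rows).to_csv(args.out_dir / "extraction_recovery.csv", index=False)

    n_gdm = sum(result.gdm_flags.values())
    print(
        f"{len(result.gdm_flags):,} deliveries "
        f"({result.n_excluded_deliveries:,} other admissions excluded); "
        f"{n_gdm:,} flagged GDM; {result.excluded_outliers:,} LOS outliers dropped"
    )
    if result.infant_event_costs:
        print("neonatal event mean tariffs (EUR):")
        for e, c in sorted(result.infant_event_costs.items()):
            print(f"  {e:24s} {c:10.1f}")
    print("\nexpected mother inpatient cost per case, recovered vs model (EUR):")
    for g in GROUPS:
        got = mother_inpatient_cost(recovered.delivery_mix, g)
        want = mother_inpatient_cost(base.delivery_mix, g)
        print(f"  {g:12s} {got:8.1f}  vs {want:8.1f}  ({100 * (got / want - 1):+.2f}%)")


if __name__ == "__main__":
    main()
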