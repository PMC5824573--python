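"""Simulate a synthetic hospital-discharge cohort.

Generates mother and infant admission records from the calibrated cohort
specification (delivery mix, LOS distributions and tariffs matching the
packaged model inputs) and writes them as discharge-record CSVs plus the
tariff map the extraction step needs.  Record files can be large, so they
go under scratch/ by default.
"""

import argparse
import json
from pathlib import Path

from gdmburden import generate_infants, generate_mothers, calibrated_cohort_spec, write_records


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--n", type=int, default=100_000, help="number of mothers")
    ap.add_argument("--seed", type=int, default=42)
    ap.add_argument("--out-dir", type=Path, default=Path("scratch"))
    args = ap.parse_args()

    spec = calibrated_cohort_spec(n_mothers=args.n, seed=args.seed)
    args.out_dir.mkdir(parents=True, exist_ok=True)

    mothers = generate_mothers(spec)
    infants = generate_infants(spec)
    write_records(mothers, args.out_dir / "mother_records.csv")
    write_records(infants, args.out_dir / "infant_records.csv")
    with open(args.out_dir / "tariffs.json", "w") as fh:
        json.dump({k: round(v, 2) for k, v in spec.tariffs.items()}, fh, indent=2)

    n_gdm = sum(1 for r in mothers if "648.8" in r.icd9_codes)
    print(
        f"wrote {len(mothers):,} mother records ({len(mothers) - args.n:,} look-back "
        f"admissions) and {len(infants):,} infant records to {args.out_dir}/"
    )
    print(f"{n_gdm:,} admissions carry the GDM code 648.8")


if __name__ == "__main__":
    main()
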