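#!/usr/bin/env python
"""Generate the synthetic multi-exposure study underlying the analyses.

Writes a 51-exposure study fixture (summary statistics for each exposure,
one shared binary-outcome GWAS with 10,754 cases / 306,882 controls, an LD
reference panel, a cross-trait table, and the ground-truth record) under
scratch/study_data/. Every downstream script reads from there.

Usage: python analysis/01_simulate_study.py [--n-exposures 51] [--seed 7]
"""

import argparse
from pathlib import Path

from mrkit.simulate import make_study_fixture

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--n-exposures", type=int, default=51)
    ap.add_argument("--seed", type=int, default=7)
    ap.add_argument("--out", type=Path, default=ROOT / "scratch" / "study_data")
    args = ap.parse_args()

    manifest = make_study_fixture(args.n_exposures, args.seed, args.out)
    n_withheld = sum(len(v) for v in manifest["withheld_from_outcome"].values())
    print(f"wrote {args.n_exposures} exposure tables + shared outcome to {args.out}")
    print(f"true effects: "
          f"{sum(1 for e in manifest['exposures'] if e['beta_true'] > 0)} positive, "
          f"{sum(1 for e in manifest['exposures'] if e['beta_true'] < 0)} negative, "
          f"{sum(1 for e in manifest['exposures'] if e['beta_true'] == 0)} null")
    print(f"{n_withheld} instrument SNPs withheld from the outcome (proxy test)")


if __name__ == "__main__":
    main()
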