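"""Report compartment distributions and the candidate-substrate cascade.

Reads results/run/summary.json and candidates.tsv and prints the GOCC
compartment distribution of all vs up-regulated Ksu proteins and the
per-stage localization-filter counts.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--run", type=Path, default=ROOT / "results" / "run")
    args = ap.parse_args()

    with open(args.run / "summary.json") as fh:
        s = json.load(fh)

    print("compartment distribution (all Ksu proteins vs up-regulated):")
    for comp in s["compartments_all_ksu"]:
        a = s["compartments_all_ksu"][comp]
        u = s["compartments_up_ksu"].get(comp)
        print(f"  {comp:30s} {a!s:>6}%  ->  {u!s:>6}%")

    print("localization filter cascade:")
    for stage, c in s["stage_counts"].items():
        print(f"  {stage:15s} {c['sites']} sites on {c['proteins']} proteins")

    cands = pd.read_csv(args.run / "candidates.tsv", sep="\t")
    print(f"candidate table: {len(cands)} up-regulated sites on "
          f"{cands['protein_id'].nunique() if not cands.empty else 0} proteins (ranked)")


if __name__ == "__main__":
    main()
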