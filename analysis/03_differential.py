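"""Report the differential succinylation results of a finished run.

Reads results/run/summary.json, prints the narrative counts (DEP
fractions, differential-site fractions) and writes the per-protein site
table of the top-ranked candidate to results/run/top_candidate_sites.tsv.
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
    print(
        f"proteins: {s['n_protein_quantified']} quantified, {s['n_dep']} ({s['pct_dep']}%) DEPs "
        f"({s['n_dep_up']} up / {s['n_dep_down']} down)"
    )
    print(
        f"Ksu sites: {s['n_site_identified']} identified, {s['n_site_quantified']} quantified, "
        f"{s['n_site_diff']} differential of which {s['n_site_diff_up']} up "
        f"({s['pct_site_diff_of_quantified']}% of quantified sites)"
    )
    print(
        f"Ksu proteins: {s['n_ksu_protein_diff']} of {s['n_ksu_protein_quantified']} "
        f"({s['pct_ksu_protein_diff']}%) carry a differential site"
    )

    sites = pd.read_csv(args.run / "sites.tsv", sep="\t")
    cands = pd.read_csv(args.run / "candidates.tsv", sep="\t")
    if not cands.empty:
        top = cands.loc[cands["rank"] == 1, "protein_id"].iloc[0]
        table = sites[sites["protein_id"] == top]
        out = args.run / "top_candidate_sites.tsv"
        table.to_csv(out, sep="\t", index=False)
        n_up = (table["call"] == "up").sum()
        print(f"top candidate {top}: {len(table)} sites, {n_up} up (table in {out})")


if __name__ == "__main__":
    main()
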