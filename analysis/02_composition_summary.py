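#!/usr/bin/env python
"""Degradome composition of the packaged inventory.

Recomputes the per-class summary grid, the class-composition
percentages, the EC exo/endo breakdown, and the shares of the largest
subfamilies.  Writes results/summary.txt (human-readable grid),
results/summary.tsv and results/summary.json.
"""

import csv
import json
from pathlib import Path

from degradome.catalogue import load_inventory
from degradome.stats import (
    render_report,
    subfamily_share,
    summarize,
    summary_json,
    summary_rows,
)

OUT = Path(__file__).resolve().parent.parent / "results"


def main():
    records = load_inventory()
    summary = summarize(records)
    OUT.mkdir(exist_ok=True)
    (OUT / "summary.txt").write_text(render_report(summary))
    with open(OUT / "summary.tsv", "w", newline="") as fh:
        rows = summary_rows(summary)
        w = csv.DictWriter(fh, fieldnames=list(rows[0]), delimiter="\t")
        w.writeheader()
        w.writerows(rows)
    with open(OUT / "summary.json", "w") as fh:
        json.dump(summary_json(summary), fh, indent=2, sort_keys=True)
        fh.write("\n")

    pct = summary.class_percentages
    print(f"{summary.total} proteases = {summary.genome_fraction}% of the "
          f"{summary.proteome_size}-protein proteome")
    print("class composition:",
          ", ".join(f"{c} {pct[c]}%" for c in pct))
    print(f"clans {summary.clans_total}, families/subfamilies "
          f"{summary.subfamilies_total}; "
          f"EC: exo {summary.ec_sides['exo']}, endo {summary.ec_sides['endo']}, "
          f"unknown {summary.ec_sides['unknown']}")
    share = subfamily_share(records, ["A1A", "T1A", "C19", "S10"])
    print(f"four largest subfamilies (A1A, T1A, C19, S10) hold {share}% "
          "of the degradome")


if __name__ == "__main__":
    main()
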