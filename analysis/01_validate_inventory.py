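#!/usr/bin/env python
"""Check the packaged protease inventory against its checksum manifest.

Every per-class total (gene models, clans, subfamilies, unassigned, new
members, new active sites, inactive, secreted, characterized) and every
EC-bucket count is recomputed from the 232 records and compared cell by
cell.  Writes results/validation.tsv.
"""

import csv
from pathlib import Path

from degradome.catalogue import load_catalogue, validate_inventory

OUT = Path(__file__).resolve().parent.parent / "results"


def main():
    cat = load_catalogue()
    report = validate_inventory(cat.records, cat.manifest)
    OUT.mkdir(exist_ok=True)
    with open(OUT / "validation.tsv", "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["row", "class", "recomputed", "expected", "equal"])
        for row, cls, got, want, ok in report.cells:
            w.writerow([row, cls, got, want, int(ok)])
        for bucket, got, want, ok in report.ec_cells:
            w.writerow(["ec_bucket", bucket, got, want, int(ok)])
    n_cells = len(report.cells) + len(report.ec_cells)
    if report.ok:
        print(f"inventory OK: all {n_cells} checksum cells match "
              f"({len(cat.records)} records, {len(cat.rules)} family rules)")
    else:
        print(f"inventory FAILED {len(report.failures)} of {n_cells} cells:")
        for f in report.failures:
            print("  ", f)
        raise SystemExit(1)


if __name__ == "__main__":
    main()
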