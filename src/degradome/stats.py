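"""Degradome composition statistics.

Aggregates an inventory (or classification output mapped onto records)
into the per-class summary table and the EC-side breakdown, with
percentages at the conventions used for genome surveys: half-up
rounding, one decimal for class-composition shares and two decimals
for genome-coverage fractions.
"""

from __future__ import annotations

import decimal
import io
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .catalogue import (
    CLASSES,
    EC_SIDE,
    UNASSIGNED,
    CatalogueManifest,
    class_counts,
    count_clans,
)

DEFAULT_PROTEOME_SIZE = 14165


class StatsError(ValueError):
    pass


def percentage(numerator: int, denominator: int, decimals: int = 1) -> float:
    """100*numerator/denominator, rounded half-up to 1 or 2 decimals."""
    if denominator <= 0:
        raise StatsError("zero or negative denominator")
    if decimals not in (1, 2):
        raise StatsError("decimals must be 1 or 2")
    q = decimal.Decimal(1).scaleb(-decimals)
    val = (
        decimal.Decimal(100)
        * decimal.Decimal(numerator)
        / decimal.Decimal(denominator)
    ).quantize(q, rounding=decimal.ROUND_HALF_UP)
    return float(val)


@dataclass(frozen=True)
class DegradomeSummary:
    """Composition of a protease inventory."""

    total: int
    per_class: dict  # {row-name: {class: count}}
    class_percentages: dict  # {class: % of total, 1 decimal}
    subfamily_sizes: dict  # {(class, subfamily): count}
    ec_counts: dict  # {bucket: count}
    ec_sides: dict  # {exo|endo|unknown: count}
    clans_total: int
    clans_total_any_unassigned: int
    subfamilies_total: int
    proteome_size: int
    genome_fraction: float  # % of proteome, 2 decimals

    def row(self, name: str) -> dict:
        return self.per_class[name]


def summarize(
    records: Sequence, proteome_size: int = DEFAULT_PROTEOME_SIZE
) -> DegradomeSummary:
    """Recompute every composition statistic from the records."""
    records = list(records)
    total = len(records)
    per_class_rows = class_counts(records)
    per_class = {
        row: dict(zip(CLASSES, counts))
        for row, counts in per_class_rows.items()
    }
    class_pct = {
        c: percentage(per_class["gene_models"][c], total, 1) if total else 0.0
        for c in CLASSES
    }
    sizes = {}
    for r in records:
        key = (r.catalytic_class, r.subfamily_id)
        sizes[key] = sizes.get(key, 0) + 1
    ec_counts = {}
    for r in records:
        ec_counts[r.ec_bucket] = ec_counts.get(r.ec_bucket, 0) + 1
    ec_sides = {"exo": 0, "endo": 0, "unknown": 0}
    for bucket, n in ec_counts.items():
        ec_sides[EC_SIDE.get(bucket, "unknown")] += n
    return DegradomeSummary(
        total=total,
        per_class=per_class,
        class_percentages=class_pct,
        subfamily_sizes=sizes,
        ec_counts=ec_counts,
        ec_sides=ec_sides,
        clans_total=sum(per_class["clans"].values()),
        clans_total_any_unassigned=sum(
            count_clans(records, c, pseudo_clan_mode="any-unassigned")
            for c in CLASSES
        ),
        subfamilies_total=sum(per_class["subfamilies"].values()),
        proteome_size=proteome_size,
        genome_fraction=(
            percentage(total, proteome_size, 2) if total else 0.0
        ),
    )


def subfamily_share(records: Sequence, subfamily_ids: Sequence[str]) -> float:
    """Share of the inventory held by the listed subfamilies (1 decimal)."""
    if not subfamily_ids:
        raise StatsError("no subfamilies given")
    records = list(records)
    known = {r.subfamily_id for r in records}
    missing = [s for s in subfamily_ids if s not in known]
    if missing:
        raise StatsError(f"unknown subfamilies: {missing}")
    n = sum(1 for r in records if r.subfamily_id in set(subfamily_ids))
    return percentage(n, len(records), 1)


ROW_LABELS = {
    "gene_models": "No. gene models",
    "clans": "No. protease clans",
    "subfamilies": "No. protease subfamilies",
    "unassigned": "Unassigned proteases",
    "new_members": "New members",
    "new_active_sites": "Proteases with new active sites",
    "inactive": "Putatively inactive proteases",
    "secreted": "Secreted proteases",
    "characterized": "Characterized proteases",
}

EC_ORDER = ("3.4.11", "3.4.13", "3.4.14", "3.4.16", "3.4.17", "3.4.19",
            "3.4.21", "3.4.22", "3.4.23", "3.4.24", "3.4.25", "3.4.99",
            "unknown")


def render_report(summary: DegradomeSummary) -> str:
    """Byte-stable text report: the per-class summary grid plus the EC
    breakdown."""
    out = io.StringIO()
    cols = ["row"] + list(CLASSES) + ["total"]
    widths = [max(34, len(cols[0]))] + [10] * (len(cols) - 1)

    def line(cells):
        out.write(
            "".join(str(c).ljust(w) for c, w in zip(cells, widths)).rstrip()
            + "\n"
        )

    line(cols)
    for row in CatalogueManifest.ROWS:
        counts = summary.per_class[row]
        line([ROW_LABELS[row]] + [counts[c] for c in CLASSES]
             + [sum(counts.values())])
    out.write("\n")
    line(["Class composition (%)"]
         + [f"{summary.class_percentages[c]:.1f}" for c in CLASSES]
         + [f"{100.0 if summary.total else 0.0:.1f}"])
    out.write("\n")
    out.write("EC breakdown\n")
    for bucket in EC_ORDER:
        n = summary.ec_counts.get(bucket, 0)
        if n:
            out.write(
                f"  {bucket:<8}{EC_SIDE.get(bucket, 'unknown'):<9}{n}\n"
            )
    out.write(
        f"  exo={summary.ec_sides['exo']} endo={summary.ec_sides['endo']} "
        f"unknown={summary.ec_sides['unknown']}\n"
    )
    out.write("\n")
    out.write(
        f"Total proteases: {summary.total} "
        f"({summary.genome_fraction:.2f}% of {summary.proteome_size} "
        "predicted proteins)\n"
    )
    out.write(
        f"Clans: {summary.clans_total} "
        f"(counting a pseudo-clan for any unassigned member: "
        f"{summary.clans_total_any_unassigned}); "
        f"families/subfamilies: {summary.subfamilies_total}\n"
    )
    out.write(
        "Clan bookkeeping: a pseudo-clan is counted only for classified "
        "families without a clan.\n"
    )
    return out.getvalue()


def summary_rows(summary: DegradomeSummary) -> list:
    """Per-class rows for TSV export."""
    rows = []
    for row in CatalogueManifest.ROWS:
        counts = summary.per_class[row]
        rows.append(
            {"row": row, **{c: counts[c] for c in CLASSES},
             "total": sum(counts.values())}
        )
    return rows


def summary_json(summary: DegradomeSummary) -> dict:
    """JSON-friendly structured summary."""
    return {
        "total": summary.total,
        "per_class": summary.per_class,
        "class_percentages": summary.class_percentages,
        "ec_counts": summary.ec_counts,
        "ec_sides": summary.ec_sides,
        "clans_total": summary.clans_total,
        "clans_total_any_unassigned": summary.clans_total_any_unassigned,
        "subfamilies_total": summary.subfamilies_total,
        "proteome_size": summary.proteome_size,
        "genome_fraction": summary.genome_fraction,
    }
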