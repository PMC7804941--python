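"""The classification catalogue and the packaged protease inventory.

The catalogue holds one :class:`FamilyRule` per MEROPS family/subfamily
present in the *Aspergillus niger* protease repertoire: the conserved
catalytic-motif architecture, the catalytic-residue arrangement, the EC
sub-subfamily bucket and — for metallopeptidases — the tribe defined by
active-site architecture (gluzincin, metzincin, inverzincin, funnelin,
the two αβα-exopeptidase families, AAA).

The packaged inventory is the transcription of the published A. niger
degradome: 232 locus-tagged records across the six catalytic classes,
with activity status, consensus-secretion flag, EC bucket and printed
motif annotation.  A :class:`CatalogueManifest` carries the per-class
checksum totals; :func:`validate_inventory` recomputes every row from
the records and reports each cell.
"""

from __future__ import annotations

import csv
import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import yaml

from .motifs import (
    DEFAULT_XN_MAX,
    MotifParseError,
    MotifPattern,
    parse_motif,
)

CLASSES = ("aspartic", "glutamic", "threonine", "cysteine", "serine", "metallo")
CLAN_PREFIX = {"aspartic": "A", "glutamic": "G", "threonine": "P",
               "cysteine": "C", "serine": "S", "metallo": "M"}
ACTIVITIES = ("active", "putatively-inactive", "non-peptidase-homologue")
TRIBES = ("gluzincin", "metzincin", "inverzincin", "funnelin",
          "aminoacylase-1", "EEM2-MPs", "AAA", "unassigned")
COMPONENT_ROLES = ("catalytic", "metal-binding", "turn", "accessory")
UNASSIGNED = "unassigned"

#: EC sub-subfamily buckets and their exo/endo side.
EC_SIDE = {
    "3.4.11": "exo", "3.4.13": "exo", "3.4.14": "exo", "3.4.16": "exo",
    "3.4.17": "exo", "3.4.19": "exo",
    "3.4.21": "endo", "3.4.22": "endo", "3.4.23": "endo", "3.4.24": "endo",
    "3.4.25": "endo", "3.4.99": "endo",
    "unknown": "unknown",
}


class CatalogueError(ValueError):
    """Raised on a malformed catalogue or inventory entry; names the entry."""


@dataclass(frozen=True)
class RuleComponent:
    pattern: MotifPattern
    role: str

    def __post_init__(self):
        if self.role not in COMPONENT_ROLES:
            raise CatalogueError(f"unknown component role {self.role!r}")


@dataclass(frozen=True)
class FamilyRule:
    """One family/subfamily classification rule."""

    subfamily_id: str
    clan_id: str
    catalytic_class: str
    archetype: str
    components: tuple  # of RuleComponent
    residue_arrangement: tuple
    ec_bucket: str
    tribe: Optional[str] = None
    motif_free: bool = False
    note: Optional[str] = None

    def __post_init__(self):
        if self.catalytic_class not in CLASSES:
            raise CatalogueError(
                f"{self.subfamily_id}: unknown class {self.catalytic_class!r}"
            )
        if self.ec_bucket not in EC_SIDE:
            raise CatalogueError(
                f"{self.subfamily_id}: unknown EC bucket {self.ec_bucket!r}"
            )
        if self.tribe is not None and self.tribe not in TRIBES:
            raise CatalogueError(
                f"{self.subfamily_id}: unknown tribe {self.tribe!r}"
            )
        if self.tribe is not None and self.catalytic_class != "metallo":
            raise CatalogueError(
                f"{self.subfamily_id}: tribe set on non-metallo rule"
            )
        n_cat = sum(1 for c in self.components if c.role == "catalytic")
        if n_cat == 0 and not self.motif_free:
            raise CatalogueError(
                f"{self.subfamily_id}: no catalytic component and not motif-free"
            )

    @property
    def catalytic_components(self) -> list:
        return [c for c in self.components if c.role == "catalytic"]

    @property
    def patterns(self) -> list:
        return [c.pattern for c in self.components]

    @property
    def roles(self) -> list:
        return [c.role for c in self.components]


@dataclass(frozen=True)
class ProteaseRecord:
    """One inventory entry (a locus-tagged putative protease)."""

    locus_tag: str
    strain: str
    catalytic_class: str
    clan_id: str
    subfamily_id: str
    provisional_id: Optional[str]
    activity: str
    secreted: bool
    ec_bucket: str
    characterized: bool
    new_member: bool = False
    new_active_site: bool = False
    motif_annotation: Optional[str] = None
    tribe: Optional[str] = None
    note: Optional[str] = None

    def __post_init__(self):
        if self.catalytic_class not in CLASSES:
            raise CatalogueError(
                f"{self.locus_tag}: unknown class {self.catalytic_class!r}"
            )
        if self.activity not in ACTIVITIES:
            raise CatalogueError(
                f"{self.locus_tag}: unknown activity {self.activity!r}"
            )
        if self.ec_bucket not in EC_SIDE:
            raise CatalogueError(
                f"{self.locus_tag}: unknown EC bucket {self.ec_bucket!r}"
            )
        if self.secreted and self.catalytic_class == "threonine":
            raise CatalogueError(
                f"{self.locus_tag}: threonine proteases are never secreted"
            )


@dataclass(frozen=True)
class CatalogueManifest:
    """Per-class checksum totals (classes in catalogue order)."""

    classes: tuple
    gene_models: tuple
    clans: tuple
    subfamilies: tuple
    unassigned: tuple
    new_members: tuple
    new_active_sites: tuple
    inactive: tuple
    secreted: tuple
    characterized: tuple
    ec_buckets: dict
    proteome_size: int

    ROWS = ("gene_models", "clans", "subfamilies", "unassigned", "new_members",
            "new_active_sites", "inactive", "secreted", "characterized")


@dataclass
class Catalogue:
    """Loaded rules + inventory + manifest with lookup helpers."""

    rules: list
    records: list
    manifest: CatalogueManifest
    xn_max: int = DEFAULT_XN_MAX
    _by_subfamily: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self._by_subfamily = {}
        for r in self.rules:
            if r.subfamily_id in self._by_subfamily:
                raise CatalogueError(f"duplicate rule {r.subfamily_id}")
            self._by_subfamily[r.subfamily_id] = r

    def lookup_rule(self, subfamily_id: str) -> FamilyRule:
        try:
            return self._by_subfamily[subfamily_id]
        except KeyError:
            raise CatalogueError(
                f"subfamily {subfamily_id!r} not in catalogue"
            ) from None

    def has_rule(self, subfamily_id: str) -> bool:
        return subfamily_id in self._by_subfamily

    @property
    def matchable_rules(self) -> list:
        """Rules with at least one motif component, in catalogue order."""
        return [r for r in self.rules if r.components]


def _package_data(name: str) -> Path:
    return Path(importlib.resources.files("degradome") / "data" / name)


def _parse_components(entries, subfamily, xn_max) -> tuple:
    comps = []
    for e in entries:
        try:
            pattern = parse_motif(e["motif"], xn_max=xn_max)
        except MotifParseError as err:
            raise CatalogueError(f"{subfamily}: {err}") from err
        comps.append(RuleComponent(pattern=pattern, role=e["role"]))
    return tuple(comps)


def load_rules(path: Union[str, Path, None] = None,
               xn_max: int = DEFAULT_XN_MAX) -> list:
    """Load family rules from the packaged (or a user) catalogue file."""
    path = _package_data("catalogue.yaml") if path is None else Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not doc or not doc.get("rules"):
        raise CatalogueError(f"no rules in {path}")
    rules = []
    for raw in doc["rules"]:
        rules.append(
            FamilyRule(
                subfamily_id=raw["subfamily"],
                clan_id=raw["clan"],
                catalytic_class=raw["catalytic_class"],
                archetype=raw.get("archetype", ""),
                components=_parse_components(
                    raw.get("components", []), raw["subfamily"], xn_max
                ),
                residue_arrangement=tuple(raw.get("residue_arrangement", [])),
                ec_bucket=raw.get("ec_bucket", "unknown"),
                tribe=raw.get("tribe"),
                motif_free=bool(raw.get("motif_free", False)),
                note=raw.get("note"),
            )
        )
    return rules


def load_inventory(path: Union[str, Path, None] = None) -> list:
    """Load the protease inventory TSV (packaged by default)."""
    path = _package_data("inventory.tsv") if path is None else Path(path)
    records = []
    seen = set()
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            locus = row["locus_tag"]
            if locus in seen:
                raise CatalogueError(f"duplicate locus tag {locus}")
            seen.add(locus)
            records.append(
                ProteaseRecord(
                    locus_tag=locus,
                    strain=row["strain"],
                    catalytic_class=row["catalytic_class"],
                    clan_id=row["clan"],
                    subfamily_id=row["subfamily"],
                    provisional_id=row["provisional_id"] or None,
                    activity=row["activity"],
                    secreted=row["secreted"] == "1",
                    ec_bucket=row["ec_bucket"],
                    characterized=row["characterized"] == "1",
                    new_member=row["new_member"] == "1",
                    new_active_site=row["new_active_site"] == "1",
                    motif_annotation=row["motif_annotation"] or None,
                    tribe=row["tribe"] or None,
                    note=row["note"] or None,
                )
            )
    return records


def load_manifest(path: Union[str, Path, None] = None) -> CatalogueManifest:
    path = _package_data("manifest.yaml") if path is None else Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return CatalogueManifest(
        classes=tuple(doc["classes"]),
        gene_models=tuple(doc["gene_models"]),
        clans=tuple(doc["clans"]),
        subfamilies=tuple(doc["subfamilies"]),
        unassigned=tuple(doc["unassigned"]),
        new_members=tuple(doc["new_members"]),
        new_active_sites=tuple(doc["new_active_sites"]),
        inactive=tuple(doc["inactive"]),
        secreted=tuple(doc["secreted"]),
        characterized=tuple(doc["characterized"]),
        ec_buckets=dict(doc["ec_buckets"]),
        proteome_size=int(doc["proteome_size"]),
    )


def load_catalogue(
    rules_path: Union[str, Path, None] = None,
    inventory_path: Union[str, Path, None] = None,
    manifest_path: Union[str, Path, None] = None,
    xn_max: int = DEFAULT_XN_MAX,
) -> Catalogue:
    """Load rules, inventory and manifest (packaged data by default) and
    resolve all cross-references."""
    rules = load_rules(rules_path, xn_max=xn_max)
    records = load_inventory(inventory_path)
    manifest = load_manifest(manifest_path)
    cat = Catalogue(rules=rules, records=records, manifest=manifest,
                    xn_max=xn_max)
    for rec in records:
        if rec.subfamily_id != UNASSIGNED and not cat.has_rule(rec.subfamily_id):
            raise CatalogueError(
                f"{rec.locus_tag}: subfamily {rec.subfamily_id} has no rule"
            )
    return cat


# ---------------------------------------------------------------- validation

def count_clans(records, catalytic_class: str, *,
                pseudo_clan_mode: str = "clanless-family") -> int:
    """Distinct clans for one class.

    ``pseudo_clan_mode`` selects the bookkeeping for groups without an
    annotated clan:

    * ``"clanless-family"`` (default, reproduces the published per-class
      table): one pseudo-clan is added only when the class contains a
      *classified family* that is itself not assigned to a clan.
    * ``"any-unassigned"``: one pseudo-clan whenever the class has any
      member outside the annotated clans.
    """
    recs = [r for r in records if r.catalytic_class == catalytic_class]
    annotated = {r.clan_id for r in recs if r.clan_id != UNASSIGNED}
    if pseudo_clan_mode == "clanless-family":
        pseudo = any(
            r.clan_id == UNASSIGNED and r.subfamily_id != UNASSIGNED
            for r in recs
        )
    elif pseudo_clan_mode == "any-unassigned":
        pseudo = any(r.clan_id == UNASSIGNED for r in recs)
    else:
        raise ValueError(f"unknown pseudo_clan_mode {pseudo_clan_mode!r}")
    return len(annotated) + (1 if pseudo else 0)


def count_subfamilies(records, catalytic_class: str) -> int:
    return len({
        r.subfamily_id
        for r in records
        if r.catalytic_class == catalytic_class
        and r.subfamily_id != UNASSIGNED
    })


def class_counts(records) -> dict:
    """Recompute every manifest row from records: {row: per-class tuple}."""
    out = {}
    per = lambda pred: tuple(
        sum(1 for r in records if r.catalytic_class == c and pred(r))
        for c in CLASSES
    )
    out["gene_models"] = per(lambda r: True)
    out["clans"] = tuple(count_clans(records, c) for c in CLASSES)
    out["subfamilies"] = tuple(count_subfamilies(records, c) for c in CLASSES)
    out["unassigned"] = per(lambda r: r.subfamily_id == UNASSIGNED)
    out["new_members"] = per(lambda r: r.new_member)
    out["new_active_sites"] = per(lambda r: r.new_active_site)
    out["inactive"] = per(lambda r: r.activity == "putatively-inactive")
    out["secreted"] = per(lambda r: r.secreted)
    out["characterized"] = per(lambda r: r.characterized)
    return out


@dataclass(frozen=True)
class ValidationReport:
    """Cell-by-cell comparison of recomputed vs manifest totals."""

    cells: tuple  # of (row, class, recomputed, expected, equal)
    ec_cells: tuple  # of (bucket, recomputed, expected, equal)

    @property
    def ok(self) -> bool:
        return all(c[-1] for c in self.cells) and all(
            c[-1] for c in self.ec_cells
        )

    @property
    def failures(self) -> list:
        return [c for c in self.cells if not c[-1]] + [
            c for c in self.ec_cells if not c[-1]
        ]


def validate_inventory(records, manifest: CatalogueManifest) -> ValidationReport:
    """Recompute every manifest row from the records and compare per cell."""
    computed = class_counts(records)
    cells = []
    for row in CatalogueManifest.ROWS:
        expected = getattr(manifest, row)
        for cls, got, want in zip(CLASSES, computed[row], expected):
            cells.append((row, cls, got, want, got == want))
        total_got, total_want = sum(computed[row]), sum(expected)
        cells.append((row, "total", total_got, total_want,
                      total_got == total_want))
    ec_counts = {}
    for r in records:
        ec_counts[r.ec_bucket] = ec_counts.get(r.ec_bucket, 0) + 1
    ec_cells = []
    for bucket, want in sorted(manifest.ec_buckets.items()):
        got = ec_counts.get(bucket, 0)
        ec_cells.append((bucket, got, want, got == want))
    return ValidationReport(cells=tuple(cells), ec_cells=tuple(ec_cells))
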