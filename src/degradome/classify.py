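"""Sequence classification by motif architecture.

A protein is assigned to the family whose conserved catalytic-motif
architecture it carries best: rules are scored by the number of
catalytic-role components present (in order, non-overlapping), ties
broken by specificity (fully specified residue positions matched) and
then by catalogue order.  Activity follows the consensus-residue rule:
a homologue carrying every catalytic-role component is called active;
one carrying some but not all is putatively inactive; a protein that a
homology table places in a family whose catalytic AND metal-binding
components are all absent is a non-peptidase homologue.

Metallopeptidases are additionally routed to a tribe (zincin subdivision
by active-site architecture): the extended three-histidine motif marks
metzincins, the inverted HXXEH motif inverzincins, HEXXH/HEXXXH
gluzincins, HXXE funnelins, and the (S/G/A)HXDXV... and EE architectures
the two αβα-exopeptidase families; FtsH-like families are AAA proteases.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from Bio import SeqIO

from .catalogue import Catalogue, CatalogueError, FamilyRule, UNASSIGNED
from .motifs import ArchitectureMatch, clean_sequence, match_architecture

#: Sequences shorter than this are not classified (too short to carry an
#: architecture plus context).
MIN_SEQUENCE_LENGTH = 20


@dataclass(frozen=True)
class HomologyEvidence:
    """An externally asserted family membership (similarity-based)."""

    seq_id: str
    subfamily_id: str
    source: str = ""


@dataclass(frozen=True)
class ClassificationResult:
    seq_id: str
    best_rule: Optional[str]
    catalytic_class: Optional[str]
    clan_id: Optional[str]
    activity: str  # active | putatively-inactive | non-peptidase-homologue | unclassified
    tribe: Optional[str] = None
    evidence: Optional[ArchitectureMatch] = None
    used_homology: bool = False
    ambiguous: bool = False
    warning: Optional[str] = None


def _score(arch: ArchitectureMatch, order: int) -> tuple:
    # specificity of the catalytic consensus ranks before accessory context
    # (a family's activity evidence is its catalytic residues, and generic
    # single-residue components would otherwise swamp degraded but genuine
    # architectures); catalogue order breaks remaining ties, earlier wins
    return (arch.n_catalytic_matched, arch.catalytic_specificity,
            arch.specificity, -order)


def _match_rule(sequence: str, rule: FamilyRule) -> ArchitectureMatch:
    return match_architecture(
        sequence,
        rule.patterns,
        roles=rule.roles,
        rule_id=rule.subfamily_id,
    )


def _n_role_matched(arch: ArchitectureMatch, rule: FamilyRule,
                    roles: tuple) -> int:
    return sum(
        1
        for (idx, m) in arch.component_matches
        if m is not None and rule.components[idx].role in roles
    )


def classify_sequence(
    sequence: str,
    catalogue: Catalogue,
    homology: Optional[HomologyEvidence] = None,
    seq_id: str = "",
    require_accessory: bool = False,
) -> ClassificationResult:
    """Classify one protein sequence against the loaded catalogue.

    ``require_accessory`` makes accessory components necessary for an
    "active" call (off by default: accessory motifs are listed with the
    architectures but are not consensus catalytic residues).
    """
    seq = clean_sequence(sequence)
    if len(seq) < MIN_SEQUENCE_LENGTH:
        warnings.warn(
            f"{seq_id or 'sequence'}: shorter than {MIN_SEQUENCE_LENGTH} "
            "residues; marked unclassified",
            stacklevel=2,
        )
        return ClassificationResult(
            seq_id=seq_id, best_rule=None, catalytic_class=None, clan_id=None,
            activity="unclassified", warning="sequence too short",
        )

    scored = []
    for order, rule in enumerate(catalogue.matchable_rules):
        arch = _match_rule(seq, rule)
        if arch.n_matched:
            scored.append((rule, arch, order))

    best = None
    if scored:
        ranked = sorted(scored, key=lambda t: _score(t[1], t[2]), reverse=True)
        top_rule, top_arch, _ = ranked[0]
        if top_arch.n_catalytic_matched > 0:
            best = (top_rule, top_arch)
            ambiguous = (
                len(ranked) > 1
                and _score(ranked[1][1], 0)[:3] == _score(top_arch, 0)[:3]
                and ranked[1][0].catalytic_class != top_rule.catalytic_class
            )

    if best is not None:
        rule, arch = best
        all_required = all(
            m is not None
            for (idx, m) in arch.component_matches
            if rule.components[idx].role == "catalytic"
            or (require_accessory and rule.components[idx].role == "accessory")
        )
        activity = "active" if all_required else "putatively-inactive"
        return ClassificationResult(
            seq_id=seq_id,
            best_rule=rule.subfamily_id,
            catalytic_class=rule.catalytic_class,
            clan_id=rule.clan_id,
            activity=activity,
            tribe=(assign_tribe_for_rule(rule)
                   if rule.catalytic_class == "metallo" else None),
            evidence=arch,
            ambiguous=ambiguous,
        )

    # no catalytic motif evidence anywhere: homology may still place the
    # sequence, as a non-peptidase homologue, in an asserted family
    if homology is not None:
        asserted = catalogue.lookup_rule(homology.subfamily_id)
        arch = _match_rule(seq, asserted)
        n_key = _n_role_matched(arch, asserted, ("catalytic", "metal-binding"))
        if n_key == 0:
            return ClassificationResult(
                seq_id=seq_id,
                best_rule=asserted.subfamily_id,
                catalytic_class=asserted.catalytic_class,
                clan_id=asserted.clan_id,
                activity="non-peptidase-homologue",
                tribe=None,
                evidence=arch,
                used_homology=True,
            )
        return ClassificationResult(
            seq_id=seq_id,
            best_rule=asserted.subfamily_id,
            catalytic_class=asserted.catalytic_class,
            clan_id=asserted.clan_id,
            activity="putatively-inactive",
            evidence=arch,
            used_homology=True,
        )

    return ClassificationResult(
        seq_id=seq_id, best_rule=None, catalytic_class=None, clan_id=None,
        activity="unclassified",
    )


# ------------------------------------------------------------------- tribes

def _elements(rule: FamilyRule):
    if not rule.components:
        return ()
    return rule.components[0].pattern.elements


def _residue_is(e, residues) -> bool:
    return (
        e.kind == "residue-set"
        and not e.is_wildcard
        and e.residues <= frozenset(residues)
    )


def infer_tribe(rule: FamilyRule) -> str:
    """Tribe implied by the first (zinc-binding) component's architecture.

    Decision order: extended three-His metzincin motif; inverted HXXEH
    (inverzincin); HEXXH / HEXXXH core (gluzincin); HXXE (funnelin);
    (S/G/A)HXDXV head of the aminoacylase-1 architecture; the EE pair
    (EEM2-MPs); otherwise unassigned.
    """
    el = _elements(rule)
    n = len(el)
    if n >= 11 and _residue_is(el[0], "H") and _residue_is(el[4], "H") \
            and _residue_is(el[10], "HD"):
        return "metzincin"
    if n >= 5 and _residue_is(el[0], "H") and _residue_is(el[3], "E") \
            and _residue_is(el[4], "H"):
        return "inverzincin"
    if n in (5, 6) and _residue_is(el[0], "H") and _residue_is(el[1], "E") \
            and _residue_is(el[-1], "H"):
        return "gluzincin"
    if n == 4 and _residue_is(el[0], "H") and _residue_is(el[3], "E"):
        return "funnelin"
    if n == 6 and _residue_is(el[1], "H") and _residue_is(el[3], "D") \
            and _residue_is(el[5], "V"):
        return "aminoacylase-1"
    if n == 2 and _residue_is(el[0], "E") and _residue_is(el[1], "E"):
        return "EEM2-MPs"
    return "unassigned"


def assign_tribe_for_rule(rule: FamilyRule) -> str:
    """Tribe for a metallopeptidase rule: the catalogue's explicit label
    (which carries the two stated context exceptions — FtsH-like families
    are AAA proteases, and the ATP23 family is left unassigned despite its
    HEXXH core) or, failing that, the architecture-inferred tribe."""
    if rule.catalytic_class != "metallo":
        raise CatalogueError(
            f"tribe assignment applies to metallopeptidases only, "
            f"not {rule.catalytic_class}"
        )
    if rule.tribe is not None:
        return rule.tribe
    return infer_tribe(rule)


def assign_tribe(result: ClassificationResult, catalogue: Catalogue) -> str:
    """Tribe label for a classified metallopeptidase."""
    if result.catalytic_class != "metallo":
        raise CatalogueError(
            "tribe assignment applies to metallopeptidases only"
        )
    if result.best_rule and result.best_rule != UNASSIGNED:
        return assign_tribe_for_rule(catalogue.lookup_rule(result.best_rule))
    return "unassigned"


# ------------------------------------------------------------------- batch

def read_evidence_table(path) -> dict:
    """Read a homology-evidence TSV (seq_id, subfamily_id, source)."""
    import csv

    out = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            ev = HomologyEvidence(
                seq_id=row["seq_id"],
                subfamily_id=row["subfamily_id"],
                source=row.get("source", ""),
            )
            out[ev.seq_id] = ev
    return out


def classify_records(
    records: Iterable,
    catalogue: Catalogue,
    evidence: Optional[dict] = None,
) -> list:
    """Classify (seq_id, sequence) pairs or Bio.SeqRecords, order-preserving."""
    evidence = evidence or {}
    results = []
    seen = set()
    for rec in records:
        if hasattr(rec, "id"):
            seq_id, seq = rec.id, str(rec.seq)
        else:
            seq_id, seq = rec
        if seq_id in seen:
            raise ValueError(f"duplicate sequence id {seq_id!r}")
        seen.add(seq_id)
        results.append(
            classify_sequence(
                seq, catalogue, homology=evidence.get(seq_id), seq_id=seq_id
            )
        )
    return results


def classify_fasta(
    fasta_path,
    catalogue: Catalogue,
    evidence: Optional[dict] = None,
) -> list:
    """Classify every record of a FASTA file, input order preserved."""
    with open(fasta_path) as fh:
        return classify_records(SeqIO.parse(fh, "fasta"), catalogue, evidence)


def results_to_rows(results: Iterable) -> list:
    """Flatten classification results for TSV output."""
    rows = []
    for r in results:
        comps = ""
        coords = ""
        if r.evidence is not None:
            parts, locs = [], []
            for idx, m in r.evidence.component_matches:
                if m is not None:
                    parts.append(m.pattern.source_text)
                    locs.append(f"{m.start}-{m.end}")
            comps, coords = "+".join(parts), ",".join(locs)
        rows.append({
            "seq_id": r.seq_id,
            "class": r.catalytic_class or "",
            "clan": r.clan_id or "",
            "subfamily": r.best_rule or "",
            "activity": r.activity,
            "tribe": r.tribe or "",
            "matched_components": comps,
            "coordinates": coords,
            "used_homology": "1" if r.used_homology else "0",
            "ambiguous": "1" if r.ambiguous else "0",
        })
    return rows
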