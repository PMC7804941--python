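"""Motif notation, compiled patterns, and sequence scanning.

Protease active-site motifs are written in a compact convention used
throughout the peptidase literature: fixed residues in one-letter code,
``X`` for any residue, ``(T/S/G)`` for an alternation at one position,
a trailing ``/B`` (as in ``NEXXT/A``) for an alternation bound to the
single preceding position, and subscripted spacers ``X_3-8``, ``X_76``
or ``X_n`` for bounded, fixed-length, or open gaps.  An *architecture*
is an ordered list of such motifs (conventionally printed with ``+``
between components); a protein carries the architecture when every
component occurs, in order and without overlap.

This module parses the notation, renders it back to a canonical string,
scans protein sequences for single motifs, and locates multi-component
architectures.  Matching is exact (presence/absence of consensus
residues) — no scoring, no fuzziness.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

#: The 20 standard amino acids, one-letter code.
STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Ambiguity / non-standard codes tolerated in input sequences.  A sequence
#: position holding one of these matches only wildcard motif elements.
NONSTANDARD_RESIDUES = frozenset("BJOUZX")

#: Default upper bound for the open-ended spacer ``X_n`` (configurable).
DEFAULT_XN_MAX = 100

#: Separators between architecture components as printed in the source
#: tables; the ideographic comma is a typographic variant of "+".
COMPONENT_SEPARATORS = ("+", "、")


class MotifParseError(ValueError):
    """Raised when motif notation cannot be parsed; names the bad token."""


@dataclass(frozen=True)
class MotifElement:
    """One position (or spacer) of a motif.

    ``kind`` is ``"residue-set"`` or ``"gap"``.  Residue-set elements hold a
    non-empty set of standard one-letter codes; the full 20-residue set is a
    wildcard.  Gap elements hold inclusive length bounds.
    """

    kind: str
    residues: frozenset = frozenset()
    min_gap: int = 0
    max_gap: int = 0

    def __post_init__(self):
        if self.kind == "residue-set":
            if not self.residues or not self.residues <= STANDARD_RESIDUES:
                raise MotifParseError(
                    f"residue set {set(self.residues)!r} outside the 20 standard codes"
                )
        elif self.kind == "gap":
            if self.min_gap < 0 or self.max_gap < self.min_gap:
                raise MotifParseError(
                    f"gap bounds {self.min_gap}-{self.max_gap} are not ordered"
                )
        else:
            raise MotifParseError(f"unknown element kind {self.kind!r}")

    @property
    def is_wildcard(self) -> bool:
        return self.kind == "residue-set" and self.residues == STANDARD_RESIDUES

    @property
    def is_fixed(self) -> bool:
        """True for a single-residue (fully specified) position."""
        return self.kind == "residue-set" and len(self.residues) == 1


@dataclass(frozen=True)
class MotifPattern:
    """A parsed motif: the printed text plus its ordered elements."""

    source_text: str
    elements: tuple = ()

    def __post_init__(self):
        if not any(e.kind == "residue-set" for e in self.elements):
            raise MotifParseError(
                f"motif {self.source_text!r} has no residue-set element"
            )

    @property
    def n_fixed(self) -> int:
        """Number of fully specified residue positions (specificity weight)."""
        return sum(1 for e in self.elements if e.is_fixed)

    @property
    def min_length(self) -> int:
        return sum(
            1 if e.kind == "residue-set" else e.min_gap for e in self.elements
        )

    @property
    def gap_span(self) -> int:
        """Total maximum spacer length across all gap elements."""
        return sum(e.max_gap for e in self.elements if e.kind == "gap")

    def render(self) -> str:
        """Canonical text form; parse(render()) is the identity."""
        out = []
        for e in self.elements:
            if e.kind == "gap":
                if e.min_gap == e.max_gap:
                    out.append(f"X_{e.min_gap}_")
                else:
                    out.append(f"X_{e.min_gap}-{e.max_gap}_")
            elif e.is_wildcard:
                out.append("X")
            elif e.is_fixed:
                out.append(next(iter(e.residues)))
            else:
                out.append("(" + "/".join(sorted(e.residues)) + ")")
        return "".join(out)

    def _regex(self) -> "re.Pattern[str]":
        parts = []
        for e in self.elements:
            if e.kind == "gap":
                hi = "" if e.max_gap is None else e.max_gap
                # lazy bound: scanning prefers the shortest feasible spacer,
                # minimised left to right
                parts.append("[A-Z]{%d,%s}?" % (e.min_gap, hi))
            elif e.is_wildcard:
                parts.append("[A-Z]")
            else:
                parts.append("[" + "".join(sorted(e.residues)) + "]")
        return re.compile("".join(parts))

    @property
    def compiled(self) -> "re.Pattern[str]":
        # compiled lazily and memoised on the instance
        rx = getattr(self, "_rx", None)
        if rx is None:
            rx = self._regex()
            object.__setattr__(self, "_rx", rx)
        return rx


@dataclass(frozen=True)
class MotifMatch:
    """One occurrence of a motif; coordinates are 1-based, inclusive."""

    pattern: MotifPattern
    start: int
    end: int
    matched_text: str

    def __post_init__(self):
        if not (1 <= self.start <= self.end):
            raise ValueError("match coordinates must satisfy 1 <= start <= end")


@dataclass(frozen=True)
class ArchitectureMatch:
    """An ordered architecture located (possibly partially) on a sequence.

    ``component_matches`` holds one entry per component, a
    (component index, MotifMatch-or-None) pair in component order.
    ``specificity`` is the number of fully specified residue positions
    among the matched components.
    """

    rule_id: str
    component_matches: tuple
    n_matched: int
    n_catalytic_matched: int
    specificity: int
    catalytic_specificity: int = 0


_TOKEN_RE = re.compile(
    r"""
    \(([A-Z](?:/[A-Z])+)\)        # (A/B/C) alternation
  | X_(\d+)-(\d+)_?               # bounded spacer X_a-b
  | X_(\d+)_?                     # fixed spacer X_k
  | X_N_?                         # open spacer X_n (input is upper-cased)
  | X                             # wildcard position
  | ([A-Z])((?:/[A-Z])+)          # trailing alternation Y/R (binds one position)
  | ([A-Z])                       # fixed residue
    """,
    re.VERBOSE,
)


def parse_motif(text: str, xn_max: int = DEFAULT_XN_MAX) -> MotifPattern:
    """Parse one motif token string into a :class:`MotifPattern`.

    Parameters
    ----------
    text:
        Motif in the printed notation, e.g. ``"GXSXX(T/S/G)"`` or
        ``"HXXGHXXGX_3-8_H"``.  Case-insensitive.
    xn_max:
        Upper bound substituted for the open spacer ``X_n``.
    """
    if not isinstance(text, str) or not text.strip():
        raise MotifParseError("empty motif text")
    s = text.strip().upper().replace(" ", "")
    elements = []
    pos = 0
    while pos < len(s):
        m = _TOKEN_RE.match(s, pos)
        if m is None:
            raise MotifParseError(
                f"cannot parse motif {text!r} at {s[pos:pos + 8]!r}"
            )
        alt, lo, hi, fixed_k, single, single_alts, residue = (
            m.group(1), m.group(2), m.group(3), m.group(4),
            m.group(5), m.group(6), m.group(7),
        )
        if alt is not None:
            residues = frozenset(alt.split("/"))
            elements.append(MotifElement("residue-set", residues=residues))
        elif lo is not None:
            a, b = int(lo), int(hi)
            if a > b:
                raise MotifParseError(
                    f"gap bounds {a}-{b} reversed in motif {text!r}"
                )
            elements.append(MotifElement("gap", min_gap=a, max_gap=b))
        elif fixed_k is not None:
            k = int(fixed_k)
            elements.append(MotifElement("gap", min_gap=k, max_gap=k))
        elif m.group(0).startswith("X_N") or m.group(0) == "X_n":
            elements.append(MotifElement("gap", min_gap=1, max_gap=xn_max))
        elif m.group(0) == "X":
            elements.append(
                MotifElement("residue-set", residues=STANDARD_RESIDUES)
            )
        elif single is not None:
            residues = frozenset([single, *single_alts.strip("/").split("/")])
            elements.append(MotifElement("residue-set", residues=residues))
        elif residue is not None:
            if residue not in STANDARD_RESIDUES:
                raise MotifParseError(
                    f"{residue!r} is not a standard residue code in {text!r}"
                )
            elements.append(
                MotifElement("residue-set", residues=frozenset(residue))
            )
        pos = m.end()
    return MotifPattern(source_text=text.strip(), elements=tuple(elements))


def parse_architecture(
    text: str, xn_max: int = DEFAULT_XN_MAX
) -> list[MotifPattern]:
    """Split a printed architecture cell on '+' (or the ideographic comma
    variant) and parse each component."""
    s = text
    for sep in COMPONENT_SEPARATORS[1:]:
        s = s.replace(sep, COMPONENT_SEPARATORS[0])
    parts = [p.strip() for p in s.split(COMPONENT_SEPARATORS[0]) if p.strip()]
    if not parts:
        raise MotifParseError(f"architecture {text!r} has no components")
    return [parse_motif(p, xn_max=xn_max) for p in parts]


def clean_sequence(sequence: str) -> str:
    """Normalise an input protein sequence: upper-case, strip gap ('-') and
    stop ('*') symbols with a warning, reject anything else non-alphabetic."""
    seq = (sequence or "").upper()
    if "*" in seq or "-" in seq:
        warnings.warn(
            "sequence contains '*' or '-' symbols; stripping them",
            stacklevel=2,
        )
        seq = seq.replace("*", "").replace("-", "")
    bad = set(seq) - STANDARD_RESIDUES - NONSTANDARD_RESIDUES
    if bad:
        raise ValueError(f"sequence contains non-residue symbols: {sorted(bad)}")
    return seq


def scan(
    sequence: str, pattern: MotifPattern, *, min_start: int = 1
) -> list[MotifMatch]:
    """All occurrences of ``pattern`` in ``sequence``.

    One match is reported per feasible start position — for gapped patterns
    the shortest feasible spacer assignment (minimised left to right) wins.
    Positions holding non-standard codes (B/J/O/U/Z/X) satisfy only wildcard
    elements and spacers.  Returns matches in start order, 1-based inclusive
    coordinates.
    """
    seq = clean_sequence(sequence)
    if not seq:
        return []
    rx = pattern.compiled
    out = []
    for s0 in range(min_start - 1, len(seq) - pattern.min_length + 1):
        m = rx.match(seq, s0)
        if m is not None:
            out.append(
                MotifMatch(
                    pattern=pattern,
                    start=s0 + 1,
                    end=m.end(),
                    matched_text=seq[s0:m.end()],
                )
            )
    return out


def find_first(
    sequence: str, pattern: MotifPattern, *, min_start: int = 1
) -> Optional[MotifMatch]:
    """Leftmost match starting at or after ``min_start`` (1-based)."""
    seq = clean_sequence(sequence)
    if not seq:
        return None
    rx = pattern.compiled
    m = rx.search(seq, min_start - 1)
    if m is None:
        return None
    return MotifMatch(
        pattern=pattern,
        start=m.start() + 1,
        end=m.end(),
        matched_text=seq[m.start():m.end()],
    )


@dataclass(frozen=True)
class GapBounds:
    """Inter-component spacing for architectures (residues between the end
    of one component and the start of the next)."""

    min_gap: int = 0
    max_gap: Optional[int] = None  # None = unbounded


def match_architecture(
    sequence: str,
    components: Sequence[MotifPattern],
    inter_gap: GapBounds = GapBounds(),
    roles: Optional[Sequence[str]] = None,
    rule_id: str = "",
) -> ArchitectureMatch:
    """Locate an ordered component architecture on a sequence.

    Greedy leftmost assignment: components are taken in order; each must
    begin at least ``inter_gap.min_gap`` residues after the previous
    component's end (and at most ``inter_gap.max_gap`` after it, when
    bounded).  A component with no feasible occurrence is recorded absent
    and the search continues from the same position.  Components are never
    reordered and matched components never overlap.
    """
    if not components:
        raise ValueError("architecture needs at least one component")
    if roles is None:
        roles = ["catalytic"] * len(components)
    if len(roles) != len(components):
        raise ValueError("one role per component required")
    seq = clean_sequence(sequence)
    matches = []
    cursor = 1  # minimum 1-based start for the next component
    for idx, comp in enumerate(components):
        hit = find_first(seq, comp, min_start=cursor) if seq else None
        if hit is not None and inter_gap.max_gap is not None and matches:
            prev_end = next(
                (m.end for _, m in reversed(matches) if m is not None), None
            )
            if prev_end is not None and hit.start - prev_end - 1 > inter_gap.max_gap:
                hit = None
        matches.append((idx, hit))
        if hit is not None:
            cursor = hit.end + 1 + inter_gap.min_gap
    matched = [m for _, m in matches if m is not None]
    n_cat = sum(
        1
        for (idx, m) in matches
        if m is not None and roles[idx] == "catalytic"
    )
    specificity = sum(m.pattern.n_fixed for m in matched)
    cat_spec = sum(
        m.pattern.n_fixed
        for (idx, m) in matches
        if m is not None and roles[idx] == "catalytic"
    )
    return ArchitectureMatch(
        rule_id=rule_id,
        component_matches=tuple(matches),
        n_matched=len(matched),
        n_catalytic_matched=n_cat,
        specificity=specificity,
        catalytic_specificity=cat_spec,
    )
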