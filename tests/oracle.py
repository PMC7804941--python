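"""Exhaustive brute-force motif matcher, independent of the scanner.

Enumerates every start position and every combination of gap lengths
and checks residues directly against the element sets.  Used as the
ground-truth oracle: the production scanner must reproduce its output
exactly on bounded-gap patterns.
"""

from itertools import product

from degradome.motifs import STANDARD_RESIDUES


def _element_accepts(element, ch: str) -> bool:
    if element.is_wildcard:
        return True  # wildcards accept standard and non-standard codes
    return ch in element.residues  # non-standard codes fail fixed sets


def brute_force_scan(sequence: str, pattern):
    """All matches as (start, end, text), 1-based inclusive; one match per
    feasible start — the lexicographically shortest gap assignment wins."""
    seq = sequence.upper()
    gaps = [e for e in pattern.elements if e.kind == "gap"]
    gap_ranges = [range(g.min_gap, g.max_gap + 1) for g in gaps]
    out = []
    for start in range(len(seq)):
        found = None
        for combo in product(*gap_ranges):  # lexicographic by construction
            pos = start
            it = iter(combo)
            ok = True
            for e in pattern.elements:
                if e.kind == "gap":
                    n = next(it)
                    if pos + n > len(seq):
                        ok = False
                        break
                    pos += n  # spacer accepts any residues
                else:
                    if pos >= len(seq) or not _element_accepts(e, seq[pos]):
                        ok = False
                        break
                    pos += 1
            if ok:
                found = (start + 1, pos, seq[start:pos])
                break
        if found:
            out.append(found)
    return out
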