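"""Ground-truth-labelled synthetic inputs for the pipeline.

Each synthetic protein carries exactly one planted family architecture:
the rule's components are instantiated left to right (one residue drawn
per wildcard/alternation position, one length per spacer), separated
and flanked by background-composition residues.  Optionally one
catalytic-role residue is knocked out (replaced by a residue outside
the motif element's allowed set), which is the signature of a
putatively inactive family member.  A six-predictor localization call
table is emitted alongside, each call flipping from the true secretion
label independently with a configurable error rate.

The generator emulates the statistical structure the classifier
assumes — one architecture per protein, components in catalogue order —
not real A. niger sequence composition or paralogy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from .catalogue import Catalogue
from .classify import _match_rule, _score, classify_records
from .localization import PredictorCall, consensus_vote
from .motifs import STANDARD_RESIDUES, MotifElement

RESIDUES = sorted(STANDARD_RESIDUES)

#: The six predictor slots emulated in call tables.
PREDICTORS = ("signalp", "wolf-psort", "predisi", "cello", "phobius", "targetp")

#: Default family mix: families whose rules carry at least two
#: catalytic-role components, so a single catalytic knockout leaves the
#: family recognizable (as for the putatively inactive inventory members,
#: which retain at least one consensus catalytic residue).
DEFAULT_FAMILY_MIX = {"A1A": 0.3, "S8A": 0.3, "S53": 0.2, "S54": 0.2}

#: Default true-secretion fraction: the secretome share of the degradome
#: (62 of 232 proteases).
DEFAULT_SECRETED_FRACTION = 62 / 232

MAX_REJECTIONS = 100


class SimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class SimulationConfig:
    n_records: int = 100
    family_mix: dict = field(
        default_factory=lambda: dict(DEFAULT_FAMILY_MIX)
    )
    flank_range: tuple = (20, 60)  # residues before/after/between components
    background: Optional[dict] = None  # residue -> frequency; None = uniform
    knockout_rate: float = 0.0
    predictor_error_rate: float = 0.0
    secreted_fraction: float = DEFAULT_SECRETED_FRACTION
    seed: int = 0

    def __post_init__(self):
        if self.n_records < 0:
            raise SimulationError("n_records must be non-negative")
        if abs(sum(self.family_mix.values()) - 1.0) > 1e-9:
            raise SimulationError("family mix proportions must sum to 1")
        for name, rate in (("knockout_rate", self.knockout_rate),
                           ("predictor_error_rate", self.predictor_error_rate),
                           ("secreted_fraction", self.secreted_fraction)):
            if not 0.0 <= rate <= 1.0:
                raise SimulationError(f"{name} must lie in [0, 1]")
        if self.seed is None:
            raise SimulationError("a seed is mandatory")


@dataclass(frozen=True)
class TruthRecord:
    seq_id: str
    subfamily_id: str
    knocked_out: bool
    secreted: bool
    calls: tuple  # (predictor, call) pairs as emitted


def _background_probs(background: Optional[dict]) -> np.ndarray:
    if background is None:
        return np.full(len(RESIDUES), 1.0 / len(RESIDUES))
    p = np.array([background.get(r, 0.0) for r in RESIDUES], dtype=float)
    if p.sum() <= 0:
        raise SimulationError("background frequencies sum to zero")
    return p / p.sum()


def _draw_flank(rng: np.random.Generator, length: int, probs) -> str:
    if length <= 0:
        return ""
    idx = rng.choice(len(RESIDUES), size=length, p=probs)
    return "".join(RESIDUES[i] for i in idx)


def _instantiate_element(rng: np.random.Generator, e: MotifElement,
                         probs) -> str:
    if e.kind == "gap":
        n = int(rng.integers(e.min_gap, e.max_gap + 1))
        return _draw_flank(rng, n, probs)
    return rng.choice(sorted(e.residues))


def _instantiate_component(rng, pattern, probs) -> tuple:
    """Realise one motif; returns (text, catalytic-position offsets)."""
    text = []
    fixed_offsets = []
    pos = 0
    for e in pattern.elements:
        piece = _instantiate_element(rng, e, probs)
        if e.kind == "residue-set" and not e.is_wildcard:
            fixed_offsets.append((pos, e))
        text.append(piece)
        pos += len(piece)
    return "".join(text), fixed_offsets


def _knockout(rng, residue_sets) -> str:
    """A residue outside every allowed set for the chosen position."""
    allowed = residue_sets
    candidates = [r for r in RESIDUES if r not in allowed]
    return str(rng.choice(candidates))


def _planted_key(catalogue, rule, sequence):
    arch = _match_rule(sequence, rule)
    order = next(
        i for i, r in enumerate(catalogue.matchable_rules)
        if r.subfamily_id == rule.subfamily_id
    )
    return _score(arch, order), arch


def _spurious_winner(catalogue, rule, sequence, planted_key) -> bool:
    """True when another rule's full catalytic architecture is accidentally
    present AND would outrank the planted one."""
    for order, other in enumerate(catalogue.matchable_rules):
        if other.subfamily_id == rule.subfamily_id:
            continue
        arch = _match_rule(sequence, other)
        n_cat_total = len(other.catalytic_components)
        if arch.n_catalytic_matched == n_cat_total and n_cat_total > 0:
            if _score(arch, order) > planted_key:
                return True
    return False


def generate(config: SimulationConfig, catalogue: Catalogue):
    """Generate (fasta_records, calls, truths).

    ``fasta_records`` is a list of (seq_id, sequence) pairs; ``calls`` a
    flat list of :class:`~degradome.localization.PredictorCall`; ``truths``
    the matching :class:`TruthRecord` list.  Fully reproducible from
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    probs = _background_probs(config.background)
    lo, hi = config.flank_range
    families = sorted(config.family_mix)
    weights = np.array([config.family_mix[f] for f in families])
    for f in families:
        rule = catalogue.lookup_rule(f)
        if not rule.components:
            raise SimulationError(f"family {f} is motif-free; cannot plant it")

    fasta, calls, truths = [], [], []
    for i in range(config.n_records):
        seq_id = f"syn{i + 1:04d}"
        family = families[int(rng.choice(len(families), p=weights))]
        rule = catalogue.lookup_rule(family)
        knocked = bool(rng.random() < config.knockout_rate)
        secreted = bool(rng.random() < config.secreted_fraction)

        n_cat_total = len(rule.catalytic_components)
        seq = None
        for _attempt in range(MAX_REJECTIONS):
            pieces = [_draw_flank(rng, int(rng.integers(lo, hi + 1)), probs)]
            catalytic_sites = []  # (piece index, offset, element)
            for comp in rule.components:
                text, fixed = _instantiate_component(rng, comp.pattern, probs)
                idx = len(pieces)
                pieces.append(text)
                if comp.role == "catalytic":
                    for off, e in fixed:
                        catalytic_sites.append((idx, off, e))
                pieces.append(
                    _draw_flank(rng, int(rng.integers(lo, hi + 1)), probs)
                )
            intact = "".join(pieces)
            key, _arch = _planted_key(catalogue, rule, intact)
            if _spurious_winner(catalogue, rule, intact, key):
                continue  # flanks created a rival architecture; redraw
            if not (knocked and catalytic_sites):
                seq = intact
                break
            k = int(rng.integers(len(catalytic_sites)))
            idx, off, e = catalytic_sites[k]
            piece = pieces[idx]
            pieces[idx] = (
                piece[:off] + _knockout(rng, e.residues) + piece[off + 1:]
            )
            candidate = "".join(pieces)
            key_deg, arch_deg = _planted_key(catalogue, rule, candidate)
            # the knockout must genuinely remove the consensus residue: the
            # knocked component may not survive via an accidental copy, and
            # the degraded architecture must still out-score rival rules so
            # the family remains recognizable
            if arch_deg.n_catalytic_matched >= n_cat_total:
                continue
            if _spurious_winner(catalogue, rule, candidate, key_deg):
                continue
            seq = candidate
            break
        if seq is None:
            raise SimulationError(
                f"could not generate a clean sequence for {family} after "
                f"{MAX_REJECTIONS} attempts"
            )
        fasta.append((seq_id, seq))

        emitted = []
        for pred in PREDICTORS:
            truth_call = "secreted" if secreted else "non-secreted"
            if rng.random() < config.predictor_error_rate:
                call = "non-secreted" if secreted else "secreted"
            else:
                call = truth_call
            emitted.append((pred, call))
            calls.append(PredictorCall(seq_id, pred, call))
        truths.append(
            TruthRecord(
                seq_id=seq_id,
                subfamily_id=family,
                knocked_out=knocked,
                secreted=secreted,
                calls=tuple(emitted),
            )
        )
    return fasta, calls, truths


def majority_vote_accuracy(error_rate: float,
                           secreted_fraction: float = DEFAULT_SECRETED_FRACTION,
                           n_predictors: int = len(PREDICTORS)) -> float:
    """Closed-form probability that the strict-majority consensus over
    ``n_predictors`` independent calls (each flipped with ``error_rate``)
    recovers the true label.

    A truly secreted protein is recovered when more than half the calls
    say secreted (flips < n/2 for even n means flips <= n/2 - 1); a truly
    non-secreted protein tolerates up to half the calls flipping.
    """
    n = n_predictors
    need_secreted = (n // 2) + 1  # strict majority
    # truth secreted: survives <= n - need flips; truth non-secreted:
    # survives <= need - 1 flips (a tie is called non-secreted)
    p_ok_secreted = float(sps.binom.cdf(n - need_secreted, n, error_rate))
    p_ok_nonsecreted = float(sps.binom.cdf(need_secreted - 1, n, error_rate))
    return (
        secreted_fraction * p_ok_secreted
        + (1 - secreted_fraction) * p_ok_nonsecreted
    )


@dataclass(frozen=True)
class RecoveryMetrics:
    n: int
    family_accuracy: float
    activity_accuracy: float
    secretion_accuracy: float
    no_data: bool = False


def recovery_experiment(config: SimulationConfig,
                        catalogue: Catalogue) -> RecoveryMetrics:
    """generate -> classify -> vote, scored against the generator's truth."""
    fasta, calls, truths = generate(config, catalogue)
    if not truths:
        return RecoveryMetrics(0, 0.0, 0.0, 0.0, no_data=True)
    results = classify_records(fasta, catalogue)
    consensus = consensus_vote(calls)
    fam_ok = act_ok = sec_ok = 0
    for truth, res in zip(truths, results):
        if res.best_rule == truth.subfamily_id:
            fam_ok += 1
        expected_activity = (
            "putatively-inactive" if truth.knocked_out else "active"
        )
        if res.activity == expected_activity:
            act_ok += 1
        verdict = consensus[truth.seq_id].call
        expected_verdict = "secreted" if truth.secreted else "non-secreted"
        if verdict == expected_verdict:
            sec_ok += 1
    n = len(truths)
    return RecoveryMetrics(
        n=n,
        family_accuracy=fam_ok / n,
        activity_accuracy=act_ok / n,
        secretion_accuracy=sec_ok / n,
    )


def write_fasta(fasta, path) -> None:
    with open(path, "w") as fh:
        for seq_id, seq in fasta:
            fh.write(f">{seq_id}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")


def write_calls_tsv(calls, path) -> None:
    with open(path, "w") as fh:
        fh.write("seq_id\tpredictor\tcall\n")
        for c in calls:
            fh.write(f"{c.seq_id}\t{c.predictor}\t{c.call}\n")


def write_truth_tsv(truths, path) -> None:
    with open(path, "w") as fh:
        fh.write("seq_id\tsubfamily\tknocked_out\tsecreted\n")
        for t in truths:
            fh.write(
                f"{t.seq_id}\t{t.subfamily_id}\t{int(t.knocked_out)}\t"
                f"{int(t.secreted)}\n"
            )
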