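"""Consensus subcellular localization and EC-bucket assignment.

Secretion calls from up to six independent localization predictors are
combined by majority vote: a protein is called secreted when the
fraction of its non-missing calls voting "secreted" strictly exceeds
the threshold (default 0.5 — a 3–3 split is conservatively called
non-secreted, and calls for other compartments count against
secretion).  Proteins with fewer than four usable calls are left
undetermined.

EC buckets are the sub-subfamily categories of peptidase nomenclature
(EC 3.4.11–3.4.99), grouped into exopeptidases, endopeptidases, and
unknown.
"""

from __future__ import annotations

import csv
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Optional, Tuple, Union

from .catalogue import EC_SIDE, UNASSIGNED, Catalogue

CALLS = ("secreted", "non-secreted", "other-compartment", "missing")
MIN_CALLS = 4


@dataclass(frozen=True)
class PredictorCall:
    seq_id: str
    predictor: str
    call: str

    def __post_init__(self):
        if self.call not in CALLS:
            raise ValueError(
                f"{self.seq_id}/{self.predictor}: unknown call {self.call!r}"
            )


@dataclass(frozen=True)
class Consensus:
    seq_id: str
    call: str  # secreted | non-secreted | undetermined
    n_secreted: int
    n_total: int  # non-missing calls


class VoteError(ValueError):
    pass


def consensus_vote(
    calls: Iterable[Union[PredictorCall, Tuple[str, str, str]]],
    threshold: float = 0.5,
) -> dict:
    """Combine per-predictor calls into one consensus per protein.

    Returns ``{seq_id: Consensus}``.  Duplicate (seq_id, predictor) rows
    with conflicting calls raise :class:`VoteError`.
    """
    if not 0 <= threshold < 1:
        raise VoteError(f"threshold {threshold} outside [0, 1)")
    table = defaultdict(dict)
    for c in calls:
        if not isinstance(c, PredictorCall):
            c = PredictorCall(*c)
        prev = table[c.seq_id].get(c.predictor)
        if prev is not None and prev != c.call:
            raise VoteError(
                f"conflicting calls for {c.seq_id}/{c.predictor}: "
                f"{prev} vs {c.call}"
            )
        table[c.seq_id][c.predictor] = c.call
    out = {}
    for seq_id, per_pred in table.items():
        usable = [v for v in per_pred.values() if v != "missing"]
        n_sec = sum(1 for v in usable if v == "secreted")
        if len(usable) < MIN_CALLS:
            verdict = "undetermined"
        elif n_sec / len(usable) > threshold:
            verdict = "secreted"
        else:
            verdict = "non-secreted"
        out[seq_id] = Consensus(
            seq_id=seq_id, call=verdict, n_secreted=n_sec, n_total=len(usable)
        )
    return out


def read_calls_tsv(path) -> list:
    with open(path, newline="") as fh:
        return [
            PredictorCall(row["seq_id"], row["predictor"], row["call"])
            for row in csv.DictReader(fh, delimiter="\t")
        ]


def write_consensus_tsv(consensus: dict, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["seq_id", "consensus", "n_secreted", "n_total"])
        for seq_id in sorted(consensus):
            c = consensus[seq_id]
            w.writerow([c.seq_id, c.call, c.n_secreted, c.n_total])


# ---------------------------------------------------------------- EC buckets

@dataclass(frozen=True)
class ECBucket:
    bucket: str
    side: str  # exo | endo | unknown

    def __post_init__(self):
        if self.bucket not in EC_SIDE:
            raise ValueError(f"unknown EC bucket {self.bucket!r}")
        if EC_SIDE[self.bucket] != self.side:
            raise ValueError(
                f"bucket {self.bucket} is {EC_SIDE[self.bucket]}, not {self.side}"
            )


def ec_bucket(bucket: str) -> ECBucket:
    return ECBucket(bucket=bucket, side=EC_SIDE.get(bucket, "unknown"))


def assign_ec_bucket(record, catalogue: Optional[Catalogue] = None) -> ECBucket:
    """EC bucket for an inventory record or classification result.

    A record's own ``ec_bucket`` field wins (subfamilies hosting both exo-
    and endopeptidases are resolved per record in the inventory); otherwise
    the catalogue's subfamily-level bucket applies; anything unmapped is
    ``unknown``.
    """
    own = getattr(record, "ec_bucket", None)
    if own:
        return ec_bucket(own)
    subfamily = (
        getattr(record, "subfamily_id", None)
        or getattr(record, "best_rule", None)
    )
    if catalogue is not None and subfamily and subfamily != UNASSIGNED \
            and catalogue.has_rule(subfamily):
        return ec_bucket(catalogue.lookup_rule(subfamily).ec_bucket)
    return ec_bucket("unknown")
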