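"""Recombination Information Content (RIC) scoring of RSSs.

An RSS (recombination signal sequence) is a conserved heptamer, a 12- or
23-nt spacer, and a conserved nonamer.  The RIC score is the log-likelihood
of an RSS under a grouped-position probability model: positions are
partitioned into groups of correlated sites, each group carries a joint
nucleotide-tuple distribution estimated from a training set, and the score
is the sum over groups of the log probability of the query's tuple.  Scores
range from very negative (poor recombination substrate) up to 0; functional
V RSSs scoring below -45 are classified as "very low".

Storage convention: every RSS is stored heptamer-first
(heptamer -> spacer -> nonamer), so V-3' and D-3' RSSs are 23-spacer
(39 nt) and D-5' and J-5' RSSs are 12-spacer (28 nt); a J RSS written
nonamer-first on the genome is reversed into this order at ingest.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

CONSENSUS_HEPTAMER = "CACAGTG"
CONSENSUS_NONAMER = "ACAAAAACC"
VERY_LOW_THRESHOLD = -45.0
NUCLEOTIDES = "ACGT"

RICKind = Literal["RIC12", "RIC23"]
Side = Literal["V3", "D5", "D3", "J5"]

#: spacer length expected on each gene side (heptamer-first convention)
SIDE_SPACER = {"V3": 23, "D3": 23, "D5": 12, "J5": 12}

# Grouped-position partitions of the 39-nt (23-spacer) and 28-nt (12-spacer)
# RSS.  Positions are 1-based over heptamer+spacer+nonamer.
_GROUPS_23: tuple[tuple[int, ...], ...] = (
    (1,), (2,), (3,), (4, 14), (5, 39), (6,), (7, 24, 25), (8, 9, 21),
    (10, 16), (11, 12), (13, 22), (15, 23), (17, 18),
    (19, 27, 30, 31, 32, 33, 37), (20, 26), (28, 29), (34, 38), (35, 36),
)
_GROUPS_12: tuple[tuple[int, ...], ...] = (
    (1,), (2,), (3, 15, 25), (4, 5), (6, 28), (7, 8, 19), (9, 26),
    (10, 12), (11, 27), (13, 14, 23), (16, 17, 18), (20, 21, 22), (24,),
)


class RICError(ValueError):
    """Invalid RSS, grouping, or model input."""


@dataclass(frozen=True)
class RSSSequence:
    """One RSS in canonical heptamer-first orientation."""

    gene: str
    side: Side
    spacer_len: int
    seq: str

    def __post_init__(self) -> None:
        if self.spacer_len not in (12, 23):
            raise RICError(f"spacer length must be 12 or 23, got {self.spacer_len}")
        expected = 7 + self.spacer_len + 9
        if len(self.seq) != expected:
            raise RICError(
                f"RSS for {self.gene!r} has length {len(self.seq)}, "
                f"expected {expected} for a {self.spacer_len}-spacer RSS"
            )
        bad = set(self.seq) - set(NUCLEOTIDES)
        if bad:
            raise RICError(
                f"RSS for {self.gene!r} contains non-ACGT symbols {sorted(bad)}"
            )

    @property
    def kind(self) -> RICKind:
        return "RIC23" if self.spacer_len == 23 else "RIC12"

    @property
    def heptamer(self) -> str:
        return self.seq[:7]

    @property
    def nonamer(self) -> str:
        return self.seq[-9:]


@dataclass(frozen=True)
class PositionGrouping:
    """A partition of RSS positions 1..L into correlated-position groups."""

    kind: RICKind
    groups: tuple[tuple[int, ...], ...]

    def __post_init__(self) -> None:
        L = self.length
        flat = [p for g in self.groups for p in g]
        if sorted(flat) != list(range(1, L + 1)):
            raise RICError(
                f"groups for {self.kind} must partition positions 1..{L}"
            )

    @property
    def length(self) -> int:
        return 39 if self.kind == "RIC23" else 28


def default_grouping(kind: RICKind) -> PositionGrouping:
    """The canonical correlated-position partitions for 23- and 12-RSSs."""
    if kind == "RIC23":
        return PositionGrouping("RIC23", _GROUPS_23)
    if kind == "RIC12":
        return PositionGrouping("RIC12", _GROUPS_12)
    raise RICError(f"unknown RIC kind {kind!r}")


@dataclass
class RICModel:
    """Grouped-position probability tables fitted to a training RSS set.

    ``tables[i]`` maps nucleotide tuples (as strings) of group i's arity to
    probabilities; unlisted tuples have the pseudocount-only baseline
    probability ``pseudocount / (n_train + pseudocount * 4**arity)``.
    """

    grouping: PositionGrouping
    tables: list[dict[str, float]]
    pseudocount: float
    n_train: int

    def group_probability(self, gi: int, tup: str) -> float:
        group = self.grouping.groups[gi]
        base = self.pseudocount / (self.n_train + self.pseudocount * 4 ** len(group))
        return self.tables[gi].get(tup, base)


@dataclass(frozen=True)
class RICScore:
    """A RIC log-likelihood with its quality label.

    ``finite`` is False when some group tuple had zero probability (only
    possible at pseudocount 0), in which case ``value`` is -inf.
    """

    value: float
    label: Literal["normal", "very_low"]
    finite: bool = True


def _tuple_at(seq: str, group: Sequence[int]) -> str:
    return "".join(seq[p - 1] for p in group)


def train_ric(
    sequences: Iterable[RSSSequence],
    grouping: PositionGrouping | None = None,
    pseudocount: float = 1.0,
) -> RICModel:
    """Fit per-group tuple probabilities by pseudocounted empirical frequency.

    For a group of arity k, P(tuple) = (count + pseudocount) /
    (n_train + pseudocount * 4**k).
    """
    seqs = list(sequences)
    if not seqs:
        raise RICError("cannot train a RIC model on an empty sequence set")
    if pseudocount < 0:
        raise RICError("pseudocount must be nonnegative")
    if grouping is None:
        grouping = default_grouping(seqs[0].kind)
    L = grouping.length
    for s in seqs:
        if len(s.seq) != L:
            raise RICError(
                f"sequence for {s.gene!r} has length {len(s.seq)}, "
                f"model grouping expects {L}"
            )
    n = len(seqs)
    tables: list[dict[str, float]] = []
    for group in grouping.groups:
        counts: dict[str, int] = {}
        for s in seqs:
            tup = _tuple_at(s.seq, group)
            counts[tup] = counts.get(tup, 0) + 1
        denom = n + pseudocount * 4 ** len(group)
        tables.append({t: (c + pseudocount) / denom for t, c in counts.items()})
    return RICModel(grouping=grouping, tables=tables, pseudocount=pseudocount, n_train=n)


def ric_score(
    model: RICModel, seq: RSSSequence | str, threshold: float = VERY_LOW_THRESHOLD
) -> RICScore:
    """Score an RSS: sum over groups of ln P(group tuple)."""
    s = seq.seq if isinstance(seq, RSSSequence) else seq
    if len(s) != model.grouping.length:
        raise RICError(
            f"query length {len(s)} does not match model length "
            f"{model.grouping.length}"
        )
    total = 0.0
    for gi, group in enumerate(model.grouping.groups):
        p = model.group_probability(gi, _tuple_at(s, group))
        if p == 0.0:
            return RICScore(value=-math.inf, label="very_low", finite=False)
        total += math.log(p)
    return RICScore(value=total, label=classify_rss(total, threshold))


def classify_rss(
    score: float, threshold: float = VERY_LOW_THRESHOLD
) -> Literal["normal", "very_low"]:
    """Label a RIC score; "very_low" strictly below the threshold."""
    if not math.isfinite(score):
        raise RICError("cannot classify a non-finite RIC score")
    return "very_low" if score < threshold else "normal"


# ---------------------------------------------------------------------------
# FASTA and JSON interchange


def write_rss_fasta(sequences: Iterable[RSSSequence], path: str | Path) -> None:
    """Write RSSs as FASTA with headers ``gene|side|spacer_len``."""
    records = [
        SeqRecord(Seq(s.seq), id=f"{s.gene}|{s.side}|{s.spacer_len}", description="")
        for s in sequences
    ]
    SeqIO.write(records, str(path), "fasta")


def read_rss_fasta(path: str | Path) -> list[RSSSequence]:
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        try:
            gene, side, spacer = rec.id.split("|")
        except ValueError:
            raise RICError(
                f"FASTA header {rec.id!r} is not of the form gene|side|spacer_len"
            ) from None
        out.append(
            RSSSequence(
                gene=gene, side=side, spacer_len=int(spacer), seq=str(rec.seq).upper()
            )
        )
    return out


def model_to_dict(model: RICModel) -> dict:
    return {
        "kind": model.grouping.kind,
        "groups": [list(g) for g in model.grouping.groups],
        "tables": model.tables,
        "pseudocount": model.pseudocount,
        "n_train": model.n_train,
    }


def model_from_dict(payload: dict) -> RICModel:
    grouping = PositionGrouping(
        kind=payload["kind"], groups=tuple(tuple(g) for g in payload["groups"])
    )
    return RICModel(
        grouping=grouping,
        tables=[dict(t) for t in payload["tables"]],
        pseudocount=float(payload["pseudocount"]),
        n_train=int(payload["n_train"]),
    )


def write_model_json(model: RICModel, path: str | Path) -> None:
    Path(path).write_text(json.dumps(model_to_dict(model)) + "\n")


def read_model_json(path: str | Path) -> RICModel:
    return model_from_dict(json.loads(Path(path).read_text()))
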