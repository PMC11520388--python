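"""TRB locus representation, gene distances, and distal/middle/proximal zoning.

The locus is an ordered catalog of V, D, J and C gene segments with
locus-relative start coordinates.  "Distal", "middle" and "proximal" are
always defined relative to the D gene of a given recombination analysis:
V genes are partitioned into three contiguous blocks by the two largest
inter-gene gaps (or by explicit boundaries), and J genes follow fixed
positional rules per D-J cluster.

Coordinates are 0-based gene start positions on the locus-forward strand;
distances are absolute differences of start positions.  Strand is ignored
for zoning: inverted V genes (e.g. TRBV30 orthologs) are placed by start
coordinate only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

Segment = Literal["V", "D", "J", "C"]
Functionality = Literal["F", "ORF", "P"]
Zone = Literal["distal", "middle", "proximal"]

_SEGMENTS = {"V", "D", "J", "C"}
_FUNCTIONALITIES = {"F", "ORF", "P"}


class LocusError(ValueError):
    """Invalid locus structure or failed gene/cluster lookup."""


@dataclass(frozen=True)
class GeneRecord:
    """A single gene segment in the locus.

    ``cluster_id`` indexes the D-J-C cluster a D/J/C gene belongs to
    (1-based); V genes carry 0.
    """

    name: str
    segment: Segment
    functionality: Functionality
    start_bp: int
    cluster_id: int = 0

    def __post_init__(self) -> None:
        if self.segment not in _SEGMENTS:
            raise LocusError(f"unknown segment {self.segment!r} for gene {self.name!r}")
        if self.functionality not in _FUNCTIONALITIES:
            raise LocusError(
                f"unknown functionality {self.functionality!r} for gene {self.name!r}"
            )
        if self.start_bp < 0:
            raise LocusError(f"negative coordinate for gene {self.name!r}")
        if self.segment in ("D", "J") and self.cluster_id < 1:
            raise LocusError(f"{self.segment} gene {self.name!r} needs cluster_id >= 1")


@dataclass
class LocusModel:
    """An ordered TRB-style locus: V array followed by D-J-C clusters."""

    species: str
    genes: list[GeneRecord]

    def __post_init__(self) -> None:
        self.genes = sorted(self.genes, key=lambda g: g.start_bp)
        seen: set[str] = set()
        prev = -1
        for g in self.genes:
            if g.name in seen:
                raise LocusError(f"duplicate gene name {g.name!r}")
            seen.add(g.name)
            if g.start_bp == prev:
                raise LocusError(f"coordinates not strictly increasing at {g.name!r}")
            prev = g.start_bp
        self._by_name = {g.name: g for g in self.genes}
        for cid in range(1, self.n_dj_clusters + 1):
            if not [g for g in self.genes if g.segment == "J" and g.cluster_id == cid]:
                raise LocusError(f"D-J cluster {cid} contains no J gene")

    @property
    def n_dj_clusters(self) -> int:
        return max((g.cluster_id for g in self.genes if g.segment == "D"), default=0)

    def gene(self, name: str) -> GeneRecord:
        try:
            return self._by_name[name]
        except KeyError:
            raise LocusError(f"unknown gene {name!r} in locus {self.species!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def segment_genes(
        self, segment: Segment, functional_only: bool = False, cluster_id: int | None = None
    ) -> list[GeneRecord]:
        out = [g for g in self.genes if g.segment == segment]
        if functional_only:
            out = [g for g in out if g.functionality == "F"]
        if cluster_id is not None:
            out = [g for g in out if g.cluster_id == cluster_id]
        return out

    def d_gene(self, cluster_id: int) -> GeneRecord:
        ds = [g for g in self.genes if g.segment == "D" and g.cluster_id == cluster_id]
        if not ds:
            raise LocusError(
                f"locus {self.species!r} has no D gene in cluster {cluster_id}"
            )
        return ds[0]

    def functionality_map(self) -> dict[str, str]:
        return {g.name: g.functionality for g in self.genes}


@dataclass
class ZoneAssignment:
    """Gene -> distal/middle/proximal mapping for one D-cluster analysis.

    ``boundaries`` records the rule applied: for gap-based V zoning the two
    boundary coordinates (bp midpoints of the chosen gaps), for rule-based
    J zoning a text description.
    """

    analysis: str
    zones: dict[str, Zone]
    boundaries: tuple[float, float] | str
    flags: list[str] = field(default_factory=list)

    def genes_in(self, zone: Zone) -> list[str]:
        return [g for g, z in self.zones.items() if z == zone]


def distance_to_d(locus: LocusModel, gene: str, d_gene: str) -> int:
    """Absolute bp distance between a gene's start and the D gene's start."""
    return abs(locus.gene(gene).start_bp - locus.gene(d_gene).start_bp)


def _two_largest_gaps(starts: Sequence[int]) -> tuple[int, int]:
    """Indices of the two gaps splitting ``starts`` into three blocks.

    Returns gap indices (i, j), i < j, where gap i lies between starts[i]
    and starts[i+1].  Ties are resolved by preferring the pair that
    maximizes the minimum block size, then the 5'-most pair.
    """
    gaps = [starts[i + 1] - starts[i] for i in range(len(starts) - 1)]
    order = sorted(range(len(gaps)), key=lambda i: (-gaps[i], i))
    cutoff = gaps[order[1]]
    # all gaps at least as large as the second-largest are tie candidates
    candidates = [i for i in range(len(gaps)) if gaps[i] >= cutoff]
    best: tuple[int, int] | None = None
    best_key: tuple[int, int, int] | None = None
    n = len(starts)
    for ai in range(len(candidates)):
        for bi in range(ai + 1, len(candidates)):
            i, j = candidates[ai], candidates[bi]
            if gaps[i] + gaps[j] < gaps[order[0]] + gaps[order[1]]:
                continue  # not actually a maximal pair
            blocks = (i + 1, j - i, n - 1 - j)
            key = (min(blocks), -i, -j)
            if best_key is None or key > best_key:
                best_key, best = key, (i, j)
    assert best is not None
    return best


def assign_v_zones(
    locus: LocusModel,
    method: Literal["largest-gaps", "explicit"] = "largest-gaps",
    boundaries: tuple[int, int] | None = None,
    d_cluster: int = 1,
) -> ZoneAssignment:
    """Partition functional V genes into distal/middle/proximal blocks.

    With ``method="largest-gaps"`` the two largest inter-gene gaps among
    consecutive functional V genes define three contiguous blocks; the block
    farthest from the analysis D gene is distal, the nearest proximal.
    With ``method="explicit"``, ``boundaries`` gives two bp positions lying
    strictly inside the V region and genes are split around them.
    """
    vs = locus.segment_genes("V", functional_only=True)
    if len(vs) < 3:
        raise LocusError(
            f"need >= 3 functional V genes to form three zones, found {len(vs)}"
        )
    starts = [g.start_bp for g in vs]
    if method == "largest-gaps":
        i, j = _two_largest_gaps(starts)
        b1 = (starts[i] + starts[i + 1]) / 2
        b2 = (starts[j] + starts[j + 1]) / 2
        blocks = [vs[: i + 1], vs[i + 1 : j + 1], vs[j + 1 :]]
    elif method == "explicit":
        if boundaries is None:
            raise LocusError("explicit zoning requires two boundary positions")
        b1, b2 = sorted(boundaries)
        if not (starts[0] < b1 and b2 < starts[-1]):
            raise LocusError("explicit boundaries must lie strictly inside the V region")
        blocks = [
            [g for g in vs if g.start_bp < b1],
            [g for g in vs if b1 <= g.start_bp < b2],
            [g for g in vs if b2 <= g.start_bp],
        ]
        if any(not b for b in blocks):
            raise LocusError("explicit boundaries leave an empty zone")
    else:
        raise LocusError(f"unknown zoning method {method!r}")

    d = locus.d_gene(d_cluster)
    # rank blocks by mean distance to D: farthest = distal, nearest = proximal
    dists = [
        sum(abs(g.start_bp - d.start_bp) for g in b) / len(b) for b in blocks
    ]
    order = sorted(range(3), key=lambda k: dists[k])
    labels: dict[int, Zone] = {order[0]: "proximal", order[1]: "middle", order[2]: "distal"}
    zones: dict[str, Zone] = {}
    for k, block in enumerate(blocks):
        for g in block:
            zones[g.name] = labels[k]
    return ZoneAssignment(
        analysis=f"V-to-D{d_cluster}", zones=zones, boundaries=(b1, b2)
    )


def assign_j_zones(locus: LocusModel, analysis: str) -> ZoneAssignment:
    """Zone J genes for a D-J recombination analysis.

    ``analysis`` is "D1-J", "D2-J2" or "D3-J".  For D1-J the two J genes of
    the first cluster closest to D1 are proximal and the last J gene of the
    last reachable cluster is distal; for D2-J2 (and D3-J analogously) the
    first J gene of the cluster is proximal and the last distal.  Everything
    else is middle.
    """
    rules = {"D1-J": 1, "D2-J2": 2, "D3-J": 3}
    if analysis not in rules:
        raise LocusError(f"unknown J-zone analysis {analysis!r}")
    cid = rules[analysis]
    if cid > locus.n_dj_clusters:
        raise LocusError(
            f"analysis {analysis!r} needs D-J cluster {cid}; locus "
            f"{locus.species!r} has {locus.n_dj_clusters}"
        )
    d = locus.d_gene(cid)
    if cid == 1:
        # all clusters downstream of D1 are reachable
        js = [
            g
            for g in locus.segment_genes("J", functional_only=True)
            if g.cluster_id >= 1
        ]
        first_cluster = sorted(
            (g for g in js if g.cluster_id == 1),
            key=lambda g: abs(g.start_bp - d.start_bp),
        )
        proximal = {g.name for g in first_cluster[:2]}
        last_cid = max(g.cluster_id for g in js)
        distal = {max((g for g in js if g.cluster_id == last_cid), key=lambda g: g.start_bp).name}
        rule = "two first-cluster J closest to D1 proximal; last J of last cluster distal"
    else:
        js = locus.segment_genes("J", functional_only=True, cluster_id=cid)
        if len(js) < 2:
            raise LocusError(f"cluster {cid} has too few J genes for zoning")
        ordered = sorted(js, key=lambda g: abs(g.start_bp - d.start_bp))
        proximal = {ordered[0].name}
        distal = {ordered[-1].name}
        rule = f"first J{cid} proximal, last J{cid} distal"
    zones: dict[str, Zone] = {}
    for g in js:
        if g.name in proximal:
            zones[g.name] = "proximal"
        elif g.name in distal:
            zones[g.name] = "distal"
        else:
            zones[g.name] = "middle"
    return ZoneAssignment(analysis=analysis, zones=zones, boundaries=rule)


# ---------------------------------------------------------------------------
# JSON interchange


def locus_to_dict(locus: LocusModel) -> dict:
    return {
        "species": locus.species,
        "genes": [
            {
                "name": g.name,
                "segment": g.segment,
                "functionality": g.functionality,
                "start_bp": g.start_bp,
                "cluster_id": g.cluster_id,
            }
            for g in locus.genes
        ],
    }


def locus_from_dict(payload: Mapping) -> LocusModel:
    genes = [
        GeneRecord(
            name=g["name"],
            segment=g["segment"],
            functionality=g["functionality"],
            start_bp=int(g["start_bp"]),
            cluster_id=int(g.get("cluster_id", 0)),
        )
        for g in payload["genes"]
    ]
    return LocusModel(species=payload["species"], genes=genes)


def write_locus_json(locus: LocusModel, path: str | Path) -> None:
    Path(path).write_text(json.dumps(locus_to_dict(locus), indent=1) + "\n")


def read_locus_json(path: str | Path) -> LocusModel:
    return locus_from_dict(json.loads(Path(path).read_text()))
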