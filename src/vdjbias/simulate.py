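"""Synthetic TRB loci, RSS catalogs, and biased clonotype repertoires.

The generator produces a human-like TRB locus (a V array in three
gap-separated blocks followed by D-J-C clusters), per-gene RSSs built from
the consensus heptamer/nonamer with controllable degradation, and
multi-sample clonotype tables whose per-gene usage weights follow a
softmax in zone effect and RSS quality:

    w_g  proportional to  exp(alpha_zone(g) + beta * RIC_g),

normalized within each segment.  V and J draws are independent.  Ground
truth (weights, zones, degraded genes) is returned and serializable next
to every output, so pipeline recovery is checkable end to end.

A configurable fraction of CDR3s is corrupted to exercise the productive
filter: unproductive ("_"/"*" inserted), malformed (C...F frame broken),
and pseudogene (V call reassigned to a non-functional gene).  The three
corruptions are applied to disjoint record subsets so per-rule removal
counts are predictable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .clonotypes import ClonotypeTable
from .locus import GeneRecord, LocusModel, assign_j_zones, assign_v_zones
from .ric import (
    CONSENSUS_HEPTAMER,
    CONSENSUS_NONAMER,
    RICModel,
    RSSSequence,
    ric_score,
    train_ric,
    write_rss_fasta,
)

_AA_INTERIOR = np.array(list("ADEGHIKLMNPQRSTVWY"), dtype="U1")
_NT = np.array(list("ACGT"), dtype="U1")
# fixed reverse-translation table (one codon per residue) for CDR3 nt strings
_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG", "M": "ATG", "N": "AAT",
    "P": "CCT", "Q": "CAA", "R": "CGT", "S": "TCT", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAT",
}


class SimulationError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimConfig:
    """Study conditions for the synthetic repertoire.

    Defaults emulate a human-like TRB locus (24 functional V genes in three
    blocks of 8, two D-J-C clusters with 6+7 J genes) sampled at bulk
    repertoire depth, with a moderate zone bias favouring proximal and
    distal genes over middle ones and a mild positive RSS-quality effect.
    """

    n_v: int = 24
    n_pseudo_v: int = 2
    n_j: int = 13
    n_dj_clusters: int = 2
    v_block_spacing_bp: int = 5_000
    zone_gap_bp: int = 100_000
    zone_effects: dict[str, float] = field(
        default_factory=lambda: {"distal": 1.0, "middle": 0.0, "proximal": 1.2}
    )
    ric_effect: float = 0.15
    rss_mutation_rate: float = 0.05
    elevated_rss_mutation_rate: float = 0.65
    n_low_quality_v: int = 0
    ric_pseudocount: float = 1.0
    unproductive_rate: float = 0.05
    malformed_rate: float = 0.03
    pseudogene_rate: float = 0.02
    d_call_rate: float = 0.7
    n_clonotypes: int = 50_000
    n_samples: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("rss_mutation_rate", "elevated_rss_mutation_rate",
                     "unproductive_rate", "malformed_rate", "pseudogene_rate",
                     "d_call_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimulationError(f"{name} must lie in [0, 1], got {v}")
        if self.n_clonotypes < 1:
            raise SimulationError("n_clonotypes must be >= 1")
        if set(self.zone_effects) != {"distal", "middle", "proximal"}:
            raise SimulationError("zone_effects must define all three zones")


@dataclass
class GroundTruth:
    """Generative truth serialized next to every simulated output."""

    v_zones: dict[str, str] = field(default_factory=dict)
    j_zones: dict[str, str] = field(default_factory=dict)
    weights: dict[str, dict[str, float]] = field(default_factory=dict)
    rss_mutation_counts: dict[str, int] = field(default_factory=dict)
    degraded_genes: list[str] = field(default_factory=list)
    ric_scores: dict[str, float] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True) + "\n")


def _split_three(n: int) -> list[int]:
    base, rem = divmod(n, 3)
    return [base + (1 if i < rem else 0) for i in range(3)]


def generate_locus(config: SimConfig, seed: int | None = None) -> tuple[LocusModel, GroundTruth]:
    """Build a synthetic TRB locus with known V zone blocks.

    Functional V genes are laid out in three contiguous blocks separated by
    gaps of ``zone_gap_bp``; pseudogene V entries are interleaved inside
    blocks.  D-J-C clusters follow downstream.  Deterministic given seed.
    """
    if config.n_v < 6:
        raise SimulationError(
            f"need n_v >= 6 to form three non-trivial zones, got {config.n_v}"
        )
    rng = np.random.default_rng(config.seed if seed is None else seed)
    truth = GroundTruth()
    if config.zone_gap_bp < 10 * config.v_block_spacing_bp:
        truth.flags.append("zone_gap_bp < 10x intra-block spacing: zone recovery not guaranteed")

    block_sizes = _split_three(config.n_v)
    genes: list[GeneRecord] = []
    pos = 0
    v_index = 0
    blocks: list[list[str]] = []
    for b, size in enumerate(block_sizes):
        block: list[str] = []
        for _ in range(size):
            v_index += 1
            name = f"TRBV{v_index}"
            genes.append(GeneRecord(name, "V", "F", pos))
            block.append(name)
            pos += int(rng.integers(
                int(0.6 * config.v_block_spacing_bp), int(1.4 * config.v_block_spacing_bp)
            ))
        blocks.append(block)
        if b < 2:
            pos += config.zone_gap_bp

    # pseudogene V entries inside the first block(s); excluded from zoning
    fn_starts = sorted(g.start_bp for g in genes)
    for k in range(config.n_pseudo_v):
        lo, hi = fn_starts[k], fn_starts[k + 1]
        genes.append(GeneRecord(f"TRBV{v_index + k + 1}P", "V", "P", (lo + hi) // 2 + 1))

    # D-J-C clusters downstream of the V array
    pos += config.zone_gap_bp
    j_sizes = _split_dj(config.n_j, config.n_dj_clusters)
    for c in range(1, config.n_dj_clusters + 1):
        genes.append(GeneRecord(f"TRBD{c}", "D", "F", pos, cluster_id=c))
        pos += 700
        for i in range(1, j_sizes[c - 1] + 1):
            genes.append(GeneRecord(f"TRBJ{c}-{i}", "J", "F", pos, cluster_id=c))
            pos += int(rng.integers(400, 900))
        genes.append(GeneRecord(f"TRBC{c}", "C", "F", pos, cluster_id=c))
        pos += 2_500

    locus = LocusModel(species="synthetic", genes=genes)
    d1 = locus.d_gene(1).start_bp
    # block nearest D1 is proximal, farthest distal
    order = sorted(
        range(3),
        key=lambda b: abs(
            sum(locus.gene(n).start_bp for n in blocks[b]) / len(blocks[b]) - d1
        ),
    )
    labels = {order[0]: "proximal", order[1]: "middle", order[2]: "distal"}
    for b, block in enumerate(blocks):
        for name in block:
            truth.v_zones[name] = labels[b]
    truth.j_zones = dict(assign_j_zones(locus, "D1-J").zones)
    return locus, truth


def _split_dj(n_j: int, n_clusters: int) -> list[int]:
    base, rem = divmod(n_j, n_clusters)
    # later clusters take the remainder (human-like 6+7)
    return [base + (1 if i >= n_clusters - rem else 0) for i in range(n_clusters)]


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> tuple[str, int]:
    arr = np.array(list(seq), dtype="U1")
    hits = np.flatnonzero(rng.random(len(arr)) < rate)
    for i in hits:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return "".join(arr), len(hits)


def _make_rss(spacer_len: int, rate: float, rng: np.random.Generator) -> tuple[str, int]:
    spacer = "".join(_NT[rng.integers(0, 4, size=spacer_len)])
    return _mutate(CONSENSUS_HEPTAMER + spacer + CONSENSUS_NONAMER, rate, rng)


def generate_rss_catalog(
    locus: LocusModel, config: SimConfig, seed: int | None = None
) -> tuple[list[RSSSequence], GroundTruth]:
    """Per-gene RSSs: 23-spacer for V-3' and D-3', 12-spacer for D-5' and J-5'.

    Sequences are consensus heptamer/nonamer around a uniform-random spacer,
    then substituted per position at ``rss_mutation_rate``; the first
    ``n_low_quality_v`` functional V genes (chosen at random) instead use
    ``elevated_rss_mutation_rate`` to create very-low-quality RSSs.
    """
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    truth = GroundTruth()
    vs = [g.name for g in locus.segment_genes("V", functional_only=True)]
    if config.n_low_quality_v > len(vs):
        raise SimulationError("n_low_quality_v exceeds the functional V count")
    degraded = set(
        rng.choice(vs, size=config.n_low_quality_v, replace=False).tolist()
    )
    truth.degraded_genes = sorted(degraded)

    catalog: list[RSSSequence] = []
    for g in locus.segment_genes("V", functional_only=True):
        rate = (
            config.elevated_rss_mutation_rate
            if g.name in degraded
            else config.rss_mutation_rate
        )
        seq, nmut = _make_rss(23, rate, rng)
        catalog.append(RSSSequence(g.name, "V3", 23, seq))
        truth.rss_mutation_counts[f"{g.name}|V3"] = nmut
    for g in locus.segment_genes("D"):
        for side, spacer in (("D5", 12), ("D3", 23)):
            seq, nmut = _make_rss(spacer, config.rss_mutation_rate, rng)
            catalog.append(RSSSequence(g.name, side, spacer, seq))
            truth.rss_mutation_counts[f"{g.name}|{side}"] = nmut
    for g in locus.segment_genes("J", functional_only=True):
        seq, nmut = _make_rss(12, config.rss_mutation_rate, rng)
        catalog.append(RSSSequence(g.name, "J5", 12, seq))
        truth.rss_mutation_counts[f"{g.name}|J5"] = nmut
    return catalog, truth


def train_catalog_models(
    catalog: list[RSSSequence], pseudocount: float = 1.0
) -> dict[str, RICModel]:
    """Train one model per RSS kind (23- and 12-spacer) from a catalog."""
    models = {}
    for kind, spacer in (("RIC23", 23), ("RIC12", 12)):
        seqs = [s for s in catalog if s.spacer_len == spacer]
        if seqs:
            models[kind] = train_ric(seqs, pseudocount=pseudocount)
    return models


def score_catalog(
    catalog: list[RSSSequence], models: Mapping[str, RICModel]
) -> dict[str, float]:
    """RIC score per catalog entry, keyed "gene|side"."""
    return {
        f"{s.gene}|{s.side}": ric_score(models[s.kind], s).value for s in catalog
    }


def _segment_weights(
    genes: list[str],
    zones: Mapping[str, str],
    scores: Mapping[str, float],
    config: SimConfig,
) -> dict[str, float]:
    logits = np.array(
        [
            config.zone_effects[zones[g]] + config.ric_effect * scores[g]
            for g in genes
        ]
    )
    w = np.exp(logits - logits.max())
    w /= w.sum()
    return dict(zip(genes, w))


_AA_BYTES = np.frombuffer(b"ADEGHIKLMNPQRSTVWY", dtype=np.uint8)


def _random_cdr3(rng: np.random.Generator, n: int) -> list[str]:
    lengths = rng.integers(8, 21, size=n)
    codes = rng.integers(0, len(_AA_BYTES), size=(n, 18))
    blob = _AA_BYTES[codes].tobytes().decode("ascii")
    return [
        "C" + blob[i * 18 : i * 18 + int(l) - 2] + "F"
        for i, l in enumerate(lengths)
    ]


def _distinct_cdr3(rng: np.random.Generator, n: int) -> list[str]:
    out = _random_cdr3(rng, n)
    ser = pd.Series(out)
    dup = ser.duplicated()
    while dup.any():
        idx = np.flatnonzero(dup.to_numpy())
        repl = _random_cdr3(rng, len(idx))
        ser.iloc[idx] = repl
        dup = ser.duplicated()
    return ser.tolist()


def simulate_repertoire(
    locus: LocusModel,
    catalog: list[RSSSequence],
    config: SimConfig,
    seed: int | None = None,
    with_cdr3_nt: bool = True,
) -> tuple[ClonotypeTable, GroundTruth]:
    """Draw biased multi-sample clonotype tables with known usage weights.

    V and J are drawn independently per clonotype from softmax weights in
    (zone effect, beta * RIC).  Each sample holds ``n_clonotypes`` records
    with distinct CDR3s; disjoint fractions are corrupted to be
    unproductive, frame-broken, or reassigned to a pseudogene V call.
    """
    rng = np.random.default_rng(config.seed + 2 if seed is None else seed)
    models = train_catalog_models(catalog, pseudocount=config.ric_pseudocount)
    all_scores = score_catalog(catalog, models)

    v_zones = dict(assign_v_zones(locus).zones)
    j_zones = dict(assign_j_zones(locus, "D1-J").zones)
    v_genes = sorted(v_zones)
    j_genes = sorted(j_zones)
    v_scores = {g: all_scores[f"{g}|V3"] for g in v_genes}
    j_scores = {g: all_scores[f"{g}|J5"] for g in j_genes}
    v_weights = _segment_weights(v_genes, v_zones, v_scores, config)
    j_weights = _segment_weights(j_genes, j_zones, j_scores, config)

    truth = GroundTruth(
        v_zones=v_zones,
        j_zones=j_zones,
        weights={"V": v_weights, "J": j_weights},
        ric_scores=all_scores,
    )
    pseudo_names = [
        g.name for g in locus.segment_genes("V") if g.functionality != "F"
    ]
    j_cluster = {g: locus.gene(g).cluster_id for g in j_genes}
    n_clusters = locus.n_dj_clusters
    nt_table = str.maketrans(_CODON)

    frames: list[pd.DataFrame] = []
    n = config.n_clonotypes
    for s in range(1, config.n_samples + 1):
        sample = f"sample{s}"
        v_arr = np.array(v_genes, dtype=object)
        j_arr = np.array(j_genes, dtype=object)
        vi = rng.choice(len(v_genes), size=n, p=[v_weights[g] for g in v_genes])
        ji = rng.choice(len(j_genes), size=n, p=[j_weights[g] for g in j_genes])
        v_draw = v_arr[vi]
        j_draw = j_arr[ji]
        cdr3 = _distinct_cdr3(rng, n)
        counts = rng.geometric(0.35, size=n)

        # disjoint corruption strata
        u = rng.random(n)
        p1, p2, p3 = (
            config.unproductive_rate,
            config.malformed_rate,
            config.pseudogene_rate,
        )
        unprod = np.flatnonzero(u < p1)
        malformed = np.flatnonzero((u >= p1) & (u < p1 + p2))
        pseudo = (
            np.flatnonzero((u >= p1 + p2) & (u < p1 + p2 + p3))
            if pseudo_names
            else np.array([], dtype=int)
        )

        bad_char = np.where(rng.random(len(unprod)) < 0.5, "_", "*")
        bad_frac = rng.random(len(unprod))
        for k, i in enumerate(unprod):
            aa = cdr3[i]
            pos = 1 + int(bad_frac[k] * (len(aa) - 2))
            cdr3[i] = aa[:pos] + bad_char[k] + aa[pos + 1 :]
        head_coin = rng.random(len(malformed)) < 0.5
        for k, i in enumerate(malformed):
            aa = cdr3[i]
            cdr3[i] = ("A" + aa[1:]) if head_coin[k] else (aa[:-1] + "G")
        v_draw = v_draw.copy()
        if len(pseudo):
            v_draw[pseudo] = np.asarray(pseudo_names)[
                rng.integers(0, len(pseudo_names), size=len(pseudo))
            ]

        has_d = rng.random(n) < config.d_call_rate
        jc = np.array([j_cluster[g] for g in j_genes])[ji]
        d2 = (rng.random(n) < 0.5) & (jc >= 2) & (n_clusters >= 2)
        d_call = np.where(d2, "TRBD2", "TRBD1")
        d_call = np.where(has_d, d_call, None)

        nt = (
            [aa.translate(nt_table) for aa in cdr3] if with_cdr3_nt else [None] * n
        )
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": sample,
                    "cdr3_aa": cdr3,
                    "cdr3_nt": nt,
                    "v_call": v_draw,
                    "d_call": d_call,
                    "j_call": j_draw,
                    "count": counts,
                }
            )
        )
    frame = pd.concat(frames, ignore_index=True)
    return ClonotypeTable(frame=frame, dialect="synthetic"), truth


# ---------------------------------------------------------------------------
# Writers: MiXCR-dialect TSV and 10x-dialect CSV from one simulation


def write_mixcr_tsv(table: ClonotypeTable, path: str | Path, sample_id: str) -> None:
    df = table.to_frame()
    df = df[df["sample_id"] == sample_id]
    total = df["count"].sum()
    out = pd.DataFrame(
        {
            "cloneCount": df["count"].values,
            "cloneFraction": df["count"].values / total,
            "allVHitsWithScore": df["v_call"].values + "*00(100)",
            "allDHitsWithScore": [
                f"{d}*00(50)" if isinstance(d, str) and d else "" for d in df["d_call"]
            ],
            "allJHitsWithScore": df["j_call"].values + "*00(80)",
            "aaSeqCDR3": df["cdr3_aa"].values,
            "nSeqCDR3": [nt if isinstance(nt, str) else "" for nt in df["cdr3_nt"]],
        }
    )
    out.to_csv(path, sep="\t", index=False)


def write_tenx_csv(table: ClonotypeTable, path: str | Path, sample_id: str) -> None:
    df = table.to_frame()
    df = df[df["sample_id"] == sample_id].reset_index(drop=True)
    out = pd.DataFrame(
        {
            "barcode": [f"BC{i:08d}-1" for i in range(len(df))],
            "chain": "TRB",
            "cdr3": df["cdr3_aa"].values,
            "v_gene": df["v_call"].values,
            "d_gene": [d if isinstance(d, str) and d else "" for d in df["d_call"]],
            "j_gene": df["j_call"].values,
            "productive": "true",
        }
    )
    out.to_csv(path, index=False)


__all__ = [
    "SimConfig",
    "GroundTruth",
    "SimulationError",
    "generate_locus",
    "generate_rss_catalog",
    "train_catalog_models",
    "score_catalog",
    "simulate_repertoire",
    "write_mixcr_tsv",
    "write_tenx_csv",
    "write_rss_fasta",
]
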