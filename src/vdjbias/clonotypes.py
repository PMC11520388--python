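"""Clonotype table ingest, productive-sequence filtering, and usage frequencies.

Reads aligner clonotype exports (MiXCR-style TSV or 10x-style contig
annotation CSV) into a uniform record table, applies the productive-CDR3
filter chain, classifies records into D-J recombination patterns, and
computes per-sample V/J usage frequency profiles.

The filter chain retains a clonotype iff its CDR3 amino-acid sequence
contains neither "_" nor "*", starts with "C" and ends with "F", and both
its V and J call are IMGT-functional (F) genes.  A "unique clonotype" is a
distinct (sample, CDR3 aa, V call, J call) tuple.

Tables are backed by a pandas DataFrame (columns sample_id, cdr3_aa,
cdr3_nt, v_call, d_call, j_call, count) so filtering and frequency
computation stay vectorized at repertoire depth; ``ClonotypeRecord``
objects are materialized on demand.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Mapping

import pandas as pd

from .locus import LocusModel

Dialect = Literal["mixcr_tsv", "tenx_csv"]
Basis = Literal["unique_clonotypes", "count_weighted"]

COLUMNS = ["sample_id", "cdr3_aa", "cdr3_nt", "v_call", "d_call", "j_call", "count"]

MIXCR_REQUIRED = [
    "cloneCount",
    "aaSeqCDR3",
    "nSeqCDR3",
    "allVHitsWithScore",
    "allJHitsWithScore",
]
TENX_REQUIRED = ["barcode", "chain", "cdr3", "v_gene", "d_gene", "j_gene", "productive"]

#: filter rules in application/reporting order
FILTER_RULES = ("underscore_star", "frame", "non_f_gene")


class ClonotypeIOError(ValueError):
    """Malformed or schema-violating clonotype input."""


@dataclass(frozen=True)
class ClonotypeRecord:
    sample_id: str
    cdr3_aa: str
    v_call: str
    j_call: str
    cdr3_nt: str | None = None
    d_call: str | None = None
    count: int = 1

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ClonotypeIOError("clonotype count must be >= 1")
        if not self.v_call or not self.j_call:
            raise ClonotypeIOError("v_call and j_call must be non-empty")


class ClonotypeTable:
    """Per-sample clonotype records with provenance of applied filters."""

    def __init__(
        self,
        records: Iterable[ClonotypeRecord] | None = None,
        frame: pd.DataFrame | None = None,
        dialect: str = "memory",
        filters_applied: list[str] | None = None,
        removal_counts: dict[str, int] | None = None,
    ) -> None:
        if (records is None) == (frame is None):
            raise ClonotypeIOError("provide exactly one of records or frame")
        if frame is None:
            recs = list(records)
            frame = pd.DataFrame(
                {
                    "sample_id": [r.sample_id for r in recs],
                    "cdr3_aa": [r.cdr3_aa for r in recs],
                    "cdr3_nt": [r.cdr3_nt for r in recs],
                    "v_call": [r.v_call for r in recs],
                    "d_call": [r.d_call for r in recs],
                    "j_call": [r.j_call for r in recs],
                    "count": [r.count for r in recs],
                },
                columns=COLUMNS,
            )
        else:
            missing = [c for c in COLUMNS if c not in frame.columns]
            if missing:
                raise ClonotypeIOError(f"table frame lacks column(s) {missing}")
            frame = frame[COLUMNS].reset_index(drop=True)
        if len(frame):
            counts = frame["count"]
            if (counts < 1).any():
                raise ClonotypeIOError("clonotype count must be >= 1")
            if frame["v_call"].eq("").any() or frame["j_call"].eq("").any():
                raise ClonotypeIOError("v_call and j_call must be non-empty")
        self._frame = frame
        self.dialect = dialect
        self.filters_applied = filters_applied or []
        self.removal_counts = removal_counts or {}
        self._records: list[ClonotypeRecord] | None = None

    @property
    def records(self) -> list[ClonotypeRecord]:
        if self._records is None:
            self._records = [
                ClonotypeRecord(
                    sample_id=row.sample_id,
                    cdr3_aa=row.cdr3_aa,
                    cdr3_nt=row.cdr3_nt if isinstance(row.cdr3_nt, str) else None,
                    v_call=row.v_call,
                    d_call=row.d_call if isinstance(row.d_call, str) and row.d_call else None,
                    j_call=row.j_call,
                    count=int(row.count),
                )
                for row in self._frame.itertuples(index=False)
            ]
        return self._records

    def __len__(self) -> int:
        return len(self._frame)

    def samples(self) -> list[str]:
        return sorted(self._frame["sample_id"].unique())

    def to_frame(self) -> pd.DataFrame:
        return self._frame.copy()


_DECORATION = re.compile(r"\*\d+|\(\s*[-\d.]+\s*\)")


def strip_gene_call(raw: str) -> str:
    """Normalize an aligner gene hit: first hit, no allele or score suffix.

    "TRBV30*01(1200),TRBV29*01(800)" -> "TRBV30".
    """
    if not isinstance(raw, str):
        return ""
    first = raw.split(",")[0].strip()
    return _DECORATION.sub("", first).strip()


def read_clonotypes(path: str | Path, dialect: Dialect, sample_id: str) -> ClonotypeTable:
    """Read one sample's clonotypes from a MiXCR TSV or a 10x contig CSV.

    10x input keeps TRB chain rows only, one record per distinct
    (barcode, cdr3, v, j) collapsed to clonotypes; the record count is the
    number of cells (distinct barcodes) carrying the clonotype.
    """
    path = Path(path)
    if dialect == "mixcr_tsv":
        df = pd.read_csv(path, sep="\t", dtype=str)
        missing = [c for c in MIXCR_REQUIRED if c not in df.columns]
        if missing:
            raise ClonotypeIOError(f"MiXCR TSV {path.name} lacks column(s) {missing}")
        if df.empty:
            raise ClonotypeIOError(f"clonotype table {path.name} is empty")
        d_col = df.get("allDHitsWithScore", pd.Series([""] * len(df)))
        frame = pd.DataFrame(
            {
                "sample_id": sample_id,
                "cdr3_aa": df["aaSeqCDR3"].astype(str),
                "cdr3_nt": df["nSeqCDR3"].where(df["nSeqCDR3"].notna(), None),
                "v_call": df["allVHitsWithScore"].map(strip_gene_call),
                "d_call": d_col.map(strip_gene_call).replace("", None),
                "j_call": df["allJHitsWithScore"].map(strip_gene_call),
                "count": df["cloneCount"].astype(float).astype(int),
            }
        )
        return ClonotypeTable(frame=frame, dialect="mixcr_tsv")
    if dialect == "tenx_csv":
        df = pd.read_csv(path, dtype=str)
        missing = [c for c in TENX_REQUIRED if c not in df.columns]
        if missing:
            raise ClonotypeIOError(f"10x CSV {path.name} lacks column(s) {missing}")
        if df.empty:
            raise ClonotypeIOError(f"clonotype table {path.name} is empty")
        trb = df[df["chain"] == "TRB"].copy()
        trb["v_call"] = trb["v_gene"].map(strip_gene_call)
        trb["j_call"] = trb["j_gene"].map(strip_gene_call)
        trb["d_call"] = trb["d_gene"].map(strip_gene_call)
        dedup = trb.drop_duplicates(subset=["barcode", "cdr3", "v_call", "j_call"])
        rows = []
        for (cdr3, v, j), grp in dedup.groupby(["cdr3", "v_call", "j_call"], sort=False):
            d_vals = [d for d in grp["d_call"] if d]
            rows.append(
                {
                    "sample_id": sample_id,
                    "cdr3_aa": cdr3,
                    "cdr3_nt": None,
                    "v_call": v,
                    "d_call": d_vals[0] if d_vals else None,
                    "j_call": j,
                    "count": grp["barcode"].nunique(),
                }
            )
        return ClonotypeTable(frame=pd.DataFrame(rows, columns=COLUMNS), dialect="tenx_csv")
    raise ClonotypeIOError(f"unknown dialect {dialect!r}")


def filter_functional(
    table: ClonotypeTable, functionality: Mapping[str, str]
) -> ClonotypeTable:
    """Apply the productive-clonotype filter chain.

    Removal counts attribute each removed record to the first rule it
    violates, in the order underscore/star -> frame -> non-F gene.  Genes
    absent from the functionality map are treated as non-functional.
    """
    df = table.to_frame()
    if df.empty:
        return ClonotypeTable(
            frame=df,
            dialect=table.dialect,
            filters_applied=table.filters_applied + ["functional"],
            removal_counts={
                k: table.removal_counts.get(k, 0) for k in FILTER_RULES
            },
        )
    aa = df["cdr3_aa"].astype(str)
    bad_chars = aa.str.contains("_", regex=False) | aa.str.contains("*", regex=False)
    bad_frame = ~(aa.str.startswith("C") & aa.str.endswith("F"))
    fmap = dict(functionality)
    non_f = ~(
        df["v_call"].map(fmap).eq("F") & df["j_call"].map(fmap).eq("F")
    )
    r1 = bad_chars
    r2 = bad_frame & ~r1
    r3 = non_f & ~r1 & ~r2
    kept = df[~(bad_chars | bad_frame | non_f)]
    removed = {
        "underscore_star": int(r1.sum()),
        "frame": int(r2.sum()),
        "non_f_gene": int(r3.sum()),
    }
    return ClonotypeTable(
        frame=kept,
        dialect=table.dialect,
        filters_applied=table.filters_applied + ["functional"],
        removal_counts={
            k: table.removal_counts.get(k, 0) + v for k, v in removed.items()
        },
    )


def assign_recombination_class(record: ClonotypeRecord, locus: LocusModel) -> str:
    """Classify a clonotype into a V-D-J recombination pattern.

    J cluster 1 forces D1 (a downstream D cannot join an upstream J under
    the 12/23 rule); for J cluster >= 2 the D call disambiguates, and a
    missing D call yields the ambiguous pattern "V-D?-J<c>".  A D call from
    a cluster downstream of the J cluster is flagged as 12/23-violating.
    """
    j = locus.gene(record.j_call)
    if j.segment != "J":
        raise ClonotypeIOError(f"{record.j_call!r} is not a J gene")
    jc = j.cluster_id
    if record.d_call is not None and record.d_call in locus:
        dc = locus.gene(record.d_call).cluster_id
        if dc > jc:
            return "12/23-violating"
        return f"V-D{dc}-J{jc}"
    if jc == 1:
        return "V-D1-J1"
    return f"V-D?-J{jc}"


def recombination_class_counts(table: ClonotypeTable, locus: LocusModel) -> dict[str, int]:
    """Tally recombination patterns over a table (vectorized by J/D pair)."""
    df = table.to_frame()
    out: dict[str, int] = {}
    for (j, d), n in df.groupby(["j_call", "d_call"], dropna=False).size().items():
        rec = ClonotypeRecord(
            sample_id="", cdr3_aa="", v_call="V",
            j_call=j, d_call=d if isinstance(d, str) else None,
        )
        label = assign_recombination_class(rec, locus)
        out[label] = out.get(label, 0) + int(n)
    return out


class UsageProfile:
    """Per-sample, per-segment gene usage frequencies (each sums to 1)."""

    def __init__(self, frequencies: dict[str, dict[str, dict[str, float]]], basis: Basis):
        self.frequencies = frequencies
        self.basis = basis

    def samples(self) -> list[str]:
        return sorted(self.frequencies)

    def frequency(self, sample: str, segment: str, gene: str) -> float:
        return self.frequencies[sample][segment].get(gene, 0.0)

    def mean_frequencies(self, segment: str, genes: list[str] | None = None) -> dict[str, float]:
        """Per-gene frequency averaged over samples (0 where unused)."""
        samples = self.samples()
        if genes is None:
            genes = sorted({g for s in samples for g in self.frequencies[s][segment]})
        return {
            g: sum(self.frequency(s, segment, g) for s in samples) / len(samples)
            for g in genes
        }

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"sample_id": s, "segment": seg, "gene": g, "frequency": f}
            for s, segs in sorted(self.frequencies.items())
            for seg, genes in sorted(segs.items())
            for g, f in sorted(genes.items())
        ]
        return pd.DataFrame(rows)


def usage_frequencies(
    table: ClonotypeTable, basis: Basis = "unique_clonotypes"
) -> UsageProfile:
    """Per-sample V and J gene usage frequencies.

    basis="unique_clonotypes": each distinct (sample, cdr3_aa, v, j) tuple
    counts once.  basis="count_weighted": tuples weighted by summed counts.
    """
    df = table.to_frame()
    if df.empty:
        raise ClonotypeIOError("cannot compute usage frequencies of an empty table")
    key = ["sample_id", "cdr3_aa", "v_call", "j_call"]
    if basis == "unique_clonotypes":
        uniq = df.drop_duplicates(subset=key)[key].copy()
        uniq["weight"] = 1.0
    elif basis == "count_weighted":
        uniq = (
            df.groupby(key, as_index=False)["count"].sum().rename(columns={"count": "weight"})
        )
    else:
        raise ClonotypeIOError(f"unknown basis {basis!r}")
    freqs: dict[str, dict[str, dict[str, float]]] = {}
    for sample, grp in uniq.groupby("sample_id"):
        total = grp["weight"].sum()
        if total == 0:
            raise ClonotypeIOError(f"sample {sample!r} has zero clonotypes")
        freqs[str(sample)] = {
            "V": (grp.groupby("v_call")["weight"].sum() / total).to_dict(),
            "J": (grp.groupby("j_call")["weight"].sum() / total).to_dict(),
        }
    return UsageProfile(frequencies=freqs, basis=basis)


def write_table_tsv(table: ClonotypeTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False)
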