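"""Reading, validating and writing immune-repertoire inputs.

Two kinds of input define the analysis universe:

* AIRR-style rearrangement tables (tab-separated, MiAIRR field names), one
  row per sequenced heavy chain, carrying the IMGT junction (nucleotide and
  amino acid), V/D/J gene calls, the D alignment coordinates within the
  junction, an optional isotype call and the cell-population / genotype
  labels attached at sorting time.
* Germline gene-segment sets as FASTA (V, D or J).

Coordinate convention: on disk the AIRR standard's 1-based closed positions
are used; in memory everything is 0-based half-open.  Conversion happens only
at the I/O boundary so downstream frame arithmetic stays unambiguous.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("hcdr3")

STOP = "*"
STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")
_NUCLEOTIDES = set("ACGT")

#: columns a rearrangement TSV must provide
MANDATORY_COLUMNS = ("sequence_id", "junction_aa", "v_call")

#: optional columns recognised on read (missing ones yield absent fields)
OPTIONAL_COLUMNS = (
    "junction",
    "d_call",
    "j_call",
    "c_call",
    "productive",
    "d_junction_start",
    "d_germline_start",
    "d_length",
    "population",
    "genotype",
    "loop_aa",
    "loop_length",
    "v_sequence_alignment",
    "v_germline_alignment",
)

#: coordinate columns stored 1-based closed on disk, 0-based half-open in memory
COORDINATE_COLUMNS = ("d_junction_start", "d_germline_start")


class FormatError(ValueError):
    """A file does not conform to the expected on-disk format."""


class ValidationError(ValueError):
    """Content is well-formed but violates a contract (e.g. duplicate ids)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RearrangementRecord:
    """One annotated heavy-chain rearrangement (internal coordinates)."""

    sequence_id: str
    junction_aa: str | None = None
    junction_nt: str | None = None
    v_call: str | None = None
    d_call: str | None = None
    j_call: str | None = None
    c_call: str | None = None
    productive: bool | None = None
    d_junction_start: int | None = None
    d_germline_start: int | None = None
    d_length: int | None = None
    population: str | None = None
    genotype: str | None = None


@dataclass(frozen=True)
class GermlineSegment:
    """A germline V, D or J gene segment."""

    name: str
    kind: str  # "V" | "D" | "J"
    sequence_nt: str
    family: str

    def __post_init__(self) -> None:
        if not self.sequence_nt:
            raise ValidationError(f"germline segment {self.name!r} has an empty sequence")
        bad = set(self.sequence_nt) - _NUCLEOTIDES
        if bad:
            raise ValidationError(
                f"germline segment {self.name!r} contains non-ACGT characters: {sorted(bad)}"
            )
        if self.kind not in {"V", "D", "J"}:
            raise ValidationError(f"segment kind must be V, D or J, got {self.kind!r}")


def segment_family(name: str) -> str:
    """Gene-family label from a segment name prefix, e.g. ``D1-1`` -> ``D1``."""
    m = re.match(r"^([A-Za-z]*\d+)", name)
    return m.group(1) if m else name


@dataclass
class RepertoireTable:
    """An ordered collection of rearrangement records backed by a DataFrame.

    The frame always carries the mandatory columns; optional columns are
    present only when the source provided them.  ``provenance`` records where
    the table came from (a path, or a simulator seed tag).
    """

    df: pd.DataFrame
    provenance: str = ""

    def __post_init__(self) -> None:
        for col in MANDATORY_COLUMNS:
            if col not in self.df.columns:
                raise FormatError(f"rearrangement table is missing mandatory column {col!r}")
        ids = self.df["sequence_id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise ValidationError(f"duplicate sequence_id {dup!r} in rearrangement table")

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self) -> Iterator[RearrangementRecord]:
        return iter(self.records())

    def records(self) -> list[RearrangementRecord]:
        out = []
        for row in self.df.itertuples(index=False):
            d = row._asdict()
            kwargs = {}
            for f in RearrangementRecord.__dataclass_fields__:
                col = "junction" if f == "junction_nt" else f
                v = d.get(col)
                if pd.isna(v) if not isinstance(v, (list, tuple)) else False:
                    v = None
                if v is not None and f in ("d_junction_start", "d_germline_start", "d_length"):
                    v = int(v)
                if v is not None and f == "productive":
                    v = bool(v)
                kwargs[f] = v
            out.append(RearrangementRecord(**kwargs))
        return out

    def copy(self) -> "RepertoireTable":
        return RepertoireTable(self.df.copy(), provenance=self.provenance)


# ---------------------------------------------------------------------------
# coordinate conversion (the only place on-disk and in-memory conventions meet)
# ---------------------------------------------------------------------------


def to_internal_coord(start_1based) -> object:
    """1-based closed start -> 0-based half-open start."""
    return start_1based if pd.isna(start_1based) else int(start_1based) - 1


def to_external_coord(start_0based) -> object:
    """0-based half-open start -> 1-based closed start."""
    return start_0based if pd.isna(start_0based) else int(start_0based) + 1


def _convert_coords(df: pd.DataFrame, fn) -> pd.DataFrame:
    df = df.copy()
    for col in COORDINATE_COLUMNS:
        if col in df.columns:
            df[col] = df[col].map(fn).astype("Int64")
    return df


# ---------------------------------------------------------------------------
# rearrangement tables
# ---------------------------------------------------------------------------

_BOOL_MAP = {
    "T": True, "TRUE": True, "true": True, "True": True,
    "F": False, "FALSE": False, "false": False, "False": False,
}


def read_rearrangements(
    path: str | Path,
    population: str | None = None,
    genotype: str | None = None,
    dedupe: bool = False,
) -> RepertoireTable:
    """Read an AIRR-style rearrangement TSV.

    ``population`` / ``genotype`` fill (or override) the corresponding
    columns.  ``dedupe`` keeps one record per exact junction nucleotide
    sequence within each population — the optional "unique sequences"
    reduction; it is off by default.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=True)
    for col in MANDATORY_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing mandatory column {col!r}")
    keep = [c for c in df.columns if c in MANDATORY_COLUMNS + OPTIONAL_COLUMNS]
    df = df[keep]
    if "productive" in df.columns:
        df["productive"] = df["productive"].map(_BOOL_MAP).astype("boolean")
    for col in ("d_junction_start", "d_germline_start", "d_length", "loop_length"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col]).astype("Int64")
    df = _convert_coords(df, to_internal_coord)
    if population is not None:
        df["population"] = population
    if genotype is not None:
        df["genotype"] = genotype
    table = RepertoireTable(df, provenance=str(path))
    if dedupe:
        table = dedupe_junctions(table)
    return table


def dedupe_junctions(table: RepertoireTable) -> RepertoireTable:
    """Keep the first record per exact ``junction`` nucleotide sequence.

    Deduplication is within population when a population column exists,
    global otherwise; records lacking a junction are always kept.
    """
    df = table.df
    if "junction" not in df.columns:
        return table.copy()
    subset = ["junction"] + (["population"] if "population" in df.columns else [])
    has_nt = df["junction"].notna()
    kept = df[has_nt].drop_duplicates(subset=subset, keep="first")
    out = pd.concat([kept, df[~has_nt]]).sort_index()
    n_dropped = len(df) - len(out)
    if n_dropped:
        logger.info("dedupe_junctions: dropped %d duplicate-junction records", n_dropped)
    return RepertoireTable(out.reset_index(drop=True), provenance=table.provenance)


def write_rearrangements(table: RepertoireTable, path: str | Path) -> None:
    """Write a table as AIRR-style TSV (1-based closed coordinates on disk)."""
    df = _convert_coords(table.df, to_external_coord)
    if "productive" in df.columns:
        df["productive"] = df["productive"].map({True: "T", False: "F"})
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# germline segment sets
# ---------------------------------------------------------------------------


def read_germline_fasta(path: str | Path, kind: str) -> list[GermlineSegment]:
    """Read a germline segment set from FASTA; ``kind`` is V, D or J."""
    path = Path(path)
    segments: list[GermlineSegment] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        name = rec.id
        if name in seen:
            raise ValidationError(f"{path}: duplicate germline segment name {name!r}")
        seen.add(name)
        segments.append(
            GermlineSegment(
                name=name,
                kind=kind,
                sequence_nt=str(rec.seq).upper(),
                family=segment_family(name),
            )
        )
    if not segments:
        raise FormatError(f"{path}: no FASTA records found")
    return segments


def write_germline_fasta(segments: Sequence[GermlineSegment], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s.sequence_nt), id=s.name, description="") for s in segments
    ]
    SeqIO.write(records, str(path), "fasta")


def bundled_germline(kind: str) -> list[GermlineSegment]:
    """The synthetic mouse-style germline fixture set shipped with the package."""
    from importlib.resources import files

    fname = {"V": "ighv_synthetic.fasta", "D": "ighd_synthetic.fasta", "J": "ighj_synthetic.fasta"}[kind]
    return read_germline_fasta(files("hcdr3.data").joinpath(fname), kind)


# ---------------------------------------------------------------------------
# the productive-sequence filter
# ---------------------------------------------------------------------------


def filter_productive(table: RepertoireTable) -> RepertoireTable:
    """Restrict a table to analysable productive rearrangements.

    A record is retained when its productive flag is not false, the junction
    amino-acid sequence is present, stop-free, starts at the conserved Cys
    and ends at the conserved Trp/Phe, and (when the nucleotide junction is
    present) the nucleotide length is three times the amino-acid length.
    Order is preserved; the result may be empty.
    """
    df = table.df
    mask = df["junction_aa"].notna()
    aa = df["junction_aa"].fillna("")
    mask &= aa.str.len() >= 2
    mask &= ~aa.str.contains(re.escape(STOP), regex=True)
    mask &= aa.str.startswith("C")
    mask &= aa.str.endswith(("W", "F"))
    if "productive" in df.columns:
        mask &= df["productive"].fillna(False).astype(bool)
    if "junction" in df.columns:
        nt_len = df["junction"].fillna("").str.len()
        has_nt = df["junction"].notna()
        mask &= ~has_nt | ((nt_len % 3 == 0) & (nt_len == 3 * aa.str.len()))
    n_dropped = int((~mask).sum())
    if n_dropped:
        logger.info("filter_productive: excluded %d records", n_dropped)
    return RepertoireTable(df[mask].reset_index(drop=True), provenance=table.provenance)
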