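"""H-CDR3 loop extraction and length statistics.

The junction (IMGT numbering) runs from the conserved Cys-104 codon to the
conserved Trp/Phe-118 codon.  The *loop* is the junction minus the three
N-terminal residues (104-106) and the single C-terminal residue (118) — the
central, antigen-facing part.  A 4-residue junction therefore yields an
empty, degenerate loop: kept in length histograms at length 0 but excluded
from physicochemical profiling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import STOP, RepertoireTable, ValidationError

logger = logging.getLogger("hcdr3")


@dataclass(frozen=True)
class Loop:
    aa: str
    degenerate: bool = False

    @property
    def length(self) -> int:
        return len(self.aa)


@dataclass
class LengthDistribution:
    counts: dict[int, int]
    total: int
    mean: float | None
    population: str | None = None
    genotype: str | None = None

    def proportions(self) -> dict[int, float]:
        if self.total == 0:
            return {}
        return {k: v / self.total for k, v in sorted(self.counts.items())}


def extract_loop(junction_aa: str) -> Loop:
    """Drop the three N-terminal residues and the one C-terminal residue.

    ``extract_loop("CTTIRYW")`` -> ``IRY``; a length-4 junction yields the
    empty loop, flagged degenerate.
    """
    if not junction_aa:
        raise ValidationError("empty junction")
    if len(junction_aa) < 4:
        raise ValidationError(
            f"junction {junction_aa!r} is shorter than 4 residues; no loop is defined"
        )
    aa = junction_aa[3:-1]
    if STOP in aa:
        raise ValidationError(f"loop of junction {junction_aa!r} contains a stop symbol")
    return Loop(aa=aa, degenerate=(len(aa) == 0))


def add_loops(table: RepertoireTable) -> RepertoireTable:
    """Annotate a table with ``loop_aa`` and ``loop_length`` columns.

    Records without a junction_aa, or with one shorter than 4 residues, get
    missing loop fields (with a logged count) rather than failing the table.
    """
    df = table.df.copy()
    aa = df["junction_aa"]
    ok = aa.notna() & (aa.fillna("").str.len() >= 4)
    df["loop_aa"] = pd.array([None] * len(df), dtype="string")
    df.loc[ok, "loop_aa"] = aa[ok].str.slice(3, -1)
    df["loop_length"] = df["loop_aa"].str.len().astype("Int64")
    n_bad = int((~ok).sum())
    if n_bad:
        logger.info("add_loops: %d records without a well-defined loop", n_bad)
    return RepertoireTable(df, provenance=table.provenance)


def _require_loops(table: RepertoireTable) -> pd.Series:
    if "loop_length" not in table.df.columns:
        table = add_loops(table)
    return table.df["loop_length"].dropna().astype(int)


def length_distribution(table: RepertoireTable) -> LengthDistribution:
    """Histogram of loop lengths (degenerate loops count at length 0)."""
    lengths = _require_loops(table)
    counts = lengths.value_counts().sort_index()
    total = int(counts.sum())
    mean = float(lengths.mean()) if total else None
    if total == 0:
        logger.warning("length_distribution: empty table, mean undefined")
    df = table.df
    pop = df["population"].iloc[0] if "population" in df.columns and len(df) else None
    gen = df["genotype"].iloc[0] if "genotype" in df.columns and len(df) else None
    return LengthDistribution(
        counts={int(k): int(v) for k, v in counts.items()},
        total=total,
        mean=mean,
        population=pop,
        genotype=gen,
    )


def distribution_to_frame(dist: LengthDistribution) -> pd.DataFrame:
    """CSV-ready view: length, count, proportion."""
    props = dist.proportions()
    return pd.DataFrame(
        {
            "length": list(props),
            "count": [dist.counts[k] for k in props],
            "proportion": [props[k] for k in props],
        }
    )


def short_loop_profile(
    table_a: RepertoireTable,
    table_b: RepertoireTable,
    lengths: Iterable[int] = range(2, 8),
) -> pd.DataFrame:
    """Per-length proportions of short loops in two repertoires, with tests.

    For each length in ``lengths`` (default 2-7) the proportion of loops of
    exactly that length is reported per table, together with a two-sided
    Fisher exact two-proportion test and Bonferroni adjustment over the
    lengths tested.
    """
    lengths = list(lengths)
    if not lengths:
        raise ValidationError("empty length range")
    la, lb = _require_loops(table_a), _require_loops(table_b)
    if len(la) == 0 or len(lb) == 0:
        raise ValidationError("short_loop_profile requires two non-empty tables")
    rows = []
    for length in lengths:
        ka, kb = int((la == length).sum()), int((lb == length).sum())
        _, p = sps.fisher_exact(
            [[ka, len(la) - ka], [kb, len(lb) - kb]], alternative="two-sided"
        )
        rows.append(
            {
                "length": length,
                "count_a": ka,
                "count_b": kb,
                "proportion_a": ka / len(la),
                "proportion_b": kb / len(lb),
                "p_value": float(p),
            }
        )
    out = pd.DataFrame(rows)
    m = len(lengths)
    out["p_adjusted"] = np.minimum(1.0, out["p_value"] * m)
    return out


def count_v_mutations(record_nt: str, germline_v: str) -> int:
    """Hamming distance to the germline V over aligned non-gap positions.

    Both strings must have equal (aligned) length; ``-`` and ``.`` are gap
    symbols and positions where either sequence is gapped are skipped.
    """
    if len(record_nt) != len(germline_v):
        raise ValidationError(
            f"aligned length mismatch: {len(record_nt)} vs {len(germline_v)}"
        )
    gaps = {"-", "."}
    return sum(
        1
        for a, b in zip(record_nt, germline_v)
        if a not in gaps and b not in gaps and a != b
    )
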