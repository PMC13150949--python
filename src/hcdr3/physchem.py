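"""Physicochemical descriptors of H-CDR3 loops.

Three per-peptide descriptors are computed, always on the loop (never the
full junction):

* net charge at a given pH by the Henderson-Hasselbalch relation over the
  ionizable side chains (Lehninger pKa scale) and, optionally, the free
  terminal amino and carboxyl groups;
* GRAVY — the grand average of hydropathy, i.e. the mean Kyte-Doolittle
  hydropathy over the residues;
* a six-factor descriptor vector (F1 hydrophobicity, F2 alpha/turn
  propensity, F3 bulk, F4 composition, F5 local flexibility, F6 electronic
  properties), averaged element-wise over the residues.

The bundled six-factor table is a synthetic analogue assembled from
classical single-property scales, z-scored over the 20 standard residues;
see ``data/fasgai_synthetic.json``.  Any 20x6 table with the same layout may
be substituted.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from importlib.resources import files

import numpy as np
import pandas as pd

from .io import STANDARD_AA, RepertoireTable, ValidationError
from .loops import add_loops

logger = logging.getLogger("hcdr3")

FACTOR_NAMES = ("F1", "F2", "F3", "F4", "F5", "F6")


def _load_json(name: str) -> dict:
    return json.loads(files("hcdr3.data").joinpath(name).read_text())


@dataclass(frozen=True)
class PkaTable:
    """Side-chain and terminal pKa values for charge computation."""

    name: str
    positive: dict[str, float]  # R, K, H — protonated form carries +1
    negative: dict[str, float]  # D, E, C, Y — deprotonated form carries -1
    n_term: float
    c_term: float

    def __post_init__(self) -> None:
        for v in (*self.positive.values(), *self.negative.values(), self.n_term, self.c_term):
            if not 0 < v < 14:
                raise ValidationError(f"pKa value {v} outside (0, 14)")
        missing = ({"R", "K", "H"} - set(self.positive)) | ({"D", "E", "C", "Y"} - set(self.negative))
        if missing:
            raise ValidationError(f"pKa table lacks required residues: {sorted(missing)}")


def _load_pka() -> PkaTable:
    d = _load_json("pka_lehninger.json")
    return PkaTable(
        name=d["name"],
        positive=d["positive"],
        negative=d["negative"],
        n_term=d["n_term"],
        c_term=d["c_term"],
    )


def _load_hydropathy() -> dict[str, float]:
    d = _load_json("hydropathy_kyte_doolittle.json")["values"]
    if set(d) != STANDARD_AA:
        raise ValidationError("hydropathy table must cover exactly the 20 standard residues")
    return d


def _load_fasgai() -> pd.DataFrame:
    """20x6 factor table: residues in rows, factors F1..F6 in columns.

    Each base scale is standardised (z-scored) across the 20 residues so the
    factors are dimensionless with mean 0 and unit variance, matching the
    convention of factor-analysis descriptor sets.
    """
    d = _load_json("fasgai_synthetic.json")
    cols = {}
    for fname, (_, scale) in zip(FACTOR_NAMES, sorted(d["base_scales"].items())):
        s = pd.Series(scale, dtype=float).reindex(sorted(STANDARD_AA))
        cols[fname] = (s - s.mean()) / s.std(ddof=0)
    table = pd.DataFrame(cols)
    if table.isna().any().any():
        raise ValidationError("six-factor table has missing residues")
    return table


PKA_LEHNINGER = _load_pka()
KYTE_DOOLITTLE = _load_hydropathy()
FASGAI = _load_fasgai()


@dataclass(frozen=True)
class PhyschemProfile:
    """Per-loop descriptor bundle (defined for non-degenerate standard loops)."""

    length: int
    net_charge: float
    gravy: float
    fasgai: tuple[float, ...]


def _check_peptide(peptide: str) -> None:
    if not peptide:
        raise ValidationError("empty peptide")
    for i, aa in enumerate(peptide):
        if aa not in STANDARD_AA:
            raise ValidationError(
                f"non-standard residue {aa!r} at position {i} of {peptide!r}"
            )


def net_charge(
    peptide: str,
    ph: float = 7.0,
    pka: PkaTable = PKA_LEHNINGER,
    include_termini: bool = True,
) -> float:
    """Henderson-Hasselbalch net charge in elementary-charge units.

    Each basic group contributes ``1 / (1 + 10**(pH - pKa))``; each acidic
    group contributes ``-1 / (1 + 10**(pKa - pH))``.  With
    ``include_termini`` the free N-terminal amino and C-terminal carboxyl
    groups are counted as one basic and one acidic group.
    """
    _check_peptide(peptide)
    basic = [pka.positive[a] for a in peptide if a in pka.positive]
    acidic = [pka.negative[a] for a in peptide if a in pka.negative]
    if include_termini:
        basic.append(pka.n_term)
        acidic.append(pka.c_term)
    pos = sum(1.0 / (1.0 + 10.0 ** (ph - k)) for k in basic)
    neg = sum(1.0 / (1.0 + 10.0 ** (k - ph)) for k in acidic)
    return pos - neg


def gravy(peptide: str, table: dict[str, float] = KYTE_DOOLITTLE) -> float:
    """Grand average of hydropathy: mean per-residue hydropathy value."""
    _check_peptide(peptide)
    return float(np.mean([table[a] for a in peptide]))


def fasgai_vector(peptide: str, table: pd.DataFrame = FASGAI) -> np.ndarray:
    """Element-wise mean of the six per-residue factor values."""
    _check_peptide(peptide)
    return table.loc[list(peptide)].mean(axis=0).to_numpy()


def profile(loop_aa: str, ph: float = 7.0, include_termini: bool = True) -> PhyschemProfile:
    return PhyschemProfile(
        length=len(loop_aa),
        net_charge=net_charge(loop_aa, ph, include_termini=include_termini),
        gravy=gravy(loop_aa),
        fasgai=tuple(fasgai_vector(loop_aa)),
    )


# ---------------------------------------------------------------------------
# table-level profiling
# ---------------------------------------------------------------------------


def _eligible_loops(table: RepertoireTable) -> pd.DataFrame:
    """Rows with a non-degenerate loop of standard residues only."""
    if "loop_aa" not in table.df.columns:
        table = add_loops(table)
    df = table.df
    ok = df["loop_aa"].notna() & (df["loop_aa"].fillna("").str.len() > 0)
    ok &= df["loop_aa"].fillna("").map(lambda s: set(s) <= STANDARD_AA)
    n_excluded = int((~ok).sum())
    if n_excluded:
        logger.info(
            "physchem: excluded %d degenerate or non-standard loops", n_excluded
        )
    return df[ok]


def annotate_properties(
    table: RepertoireTable, ph: float = 7.0, include_termini: bool = True
) -> RepertoireTable:
    """Add net_charge, gravy and fasgai_f1..f6 columns (NA where undefined)."""
    if "loop_aa" not in table.df.columns:
        table = add_loops(table)
    df = table.df.copy()
    charges, gravys, fas = [], [], []
    for s in df["loop_aa"]:
        if pd.isna(s) or not s or set(s) - STANDARD_AA:
            charges.append(np.nan)
            gravys.append(np.nan)
            fas.append([np.nan] * 6)
        else:
            charges.append(net_charge(s, ph, include_termini=include_termini))
            gravys.append(gravy(s))
            fas.append(list(fasgai_vector(s)))
    df["net_charge"] = charges
    df["gravy"] = gravys
    for j, fname in enumerate(FACTOR_NAMES):
        df[f"fasgai_{fname.lower()}"] = [row[j] for row in fas]
    return RepertoireTable(df, provenance=table.provenance)


def population_profiles(
    table: RepertoireTable,
    by: tuple[str, ...] = ("population", "genotype"),
    ph: float = 7.0,
    include_termini: bool = True,
) -> pd.DataFrame:
    """Per-group arithmetic means of length, charge, GRAVY and each factor.

    Groups with zero eligible loops are omitted with a warning.  Returns one
    row per group: group columns, n, mean_length, mean_charge, mean_gravy,
    f1..f6.
    """
    by = tuple(c for c in by if c in table.df.columns)
    if not by:
        raise ValidationError("no grouping columns present in table")
    eligible = _eligible_loops(table)
    all_groups = set(map(tuple, table.df[list(by)].fillna("").to_numpy().tolist()))
    rows = []
    for key, grp in eligible.groupby(list(by), dropna=False):
        key = key if isinstance(key, tuple) else (key,)
        loops = grp["loop_aa"].tolist()
        profs = [profile(s, ph, include_termini) for s in loops]
        row = dict(zip(by, key))
        row["n"] = len(profs)
        row["mean_length"] = float(np.mean([p.length for p in profs]))
        row["mean_charge"] = float(np.mean([p.net_charge for p in profs]))
        row["mean_gravy"] = float(np.mean([p.gravy for p in profs]))
        fmat = np.array([p.fasgai for p in profs])
        for j, fname in enumerate(FACTOR_NAMES):
            row[fname.lower()] = float(fmat[:, j].mean())
        rows.append(row)
    present = {tuple(str(r[c]) for c in by) for r in rows}
    for g in all_groups:
        if tuple(map(str, g)) not in present:
            logger.warning("population_profiles: group %s has no eligible loops; omitted", g)
    return pd.DataFrame(rows).sort_values(list(by)).reset_index(drop=True)
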