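"""Clone stratification, expansion classification and treemap landscapes.

Sequences sharing 100% amino-acid identity on the chosen clone key form a
clone.  The key is the H-CDR3 loop by default and can be refined with the V
and/or J gene call — refinement only ever splits clones.  Clones are then
classified by abundance within their compartment:

* ``single``          — exactly one sequence;
* ``expanded_lt1``    — more than one sequence, below the highly-expanded
                        frequency threshold;
* ``highly_expanded`` — at least the threshold fraction (default 1%) of all
                        sequences in the compartment.

The frequency denominator is the number of (productive) sequences in the
compartment, not the number of clones, and a size-1 clone is always
``single`` regardless of frequency.
"""

from __future__ import annotations

import json
import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .io import RepertoireTable, ValidationError
from .loops import add_loops

logger = logging.getLogger("hcdr3")

SINGLE = "single"
EXPANDED_LT1 = "expanded_lt1"
HIGHLY_EXPANDED = "highly_expanded"

#: mapping from key-field names to table columns
_KEY_COLUMNS = {"loop": "loop_aa", "v_gene": "v_call", "j_gene": "j_call"}


@dataclass(frozen=True)
class CloneKey:
    loop_aa: str
    v_gene: str | None = None
    j_gene: str | None = None

    def as_tuple(self) -> tuple:
        return tuple(x for x in (self.loop_aa, self.v_gene, self.j_gene) if x is not None)


@dataclass
class Clone:
    key: CloneKey
    member_ids: list[str]
    frequency: float
    category: str | None = None
    compartment: str | None = None

    @property
    def n(self) -> int:
        return len(self.member_ids)


@dataclass
class Stratification:
    clones: list[Clone]
    total_sequences: int
    key_fields: tuple[str, ...]
    he_threshold: float = 0.01
    compartment: str | None = None

    def sizes(self) -> list[int]:
        return [c.n for c in self.clones]

    def category_counts(self) -> dict[str, int]:
        """Sequence counts per expansion category."""
        out: Counter = Counter()
        for c in self.clones:
            out[c.category] += c.n
        return dict(out)


def group_clones(
    table: RepertoireTable,
    key_fields: Sequence[str] = ("loop",),
    compartment: str | None = None,
    he_threshold: float = 0.01,
) -> Stratification:
    """Partition a table into clones on the chosen key, largest first.

    Records without a defined loop (or a missing keyed gene call) cannot be
    assigned a clone identity and are excluded with a logged count.  Clone
    ordering is deterministic: descending size, then lexicographic key.
    """
    bad = set(key_fields) - set(_KEY_COLUMNS)
    if bad:
        raise ValidationError(f"unknown key fields: {sorted(bad)}")
    if "loop" not in key_fields:
        raise ValidationError("clone keys must include the loop")
    if "loop_aa" not in table.df.columns:
        table = add_loops(table)
    if len(table) == 0:
        raise ValidationError("cannot group an empty table into clones")
    cols = [_KEY_COLUMNS[f] for f in key_fields]
    df = table.df
    ok = pd.Series(True, index=df.index)
    for c in cols:
        if c not in df.columns:
            raise ValidationError(f"table lacks column {c!r} required by the clone key")
        ok &= df[c].notna()
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("group_clones: excluded %d records without a complete key", n_dropped)
    df = df[ok]
    if len(df) == 0:
        raise ValidationError("no records carry a complete clone key")
    total = len(df)
    groups = df.groupby(cols, sort=False)["sequence_id"].apply(list)
    clones = []
    for key, ids in groups.items():
        key = key if isinstance(key, tuple) else (key,)
        kw = dict(zip(key_fields, key))
        clones.append(
            Clone(
                key=CloneKey(
                    loop_aa=kw["loop"],
                    v_gene=kw.get("v_gene"),
                    j_gene=kw.get("j_gene"),
                ),
                member_ids=list(ids),
                frequency=len(ids) / total,
                compartment=compartment,
            )
        )
    clones.sort(key=lambda c: (-c.n, c.key.as_tuple()))
    strat = Stratification(
        clones=clones,
        total_sequences=total,
        key_fields=tuple(key_fields),
        he_threshold=he_threshold,
        compartment=compartment,
    )
    return classify_expansion(strat)


def stratification_from_sizes(
    sizes: Sequence[int],
    he_threshold: float = 0.01,
    compartment: str | None = None,
) -> Stratification:
    """Build a stratification from bare clone sizes (synthetic members).

    Useful for toy inputs and for reproducing published per-category counts
    where only sizes are known.
    """
    if not sizes or any(s < 1 for s in sizes):
        raise ValidationError("clone sizes must be a non-empty list of positive counts")
    total = int(sum(sizes))
    clones = []
    offset = 0
    for i, s in enumerate(sorted(sizes, reverse=True)):
        ids = [f"seq{offset + j}" for j in range(s)]
        offset += s
        clones.append(
            Clone(
                key=CloneKey(loop_aa=f"CLONE{i}"),
                member_ids=ids,
                frequency=s / total,
                compartment=compartment,
            )
        )
    strat = Stratification(
        clones=clones,
        total_sequences=total,
        key_fields=("loop",),
        he_threshold=he_threshold,
        compartment=compartment,
    )
    return classify_expansion(strat)


def classify_expansion(strat: Stratification) -> Stratification:
    """Assign single / expanded_lt1 / highly_expanded categories in place."""
    if strat.total_sequences <= 0:
        raise ValidationError("total_sequences must be positive")
    thr = strat.he_threshold
    for clone in strat.clones:
        if clone.n == 1:
            clone.category = SINGLE
        elif clone.frequency >= thr:
            clone.category = HIGHLY_EXPANDED
        else:
            clone.category = EXPANDED_LT1
    return strat


def min_he_clone_size(total_sequences: int, threshold: float = 0.01) -> int:
    """Smallest clone size reaching the highly-expanded threshold.

    The least integer ``n`` with ``n / total >= threshold``, computed with an
    integer fix-up so binary floating point cannot shift the boundary.
    """
    if total_sequences <= 0:
        raise ValidationError("total_sequences must be positive")
    n = max(1, math.ceil(threshold * total_sequences))
    while n > 1 and (n - 1) / total_sequences >= threshold:
        n -= 1
    while n / total_sequences < threshold:
        n += 1
    return n


def shared_clones(strat_a: Stratification, strat_b: Stratification) -> pd.DataFrame:
    """Clone keys present in both stratifications, with both sizes.

    Both stratifications must use the same key fields.
    """
    if strat_a.key_fields != strat_b.key_fields:
        raise ValidationError(
            f"key-field mismatch: {strat_a.key_fields} vs {strat_b.key_fields}"
        )
    by_key_b = {c.key: c for c in strat_b.clones}
    rows = []
    for ca in strat_a.clones:
        cb = by_key_b.get(ca.key)
        if cb is not None:
            rows.append(
                {
                    "loop_aa": ca.key.loop_aa,
                    "v_gene": ca.key.v_gene,
                    "j_gene": ca.key.j_gene,
                    "n_a": ca.n,
                    "n_b": cb.n,
                }
            )
    return pd.DataFrame(rows, columns=["loop_aa", "v_gene", "j_gene", "n_a", "n_b"])


def tabulate_isotypes(strat: Stratification, table: RepertoireTable) -> pd.DataFrame:
    """Isotype counts per clone; records without an isotype call are 'unknown'."""
    df = table.df
    iso = (
        df.set_index("sequence_id")["c_call"].fillna("unknown")
        if "c_call" in df.columns
        else pd.Series("unknown", index=df["sequence_id"])
    )
    rows = []
    for i, clone in enumerate(strat.clones):
        counts = Counter(iso.reindex(clone.member_ids).fillna("unknown"))
        for isotype, k in sorted(counts.items()):
            rows.append(
                {
                    "clone_index": i,
                    "loop_aa": clone.key.loop_aa,
                    "v_gene": clone.key.v_gene,
                    "isotype": isotype,
                    "count": k,
                }
            )
    return pd.DataFrame(rows, columns=["clone_index", "loop_aa", "v_gene", "isotype", "count"])


def clones_to_frame(strat: Stratification) -> pd.DataFrame:
    """CSV-ready clone table."""
    return pd.DataFrame(
        {
            "loop_aa": [c.key.loop_aa for c in strat.clones],
            "v_gene": [c.key.v_gene for c in strat.clones],
            "j_gene": [c.key.j_gene for c in strat.clones],
            "n": [c.n for c in strat.clones],
            "frequency": [c.frequency for c in strat.clones],
            "category": [c.category for c in strat.clones],
            "compartment": [c.compartment for c in strat.clones],
        }
    )


# ---------------------------------------------------------------------------
# squarified treemap layout
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TreemapTile:
    x: float
    y: float
    width: float
    height: float
    clone_index: int
    category: str | None

    @property
    def area(self) -> float:
        return self.width * self.height


def _worst_aspect(row: list[float], side: float) -> float:
    s = sum(row)
    mx, mn = max(row), min(row)
    return max((side * side * mx) / (s * s), (s * s) / (side * side * mn))


def treemap_layout(
    strat: Stratification, width: float = 100.0, height: float = 100.0
) -> list[TreemapTile]:
    """Squarified treemap of the clone landscape.

    Tiles are laid out largest-first (the stratification's deterministic
    ordering) along the shorter canvas side, fixing each row when adding the
    next clone would worsen the worst aspect ratio.  Tile areas are exactly
    proportional to clone sizes up to floating-point rounding.
    """
    if width <= 0 or height <= 0:
        raise ValidationError("canvas must have positive area")
    if strat.total_sequences <= 0:
        raise ValidationError("cannot lay out an empty stratification")
    scale = width * height / strat.total_sequences
    areas = [c.n * scale for c in strat.clones]
    tiles: list[TreemapTile] = []
    x, y, w, h = 0.0, 0.0, float(width), float(height)
    i = 0
    while i < len(areas):
        side = min(w, h)
        row = [areas[i]]
        j = i + 1
        while j < len(areas):
            if _worst_aspect(row + [areas[j]], side) <= _worst_aspect(row, side):
                row.append(areas[j])
                j += 1
            else:
                break
        row_area = sum(row)
        if w >= h:
            # vertical strip on the left
            strip_w = row_area / h
            yy = y
            for k, a in enumerate(row):
                th = a / strip_w
                tiles.append(TreemapTile(x, yy, strip_w, th, i + k, strat.clones[i + k].category))
                yy += th
            x += strip_w
            w -= strip_w
        else:
            strip_h = row_area / w
            xx = x
            for k, a in enumerate(row):
                tw = a / strip_h
                tiles.append(TreemapTile(xx, y, tw, strip_h, i + k, strat.clones[i + k].category))
                xx += tw
            y += strip_h
            h -= strip_h
        i = j
    return tiles


_CATEGORY_COLOURS = {
    SINGLE: "#c6dbef",
    EXPANDED_LT1: "#6baed6",
    HIGHLY_EXPANDED: "#08519c",
    None: "#cccccc",
}


def treemap_to_json(strat: Stratification, tiles: Iterable[TreemapTile], path: str | Path) -> None:
    payload = [
        {
            "loop_aa": strat.clones[t.clone_index].key.loop_aa,
            "v_gene": strat.clones[t.clone_index].key.v_gene,
            "n": strat.clones[t.clone_index].n,
            "category": t.category,
            "x": t.x,
            "y": t.y,
            "width": t.width,
            "height": t.height,
        }
        for t in tiles
    ]
    Path(path).write_text(json.dumps(payload, indent=1))


def treemap_to_svg(
    strat: Stratification,
    tiles: Iterable[TreemapTile],
    path: str | Path,
    width: float = 100.0,
    height: float = 100.0,
) -> None:
    """Minimal SVG rendering of a treemap landscape."""
    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" viewBox="0 0 {width} {height}">'
    ]
    for t in tiles:
        colour = _CATEGORY_COLOURS.get(t.category, "#cccccc")
        parts.append(
            f'<rect x="{t.x:.4f}" y="{t.y:.4f}" width="{t.width:.4f}" '
            f'height="{t.height:.4f}" fill="{colour}" stroke="white" stroke-width="0.2"/>'
        )
    parts.append("</svg>")
    Path(path).write_text("\n".join(parts))
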