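"""Reading-frame assignment for the germline D segment of each junction.

A germline D segment can be read in three frames.  Which frame a given
rearrangement uses follows from the D alignment: with 0-based coordinates,
``(d_germline_start - d_junction_start) mod 3`` is the germline offset that
falls on a junction codon boundary, because the junction itself starts at
the Cys-104 codon.  The offset is then mapped to the conventional I/II/III
labels through a per-gene anchor map (frame numbering is gene-specific in
the classical nomenclature): RFI is anchored to the tyrosine-rich
translation, RFIII to the arginine/stop-bearing one.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass
from importlib.resources import files
from pathlib import Path

import pandas as pd

from .clonal import Stratification
from .io import RearrangementRecord, RepertoireTable, ValidationError

logger = logging.getLogger("hcdr3")

RF_LABELS = ("I", "II", "III")


@dataclass(frozen=True)
class RFAssignment:
    sequence_id: str
    d_gene: str | None
    frame_offset: int | None
    label: str | None  # None = unassignable (no usable D alignment)

    @property
    def assignable(self) -> bool:
        return self.label is not None


@dataclass
class RFDistribution:
    proportions: dict[str, float]
    n: int
    weighting: str  # "per_sequence" | "per_clone"
    n_unassignable: int = 0


def load_anchor_map(path: str | Path | None = None) -> dict:
    """Anchor map: per-gene (and default) offset -> RF label.

    The bundled map is calibrated to the bundled synthetic D set; supply a
    JSON file of the same shape for other germline sets.
    """
    if path is None:
        raw = files("hcdr3.data").joinpath("rf_anchors.json").read_text()
    else:
        raw = Path(path).read_text()
    d = json.loads(raw)
    for table in [d.get("default", {}), *d.get("genes", {}).values()]:
        for off, lab in table.items():
            if off not in {"0", "1", "2"} or lab not in RF_LABELS:
                raise ValidationError(f"invalid anchor entry {off!r} -> {lab!r}")
    return d


ANCHORS = load_anchor_map()


def frame_offset(d_junction_start: int, d_germline_start: int) -> int:
    """Germline-relative translation offset of the junction reading frame."""
    return (d_germline_start - d_junction_start) % 3


def label_for(d_gene: str, offset: int, anchors: dict = ANCHORS) -> str:
    genes = anchors.get("genes", {})
    if d_gene in genes:
        return genes[d_gene][str(offset)]
    default = anchors.get("default")
    if default is None:
        raise ValidationError(f"D gene {d_gene!r} absent from the anchor map")
    return default[str(offset)]


def assign_rf(record: RearrangementRecord, anchors: dict = ANCHORS) -> RFAssignment:
    """Infer the D reading frame of one record from its alignment coordinates.

    Records without a D call, without alignment coordinates, or whose aligned
    D remnant is empty are returned unassignable (label ``None``) and are
    excluded from distributions with a logged count.
    """
    if (
        record.d_call is None
        or record.d_junction_start is None
        or record.d_germline_start is None
        or (record.d_length is not None and record.d_length < 1)
    ):
        return RFAssignment(record.sequence_id, record.d_call, None, None)
    off = frame_offset(record.d_junction_start, record.d_germline_start)
    return RFAssignment(record.sequence_id, record.d_call, off, label_for(record.d_call, off, anchors))


def assign_rf_table(table: RepertoireTable, anchors: dict = ANCHORS) -> list[RFAssignment]:
    out = [assign_rf(r, anchors) for r in table.records()]
    n_un = sum(1 for a in out if not a.assignable)
    if n_un:
        logger.info("assign_rf: %d records unassignable (no usable D alignment)", n_un)
    return out


def assignments_to_frame(assignments: list[RFAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sequence_id": [a.sequence_id for a in assignments],
            "d_gene": [a.d_gene for a in assignments],
            "frame_offset": [a.frame_offset for a in assignments],
            "rf_label": [a.label for a in assignments],
        }
    )


def rf_distribution(
    table: RepertoireTable, anchors: dict = ANCHORS
) -> RFDistribution:
    """Per-sequence RF proportions over assignable records."""
    assignments = assign_rf_table(table, anchors)
    labels = [a.label for a in assignments if a.assignable]
    if not labels:
        raise ValidationError("no records with an assignable reading frame")
    counts = Counter(labels)
    n = len(labels)
    return RFDistribution(
        proportions={lab: counts.get(lab, 0) / n for lab in RF_LABELS},
        n=n,
        weighting="per_sequence",
        n_unassignable=len(assignments) - n,
    )


def rf_distribution_per_clone(
    strat: Stratification, assignments: list[RFAssignment]
) -> RFDistribution:
    """RF proportions where each clone contributes one count.

    A clone's frame is the majority frame of its assignable members (with a
    warning when members disagree); clones with no assignable member are
    skipped.
    """
    by_id = {a.sequence_id: a for a in assignments}
    clone_labels = []
    for clone in strat.clones:
        labs = [
            by_id[sid].label
            for sid in clone.member_ids
            if sid in by_id and by_id[sid].assignable
        ]
        if not labs:
            continue
        counts = Counter(labs)
        if len(counts) > 1:
            logger.warning(
                "clone %s has discordant reading frames %s; using majority",
                clone.key.loop_aa,
                dict(counts),
            )
        # majority, ties broken by canonical label order for determinism
        clone_labels.append(
            max(RF_LABELS, key=lambda lab: (counts.get(lab, 0), -RF_LABELS.index(lab)))
        )
    if not clone_labels:
        raise ValidationError("no clones with an assignable reading frame")
    counts = Counter(clone_labels)
    n = len(clone_labels)
    return RFDistribution(
        proportions={lab: counts.get(lab, 0) / n for lab in RF_LABELS},
        n=n,
        weighting="per_clone",
    )


def d_usage(table: RepertoireTable) -> pd.DataFrame:
    """Counts and proportions per D gene and per D family.

    Records without a D call are tallied under gene/family ``unresolved``.
    Returns rows (level, name, count, proportion) where level is ``gene`` or
    ``family``.
    """
    from .io import segment_family

    df = table.df
    calls = (
        df["d_call"].fillna("unresolved")
        if "d_call" in df.columns
        else pd.Series("unresolved", index=df.index)
    )
    n = len(calls)
    rows = []
    for name, k in sorted(Counter(calls).items()):
        rows.append({"level": "gene", "name": name, "count": k, "proportion": k / n})
    fams = calls.map(lambda c: "unresolved" if c == "unresolved" else segment_family(c))
    for name, k in sorted(Counter(fams).items()):
        rows.append({"level": "family", "name": name, "count": k, "proportion": k / n})
    return pd.DataFrame(rows, columns=["level", "name", "count", "proportion"])
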