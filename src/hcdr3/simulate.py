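"""Synthetic VDJ heavy-chain repertoires with ground truth.

The generator emulates the structure of an annotated plasma-cell/B-cell
rearrangement table: junctions assembled from a germline V 3' tail (which
contributes the conserved Cys-104 codon and the following residues), a
trimmed D segment flanked by random non-templated N additions, and a J head
ending at the conserved Trp codon.  Productivity (in-frame, stop-free,
C...W) is enforced by rejection.  An optional selection step accepts
sequences with probability proportional to configurable weights on the D
reading frame, the loop length and the loop net charge — "selection on"
mimics a pre-BCR-checkpoint repertoire, "selection off" the checkpoint-free
one.  Clones are expanded to sizes drawn from a heavy-tailed (Zipf) law or
given explicitly, with point-mutation SHM applied to the aligned V region of
expanded-clone members, and isotypes are drawn from per-compartment
probabilities.

Distributional choices (geometric trimming, Poisson N-addition lengths,
Zipf clone sizes) are modelling conveniences chosen for testability, not
biological claims; every parameter lives in :class:`SimConfig` and the
resolved configuration can be serialised alongside the output.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .io import GermlineSegment, RepertoireTable, ValidationError, bundled_germline
from .physchem import net_charge
from .rf import ANCHORS, label_for

logger = logging.getLogger("hcdr3")

_NT = np.array(list("ACGT"))

#: nucleotides of the V tail entering the junction, and the protected parts
V_TAIL_LEN = 12      # last 12 nt of the V segment form the junction's 5' end
V_PROTECTED = 9      # Cys codon + two codons never trimmed
J_PROTECTED = 3      # the terminal Trp codon never trimmed


@dataclass
class SimConfig:
    """Parameters of one simulated repertoire (one population/compartment)."""

    seed: int
    n_clones: int = 200
    clone_sizes: list[int] | None = None      # explicit sizes override the Zipf law
    zipf_exponent: float = 2.5
    max_clone_size: int = 500
    v_segments: list[GermlineSegment] | None = None
    d_segments: list[GermlineSegment] | None = None
    j_segments: list[GermlineSegment] | None = None
    v_weights: list[float] | None = None
    d_weights: list[float] | None = None
    j_weights: list[float] | None = None
    trim_p: float = 0.45            # geometric parameter, per trimmed end
    n_insert_mean: float = 2.0      # Poisson mean N-addition length, per joint
    rf_acceptance: dict[str, float] = field(
        default_factory=lambda: {"I": 1.0, "II": 1.0, "III": 1.0}
    )
    no_d_acceptance: float = 1.0
    loop_length_weights: dict[int, float] | None = None
    charge_penalty: float = 0.0     # acceptance *= exp(-penalty * max(charge, 0))
    shm_rate: float = 0.0           # per-site substitution prob in expanded clones
    preserve_clone_key: bool = True
    isotype_probs: dict[str, float] | None = None
    population: str = "PC_SPL"
    genotype: str = "KO"
    max_attempts: int = 5000

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValidationError("a seed is mandatory")
        if self.v_segments is None:
            self.v_segments = bundled_germline("V")
        if self.d_segments is None:
            self.d_segments = bundled_germline("D")
        if self.j_segments is None:
            self.j_segments = bundled_germline("J")
        for name, w, seg in (
            ("v_weights", self.v_weights, self.v_segments),
            ("d_weights", self.d_weights, self.d_segments),
            ("j_weights", self.j_weights, self.j_segments),
        ):
            if w is not None:
                if len(w) != len(seg) or any(x < 0 for x in w) or sum(w) <= 0:
                    raise ValidationError(f"invalid {name}")
        if any(w < 0 for w in self.rf_acceptance.values()) or not any(
            self.rf_acceptance.values()
        ):
            raise ValidationError("rf_acceptance weights must be non-negative, one positive")
        if not 0 <= self.shm_rate <= 1:
            raise ValidationError("shm_rate must lie in [0, 1]")

    def to_json(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        for k in ("v_segments", "d_segments", "j_segments"):
            d[k] = [{"name": s["name"], "sequence_nt": s["sequence_nt"]} for s in d[k]]
        Path(path).write_text(json.dumps(d, indent=1))


@dataclass
class GroundTruth:
    """True per-sequence and per-clone labels emitted with a simulated table."""

    sequences: pd.DataFrame   # sequence_id, clone_id, v/d/j gene, rf_label, mutations, loop
    clones: pd.DataFrame      # clone_id, size
    config: SimConfig


def _norm(weights, n) -> np.ndarray:
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    return w / w.sum()


def _translate(nt: str) -> str:
    return str(Seq(nt).translate())


def _sample_founder(cfg: SimConfig, rng: np.random.Generator) -> dict:
    """Rejection-sample one productive, selection-accepted junction."""
    vw = _norm(cfg.v_weights, len(cfg.v_segments))
    dw = _norm(cfg.d_weights, len(cfg.d_segments))
    jw = _norm(cfg.j_weights, len(cfg.j_segments))
    w_max = (
        max(max(cfg.rf_acceptance.values()), cfg.no_d_acceptance)
        * (max(list(cfg.loop_length_weights.values()) + [1.0]) if cfg.loop_length_weights else 1.0)
    )
    for _ in range(cfg.max_attempts):
        v = cfg.v_segments[rng.choice(len(cfg.v_segments), p=vw)]
        d = cfg.d_segments[rng.choice(len(cfg.d_segments), p=dw)]
        j = cfg.j_segments[rng.choice(len(cfg.j_segments), p=jw)]
        tail = v.sequence_nt[-V_TAIL_LEN:]
        v_trim = max(0, min(int(rng.geometric(cfg.trim_p) - 1), len(tail) - V_PROTECTED))
        j_trim = max(0, min(int(rng.geometric(cfg.trim_p) - 1), len(j.sequence_nt) - J_PROTECTED))
        d5 = int(rng.geometric(cfg.trim_p) - 1)
        d3 = int(rng.geometric(cfg.trim_p) - 1)
        n1 = int(rng.poisson(cfg.n_insert_mean))
        n2 = int(rng.poisson(cfg.n_insert_mean))
        v_part = tail[: len(tail) - v_trim]
        j_part = j.sequence_nt[j_trim:]
        d_part = "" if d5 + d3 >= len(d.sequence_nt) else d.sequence_nt[d5 : len(d.sequence_nt) - d3]
        n1s = "".join(rng.choice(_NT, n1))
        n2s = "".join(rng.choice(_NT, n2))
        junction = v_part + n1s + d_part + n2s + j_part
        if len(junction) % 3:
            continue
        aa = _translate(junction)
        if "*" in aa or not aa.startswith("C") or not aa.endswith(("W", "F")):
            continue
        if d_part:
            d_junction_start = len(v_part) + n1
            offset = (d5 - d_junction_start) % 3
            rf = label_for(d.name, offset, ANCHORS)
            weight = cfg.rf_acceptance.get(rf, 0.0)
        else:
            d_junction_start = None
            rf = None
            weight = cfg.no_d_acceptance
        loop = aa[3:-1]
        if cfg.loop_length_weights:
            weight *= cfg.loop_length_weights.get(len(loop), 1.0)
        if cfg.charge_penalty and loop:
            weight *= float(np.exp(-cfg.charge_penalty * max(net_charge(loop), 0.0)))
        if rng.random() * w_max > weight:
            continue
        return {
            "junction": junction,
            "junction_aa": aa,
            "loop_aa": loop,
            "v_call": v.name,
            "d_call": d.name if d_part else None,
            "j_call": j.name,
            "d_junction_start": d_junction_start,
            "d_germline_start": d5 if d_part else None,
            "d_length": len(d_part) if d_part else None,
            "rf_label": rf,
            "v_germline": v.sequence_nt,
        }
    raise ValidationError(
        "could not generate a productive accepted junction within the retry bound; "
        "the configuration is likely contradictory"
    )


def _clone_sizes(cfg: SimConfig, rng: np.random.Generator) -> list[int]:
    if cfg.clone_sizes is not None:
        if any(s < 1 for s in cfg.clone_sizes):
            raise ValidationError("explicit clone sizes must be positive")
        return list(cfg.clone_sizes)
    sizes = rng.zipf(cfg.zipf_exponent, cfg.n_clones)
    return list(np.minimum(sizes, cfg.max_clone_size).astype(int))


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> tuple[str, int]:
    if rate <= 0:
        return seq, 0
    chars = list(seq)
    k = 0
    for i in range(len(chars)):
        if rng.random() < rate:
            alt = [c for c in "ACGT" if c != chars[i]]
            chars[i] = alt[int(rng.integers(3))]
            k += 1
    return "".join(chars), k


def _mutate_loop_region(junction: str, rate: float, rng: np.random.Generator) -> str:
    """Point-mutate loop codons only, reverting changes that break productivity."""
    loop_nt = list(junction[9:-3])
    for i in range(len(loop_nt)):
        if rng.random() < rate:
            old = loop_nt[i]
            alt = [c for c in "ACGT" if c != old]
            loop_nt[i] = alt[int(rng.integers(3))]
            cand = junction[:9] + "".join(loop_nt) + junction[-3:]
            if "*" in _translate(cand):
                loop_nt[i] = old
    return junction[:9] + "".join(loop_nt) + junction[-3:]


def simulate_repertoire(config: SimConfig) -> tuple[RepertoireTable, GroundTruth]:
    """Generate one annotated repertoire plus its ground truth.

    Same seed, same config -> bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    sizes = _clone_sizes(config, rng)
    iso_names, iso_probs = None, None
    if config.isotype_probs:
        iso_names = list(config.isotype_probs)
        iso_probs = _norm(list(config.isotype_probs.values()), len(iso_names))
    rows, truth_rows = [], []
    for ci, size in enumerate(sizes):
        founder = _sample_founder(config, rng)
        for mi in range(size):
            sid = f"{config.population}-{config.genotype}-c{ci:05d}-m{mi:04d}"
            junction = founder["junction"]
            # SHM only within expanded clones; the founder stays germline-true
            mutate = size > 1 and mi > 0 and config.shm_rate > 0
            v_seq, n_mut = (
                _mutate(founder["v_germline"], config.shm_rate, rng)
                if mutate
                else (founder["v_germline"], 0)
            )
            if mutate and not config.preserve_clone_key:
                junction = _mutate_loop_region(junction, config.shm_rate, rng)
            aa = _translate(junction)
            isotype = (
                str(rng.choice(iso_names, p=iso_probs)) if iso_names else None
            )
            rows.append(
                {
                    "sequence_id": sid,
                    "junction": junction,
                    "junction_aa": aa,
                    "v_call": founder["v_call"],
                    "d_call": founder["d_call"],
                    "j_call": founder["j_call"],
                    "c_call": isotype,
                    "productive": True,
                    "d_junction_start": founder["d_junction_start"],
                    "d_germline_start": founder["d_germline_start"],
                    "d_length": founder["d_length"],
                    "population": config.population,
                    "genotype": config.genotype,
                    "v_sequence_alignment": v_seq,
                    "v_germline_alignment": founder["v_germline"],
                }
            )
            truth_rows.append(
                {
                    "sequence_id": sid,
                    "clone_id": ci,
                    "v_gene": founder["v_call"],
                    "d_gene": founder["d_call"],
                    "j_gene": founder["j_call"],
                    "rf_label": founder["rf_label"],
                    "mutation_count": n_mut,
                    "productive": True,
                    "loop_aa": aa[3:-1],
                    "loop_length": len(aa) - 4,
                }
            )
    df = pd.DataFrame(rows)
    for col in ("d_junction_start", "d_germline_start", "d_length"):
        df[col] = df[col].astype("Int64")
    table = RepertoireTable(df, provenance=f"simulated:seed={config.seed}")
    truth = GroundTruth(
        sequences=pd.DataFrame(truth_rows),
        clones=pd.DataFrame({"clone_id": range(len(sizes)), "size": sizes}),
        config=config,
    )
    return table, truth


# ---------------------------------------------------------------------------
# paired study scenarios
# ---------------------------------------------------------------------------

#: selection weights of the checkpoint-on (WT-like) arm: the Y-rich frame is
#: favoured, short and positively charged loops are counter-selected
WT_SELECTION = {
    "rf_acceptance": {"I": 1.0, "II": 0.35, "III": 0.25},
    "loop_length_weights": {0: 0.05, 1: 0.05, 2: 0.1, 3: 0.1, 4: 0.2, 5: 0.35, 6: 0.55, 7: 0.75},
    "charge_penalty": 0.4,
}

ISOTYPES_SPLEEN = {"IgG2b": 0.55, "IgG2c": 0.35, "IgG3": 0.08, "IgG1": 0.02}
ISOTYPES_BM = {"IgG2b": 0.39, "IgG2c": 0.50, "IgG3": 0.05, "IgG1": 0.06}


def scenario_wt_vs_ko(
    seed: int,
    n_clones: int = 2000,
    population: str = "mB",
    **overrides,
) -> dict[str, tuple[RepertoireTable, GroundTruth]]:
    """Matched pair of repertoires: pre-BCR selection on (WT) vs off (KO).

    The WT arm applies frame-I-favouring acceptance plus short-loop and
    positive-charge penalties; the KO arm applies no selection.  Seeds are
    derived from ``seed`` so the two arms are independent but reproducible.
    """
    base = dict(n_clones=n_clones, clone_sizes=[1] * n_clones, population=population)
    base.update(overrides)
    wt_cfg = SimConfig(seed=seed * 2 + 1, genotype="WT", **WT_SELECTION, **base)
    ko_cfg = SimConfig(seed=seed * 2 + 2, genotype="KO", **base)
    return {"WT": simulate_repertoire(wt_cfg), "KO": simulate_repertoire(ko_cfg)}


def write_outputs(
    table: RepertoireTable, truth: GroundTruth, outdir: str | Path
) -> dict[str, Path]:
    """Emit the AIRR TSV, ground-truth CSV and resolved config JSON."""
    from .io import write_rearrangements

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "rearrangements": outdir / "rearrangements.tsv",
        "ground_truth": outdir / "ground_truth.csv",
        "config": outdir / "sim_config.json",
    }
    write_rearrangements(table, paths["rearrangements"])
    truth.sequences.to_csv(paths["ground_truth"], index=False)
    truth.config.to_json(paths["config"])
    return paths
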