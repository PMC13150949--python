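# hcdr3

Analysis of the H-CDR3 loop repertoire of immunoglobulin heavy chains, built
for studies of B-cell selection — in particular settings where the pre-BCR
checkpoint is impaired (surrogate-light-chain-deficient mice) and plasma-cell
compartments become dominated by a few expanded clones with short,
hydrophobic and positively charged loops.

The package consumes AIRR-style rearrangement tables (or generates synthetic
ones with full ground truth) and provides:

* **Loop extraction** — the H-CDR3 loop is the IMGT junction
  (Cys-104 … Trp/Phe-118) minus its three N-terminal residues and one
  C-terminal residue; e.g. junction `CTTIRYW` → loop `IRY` (3 aa).
* **Clone stratification** — sequences with 100% amino-acid-identical loops
  (optionally also matching V/J calls) form clones, classified as *single*
  (n = 1), *expanded <1%* or *highly expanded* (clone frequency ≥ 1% of the
  compartment's sequences); squarified treemap landscapes of the result.
* **D reading-frame inference** — each junction's D segment is read in one
  of three frames; with 0-based coordinates the frame is
  `(d_germline_start − d_junction_start) mod 3`, mapped to the conventional
  RF I/II/III labels via a per-gene anchor map (RFI = tyrosine-rich frame,
  RFIII = arginine/stop-bearing frame).
* **Physicochemical profiling** — per-loop net charge at pH 7
  (Henderson–Hasselbalch over the Lehninger pKa scale,
  `q = Σ_basic 1/(1+10^(pH−pKa)) − Σ_acidic 1/(1+10^(pKa−pH))`), GRAVY
  (mean Kyte–Doolittle hydropathy) and a six-factor descriptor vector
  (see `docs/methods.md` for the synthetic factor table).
* **Population statistics** — Mann–Whitney U tests (exact for small
  tie-free samples) with Bonferroni correction per property family, and PCA
  of per-population mean factor profiles.
* **A VDJ repertoire simulator** — germline V/D/J assembly with trimming and
  N-additions, productivity enforcement, reading-frame/length/charge
  selection weights, Zipf clone sizes, SHM within expanded clones and
  compartment-skewed isotypes, emitting an AIRR table plus ground truth.

## Worked example

Simulate a matched pair of repertoires — pre-BCR selection on ("WT") versus
off ("KO") — and compare reading-frame usage and loop chemistry:

```python
import hcdr3 as h

arms = h.scenario_wt_vs_ko(seed=42, n_clones=1500)
for arm, (table, truth) in arms.items():
    t = h.add_loops(table)
    rf = h.rf_distribution(t)
    prof = h.population_profiles(t)
    print(arm, {k: round(v, 3) for k, v in rf.proportions.items()},
          "charge", round(prof.iloc[0].mean_charge, 3),
          "gravy", round(prof.iloc[0].mean_gravy, 3))
```

prints

```
WT {'I': 0.711, 'II': 0.28, 'III': 0.009} charge -1.212 gravy -0.481
KO {'I': 0.474, 'II': 0.501, 'III': 0.025} charge -1.087 gravy -0.198
```

With the selection checkpoint on, ~71% of sequences use the tyrosine-rich
frame I; without it frame I drops to ~47% while the hydrophobic frame II
doubles, and the mean loop becomes more positively charged and more
hydrophobic — the direction expected when unfavourable heavy chains escape
counter-selection.  (Frame III is rare in both arms because its
stop-codon-bearing germline translations are mostly removed by the
productivity requirement itself.)

The same pipeline runs from the shell:

```sh
hcdr3 run --out results/demo --seed 42          # simulate + full analysis
hcdr3 run --input my_rearrangements.tsv --out results/real --key loop+v
```

writing the annotated table, clone and isotype tables, length and
reading-frame distributions, population profiles, PCA scores/loadings,
treemap JSON/SVG and a manifest.

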