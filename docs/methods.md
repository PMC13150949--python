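# Methods

## Scope and data model

The package analyses annotated heavy-chain rearrangement tables: one row per
sequenced cell/molecule with the IMGT junction (nucleotide and amino acid),
V/D/J gene calls, D alignment coordinates, an optional isotype call and
population/genotype labels.  On disk the AIRR convention (tab-separated,
MiAIRR field names, 1-based closed coordinates) is used; in memory all
coordinates are 0-based half-open, converted only at the I/O boundary so the
reading-frame arithmetic below is unambiguous.

The analysis universe is the productive repertoire: records whose productive
flag is set, whose junction is stop-free, in frame (nucleotide length three
times the amino-acid length), starts at the conserved Cys and ends at the
conserved Trp/Phe.  An optional deduplication flag collapses records with
identical junction nucleotide sequences within a population; it is off by
default because published "unique sequence" counts do not pin down the exact
rule (nucleotide vs amino acid level, per population vs pooled).

## Loop definition

The H-CDR3 loop is the junction minus its first three residues (IMGT
104–106) and its last residue (118).  A 4-residue junction yields an empty
loop, flagged degenerate: it is counted at length 0 in length histograms but
excluded from physicochemical profiling, since the properties of an empty
peptide are undefined.  Per-length comparisons of short loops (default 2–7
aa) between two repertoires use a two-sided Fisher exact test per length
with Bonferroni correction over the lengths tested; the exact test was
chosen because short-loop counts can be small.

## Clonal stratification

Clones are groups of sequences with 100% amino-acid-identical loops on the
chosen key — loop alone, or loop refined by V and/or J call.  Refinement can
only split clones, so clone counts and single-sequence counts are
monotonically non-decreasing under refinement (a property the test suite
checks on random simulated tables).  Classification:

* `single`: n = 1 (always, even if 1/total reaches the threshold — an
  "expanded" clone requires more than one identical sequence);
* `highly_expanded`: n ≥ 2 and n/total ≥ threshold (default 1%);
* `expanded_lt1`: the remainder.

The denominator is the number of productive sequences in the compartment.
The smallest highly-expanded clone size is the least integer n with
n/total ≥ threshold, computed with an integer fix-up around `ceil` so binary
floating point cannot shift the boundary.

Treemap landscapes use the squarified layout: clones pre-sorted by
descending size (ties broken lexicographically by key), rows laid along the
shorter canvas side and closed when adding the next tile would worsen the
worst aspect ratio.  The subdivision is exact, so tile areas are
proportional to clone sizes to ~1e-12 relative error, tiles never overlap
and the union covers the canvas.

## Reading-frame assignment

The junction begins at a codon boundary, so the germline offset read in
frame is `(d_germline_start − d_junction_start) mod 3` (0-based); the
offset is invariant to re-anchoring the alignment.  Offsets are mapped to
RF I/II/III labels through a per-gene anchor map stored as JSON, because the
classical frame numbering is gene-specific.  The bundled map is calibrated
on the bundled D set so that RFI is the tyrosine-rich frame, RFII the
hydrophobic (valine-rich) frame and RFIII the leucine/arginine/stop-bearing
frame; genes absent from the map fall back to a default (offset 0 → RFI).
Records without a usable D alignment (fully trimmed or unaligned D — common
for very short loops) are reported as a separate unassignable fraction and
excluded from distributions.  Per-clone distributions count each clone once,
using the majority frame with a logged warning when members disagree.

## Physicochemical descriptors

All descriptors are computed on the loop, never the full junction.

* **Net charge** at pH 7.0 (default): Henderson–Hasselbalch over ionizable
  side chains using the Lehninger pKa scale (R 12.48, K 10.53, H 6.00;
  D 3.65, E 4.25, C 8.18, Y 10.07), plus the free terminal groups
  (N 9.69, C 2.34) when `include_termini` is on.  The termini default is ON
  for compatibility with common peptide-property tools, although a loop is
  chemically an internal fragment; the flag makes the choice explicit.
* **GRAVY**: arithmetic mean of Kyte–Doolittle hydropathy values.
* **Six-factor vector**: element-wise mean of per-residue factor values.
  The bundled factor table (`data/fasgai_synthetic.json`) is **synthetic**:
  the published factor-analysis matrix with these factor semantics could not
  be redistributed here, so the package constructs an analogue by z-scoring
  six classical single-property scales over the 20 residues — Kyte–Doolittle
  hydropathy (F1), Chou–Fasman helix propensity (F2), residue volume (F3),
  residue mass (F4), side-chain rotatable-bond count (F5) and side-chain
  charge at pH 7 (F6).  Factor means and signs behave like the published
  set's (hydrophobic loops score high on F1, basic loops high on F6), but
  numeric values are not interchangeable with it; any 20×6 table with the
  same layout can be substituted.

Population profiles are arithmetic means per population×genotype group over
eligible (non-degenerate, standard-residue) loops, with exclusion counts
logged and empty groups omitted with a warning.

## Statistics

The Mann–Whitney U statistic is computed from midranks.  For pooled samples
of at most 12 without ties the two-sided p-value is exact, by enumeration of
all C(n1+n2, n1) labelings; otherwise the normal approximation with midrank
tie correction and a 0.5 continuity correction is used.  The two regimes
agree to well under 0.02 at n1 = n2 = 8, and both are cross-checked against
an independent implementation in the test suite.  Bonferroni families are
per property (length, charge, GRAVY), with m equal to the number of
population pairs compared in the run.

PCA operates on the small populations × factors matrix of group means — each
population is one point — not on per-sequence vectors, which would let large
clones dominate through sheer multiplicity.  Columns are centred but not
rescaled by default (the factors are already standardised descriptors); a
`scale` flag enables correlation-matrix PCA.  Components come from an SVD of
the centred matrix; variance fractions are the normalised squared singular
values, and each loading vector's largest-magnitude element is made positive
so scores are deterministic across platforms.

## The repertoire simulator

The simulator is a structural stand-in for real sequencing data, not a
biological model.  Per clone founder it samples V, D and J segments by
weight, trims geometrically (parameter 0.45 per trimmed end; D on both
ends, V/J only outside protected regions — the V-encoded first three
junction codons and the J-encoded terminal Trp codon are never trimmed, so
every junction is C…W-framed by construction), inserts Poisson-length
(mean 2 per joint) uniform-nucleotide N additions, and rejection-samples
until the junction is in frame and stop-free.  A second rejection layer
implements selection: acceptance proportional to a configurable weight per
reading frame, per loop length, and an exponential penalty on positive loop
charge.  "WT" scenario arms favour frame I and penalise short/charged
loops; "KO" arms apply no selection.  Clone sizes are explicit or Zipf
(exponent 2.5, capped); within expanded clones, members receive per-site
point mutations (SHM) on their aligned V region, with true counts recorded;
by default the loop amino-acid sequence is preserved so clone identity
remains valid (a flag disables this to stress-test clone splitting).
Isotypes are drawn from per-compartment probabilities.  Everything is
driven by a single mandatory seed; identical configs give bit-identical
tables.

Ground truth (clone id, D gene, reading frame, mutation count, loop) is
emitted per sequence, which lets the tests check exact recovery: the
productive filter retains everything, loop extraction reproduces the
intended loops, and frame assignment recovers the true frame for every
record with a surviving D remnant.

The construction distribution of reading frames and D-gene usage under "no
selection" is not uniform — it is shaped by trimming, N-additions and the
productivity requirement (frames whose germline translation carries stop
codons are suppressed).  The test suite therefore derives the expected
distribution by exact enumeration over (D gene, 5'/3' trim, N-lengths)
outcomes, computing each outcome's productivity probability in closed form
(codon-wise, since independent uniform N positions make codons
independent), and checks simulated proportions at n = 4,000–10,000 against
a 99% binomial interval around the enumerated values.

What the simulator does not emulate: real germline alleles (the bundled
V/D/J sets are small synthetic fixtures, with a D1-1 whose three frames
translate to tyrosine-rich / valine-rich / leucine-arginine-stop patterns as
in the murine locus), insertion/deletion SHM, lineage structure within
clones, sequencing error, or any fitted abundance distribution.  Passing
tests therefore demonstrate correctness of the analysis machinery on data
with the assumed structure, not biological claims about real repertoires.

## Problem sizes and numerical choices

Simulation-based tests use 10³–10⁴ sequences, which keeps the full suite
around a minute while leaving binomial intervals tight enough to detect
mis-implemented weights.  Treemap geometry is validated to 1e-9 relative
tolerance; PCA identities (variance fractions summing to one,
reconstruction of the centred matrix, orthonormal loadings) to 1e-9
absolute.  Degenerate inputs follow explicit rules stated above: empty
tables give empty distributions with an undefined (flagged) mean; groups or
clones with no eligible members are omitted with warnings rather than
poisoned with NaNs; zero-variance PCA input yields zero variance fractions
with a warning rather than an error.
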