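"""Independent oracles used by the test suite.

These deliberately re-derive expected quantities from first principles —
closed-form enumeration over the simulator's generative outcomes — without
touching the implementation code paths they are checking.
"""

from __future__ import annotations

from math import exp, factorial

STOPS = {"TAA", "TAG", "TGA"}
NTS = "ACGT"


def geometric_pmf(k: int, p: float) -> float:
    """P(k failures before first success), support {0, 1, ...}."""
    return (1 - p) ** k * p


def poisson_pmf(k: int, mu: float) -> float:
    return exp(-mu) * mu**k / factorial(k)


def _p_no_stop(template: str) -> float:
    """P(translation has no stop) for a codon-aligned template.

    ``N`` marks an independently uniform random nucleotide; all other
    positions are fixed.  Codons are independent because each random
    position belongs to exactly one codon.
    """
    assert len(template) % 3 == 0
    p = 1.0
    for i in range(0, len(template), 3):
        codon = template[i : i + 3]
        ks = [j for j, c in enumerate(codon) if c == "N"]
        if not ks:
            if codon in STOPS:
                return 0.0
            continue
        total, stop = 0, 0
        # enumerate completions of the random positions (at most 64)
        fills = [""]
        for _ in ks:
            fills = [f + n for f in fills for n in NTS]
        for f in fills:
            c = list(codon)
            for j, ch in zip(ks, f):
                c[j] = ch
            total += 1
            stop += "".join(c) in STOPS
        p *= 1 - stop / total
    return p


def construction_distribution(
    v_tail: str,
    j_head: str,
    d_sequences: dict[str, str],
    d_weights: dict[str, float],
    trim_p: float,
    n_insert_mean: float,
    max_trim: int = 32,
    max_n: int = 16,
) -> dict:
    """Exact enumeration of the pre-selection construction distribution.

    Assumes an untrimmable V tail and J head (the oracle configs use
    segments short enough that trimming is impossible).  Enumerates
    (D gene, 5'/3' D trim, N1/N2 length) outcomes, weighting each by its
    sampling probability times the probability that the assembled junction
    is productive (in-frame and stop-free; conserved ends are fixed by the
    V/J parts).  Returns normalised masses:

    * ``offset``: germline translation offset (0/1/2) among D-bearing
      productive junctions;
    * ``d_gene``: D-gene proportions among D-bearing productive junctions;
    * ``no_d``: fraction of productive junctions without a D remnant.
    """
    assert len(v_tail) % 3 == 0
    wsum = sum(d_weights.values())
    offset_mass = {0: 0.0, 1: 0.0, 2: 0.0}
    gene_mass = {g: 0.0 for g in d_sequences}
    no_d_mass = 0.0
    for gene, dseq in d_sequences.items():
        wd = d_weights[gene] / wsum
        L = len(dseq)
        for d5 in range(max_trim + 1):
            p5 = geometric_pmf(d5, trim_p)
            for d3 in range(max_trim + 1):
                p53 = p5 * geometric_pmf(d3, trim_p)
                d_part = "" if d5 + d3 >= L else dseq[d5 : L - d3]
                for n1 in range(max_n + 1):
                    pn1 = poisson_pmf(n1, n_insert_mean)
                    for n2 in range(max_n + 1):
                        total_len = len(v_tail) + n1 + len(d_part) + n2 + len(j_head)
                        if total_len % 3:
                            continue
                        prob = wd * p53 * pn1 * poisson_pmf(n2, n_insert_mean)
                        if prob < 1e-14:
                            continue
                        template = v_tail + "N" * n1 + d_part + "N" * n2 + j_head
                        prob *= _p_no_stop(template)
                        if not prob:
                            continue
                        if d_part:
                            off = (d5 - (len(v_tail) + n1)) % 3
                            offset_mass[off] += prob
                            gene_mass[gene] += prob
                        else:
                            no_d_mass += prob
    z = sum(offset_mass.values())
    total = z + no_d_mass
    return {
        "offset": {k: v / z for k, v in offset_mass.items()},
        "d_gene": {g: v / z for g, v in gene_mass.items()},
        "no_d": no_d_mass / total,
    }


def binomial_ci99_halfwidth(p: float, n: int) -> float:
    """Normal-approximation 99% CI half-width for a proportion."""
    return 2.576 * (p * (1 - p) / n) ** 0.5
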