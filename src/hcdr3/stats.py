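"""Population-level statistics: rank tests and descriptor-profile PCA.

Pairwise population comparisons of per-loop properties use the two-sided
Mann-Whitney U test, Bonferroni-corrected within each property family.  The
U statistic is computed from midranks; the p-value by exact enumeration of
all group labelings for small tie-free samples, otherwise by the normal
approximation with tie and continuity corrections.

Dimensionality reduction of the per-population mean six-factor profiles is a
plain covariance-eigendecomposition PCA on the small populations x factors
matrix: columns are centred (not rescaled — the factors are already
standardised descriptors; a flag enables scaling), components are ordered by
decreasing variance, and each loading vector's largest-magnitude element is
made positive so scores are reproducible across platforms.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb, erf, sqrt
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import RepertoireTable, ValidationError
from .physchem import FACTOR_NAMES, annotate_properties

logger = logging.getLogger("hcdr3")

EXACT_LIMIT = 12  # exact enumeration when n1 + n2 <= this and no ties


@dataclass(frozen=True)
class TestResult:
    group1: str
    group2: str
    property: str | None
    n1: int
    n2: int
    u_statistic: float
    p_value: float
    p_adjusted: float | None = None
    method: str = ""


@dataclass
class PCAResult:
    scores: pd.DataFrame        # rows = populations, columns = PC1..PCk
    loadings: pd.DataFrame      # rows = input factors, columns = PC1..PCk
    variance_fraction: np.ndarray


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U for sample x, from midranks of the pooled data."""
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    r1 = ranks[: len(x)].sum()
    return float(r1 - len(x) * (len(x) + 1) / 2)


def mann_whitney_u(
    x: Sequence[float], y: Sequence[float], group1: str = "x", group2: str = "y",
    property: str | None = None,
) -> TestResult:
    """Two-sided Mann-Whitney U test.

    Exact enumeration over all C(n1+n2, n1) group labelings when the pooled
    sample is small (<= 12) and tie-free; otherwise normal approximation with
    midrank tie correction and a 0.5 continuity correction.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValidationError("both samples must be non-empty")
    n1, n2 = len(x), len(y)
    u = _u_statistic(x, y)
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if n1 + n2 <= EXACT_LIMIT and not has_ties:
        p = _exact_p(pooled, n1, u)
        method = "exact"
    else:
        p = _normal_p(pooled, n1, n2, u)
        method = "normal_approx"
    return TestResult(group1, group2, property, n1, n2, u, p, method=method)


def _exact_p(pooled: np.ndarray, n1: int, u_obs: float) -> float:
    """Two-sided exact p: enumerate every assignment of n1 labels."""
    n = len(pooled)
    ranks = rankdata(pooled)
    mu = n1 * (n - n1) / 2
    dev = abs(u_obs - mu)
    hits = 0
    for idx in combinations(range(n), n1):
        r1 = ranks[list(idx)].sum()
        u = r1 - n1 * (n1 + 1) / 2
        if abs(u - mu) >= dev - 1e-12:
            hits += 1
    return hits / comb(n, n1)


def _normal_p(pooled: np.ndarray, n1: int, n2: int, u: float) -> float:
    n = n1 + n2
    mu = n1 * n2 / 2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum())
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return 1.0
    z = (abs(u - mu) - 0.5) / sqrt(var)
    z = max(z, 0.0)
    return min(1.0, 2.0 * (1.0 - 0.5 * (1.0 + erf(z / sqrt(2.0)))))


def bonferroni(p_values: Iterable[float], m: int | None = None) -> list[float]:
    """Bonferroni adjustment: ``min(1, m * p)`` with family size ``m``."""
    ps = list(p_values)
    if m is None:
        m = len(ps)
    if m < 1:
        raise ValidationError("family size m must be >= 1")
    if m < len(ps):
        raise ValidationError(f"family size m={m} smaller than {len(ps)} tests")
    return [min(1.0, m * p) for p in ps]


_PROPERTY_COLUMNS = {"length": "loop_length", "charge": "net_charge", "gravy": "gravy"}


def compare_populations(
    table: RepertoireTable,
    pairs: Sequence[tuple[str, str]],
    properties: Sequence[str] = ("length", "charge", "gravy"),
    ph: float = 7.0,
) -> list[TestResult]:
    """One Mann-Whitney test per (property, population pair).

    Populations are matched on the ``population`` column (with genotype
    appended as ``population:genotype`` labels also accepted).  Bonferroni
    families are per property, with m = the number of pairs compared.
    """
    bad = set(properties) - set(_PROPERTY_COLUMNS)
    if bad:
        raise ValidationError(f"unknown properties: {sorted(bad)}")
    need = {_PROPERTY_COLUMNS[p] for p in properties}
    if not need <= set(table.df.columns):
        table = annotate_properties(table, ph=ph)
    df = table.df
    if "population" not in df.columns:
        raise ValidationError("table lacks a population column")
    labels = df["population"].astype(str)
    if "genotype" in df.columns:
        combined = labels + ":" + df["genotype"].astype(str)
    else:
        combined = labels
    known = set(labels) | set(combined)
    results: list[TestResult] = []
    for prop in properties:
        col = _PROPERTY_COLUMNS[prop]
        family: list[TestResult] = []
        for g1, g2 in pairs:
            for g in (g1, g2):
                if g not in known:
                    raise ValidationError(f"unknown population label {g!r}")
            sel1 = (labels == g1) | (combined == g1)
            sel2 = (labels == g2) | (combined == g2)
            v1 = df.loc[sel1, col].dropna().astype(float)
            v2 = df.loc[sel2, col].dropna().astype(float)
            family.append(mann_whitney_u(v1, v2, g1, g2, property=prop))
        adj = bonferroni([t.p_value for t in family], m=len(pairs))
        results.extend(
            TestResult(
                t.group1, t.group2, t.property, t.n1, t.n2,
                t.u_statistic, t.p_value, p_adjusted=a, method=t.method,
            )
            for t, a in zip(family, adj)
        )
    return results


def results_to_frame(results: list[TestResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "property": [t.property for t in results],
            "group1": [t.group1 for t in results],
            "group2": [t.group2 for t in results],
            "n1": [t.n1 for t in results],
            "n2": [t.n2 for t in results],
            "U": [t.u_statistic for t in results],
            "p": [t.p_value for t in results],
            "p_adj": [t.p_adjusted for t in results],
            "method": [t.method for t in results],
        }
    )


def pca_profiles(profiles: pd.DataFrame, scale: bool = False) -> PCAResult:
    """PCA of a small populations x descriptors matrix.

    ``profiles`` has one row per population (index = labels) and one
    descriptor per column (by default the six factor means).  Columns are
    centred; with ``scale`` they are also divided by their standard
    deviation.  Returns scores, orthonormal loadings and the fraction of
    variance per component; a zero-variance input yields all-zero fractions
    with a warning.
    """
    X = profiles.to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ValidationError("PCA needs at least two populations (rows)")
    Xc = X - X.mean(axis=0)
    if scale:
        sd = Xc.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        Xc = Xc / sd
    k = min(Xc.shape)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    total = float((s**2).sum())
    if total == 0:
        warnings.warn("zero-variance profile matrix; variance fractions set to 0")
        frac = np.zeros(k)
    else:
        frac = s**2 / total
    # sign convention: largest-|.| element of each loading positive
    for j in range(k):
        i = int(np.argmax(np.abs(Vt[j])))
        if Vt[j, i] < 0:
            Vt[j] *= -1
            U[:, j] *= -1
    comp = [f"PC{j + 1}" for j in range(k)]
    scores = pd.DataFrame(U * s, index=profiles.index, columns=comp)
    loadings = pd.DataFrame(Vt.T, index=profiles.columns, columns=comp)
    return PCAResult(scores=scores, loadings=loadings, variance_fraction=frac)


def pca_from_population_profiles(summary: pd.DataFrame, scale: bool = False) -> PCAResult:
    """Convenience: run PCA on the f1..f6 columns of a population summary."""
    cols = [f.lower() for f in FACTOR_NAMES]
    idx_cols = [c for c in ("population", "genotype") if c in summary.columns]
    mat = summary.set_index(idx_cols)[cols] if idx_cols else summary[cols]
    if len(idx_cols) > 1:
        mat.index = [":".join(map(str, t)) for t in mat.index]
    return pca_profiles(mat, scale=scale)
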