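"""Mutual exclusivity and cooccurrence of gene alterations.

Two testing routes over a binary gene-by-sample alteration matrix:

* a margin-aware test in the style of DISCOVER: a maximum-entropy
  background model assigns each (gene, sample) cell an alteration
  probability ``p_ij = sigmoid(mu_i + nu_j)`` whose expected row and
  column sums reproduce the observed margins, so tumors with high
  overall alteration rates do not masquerade as cooccurrence; the
  overlap count of a gene pair is then referred to its Poisson-binomial
  null ``q_j = p_Aj * p_Bj``;
* Fisher's exact test on the 2x2 cross-tabulation, reported for
  comparison (conservative for exclusivity, anticonservative for
  cooccurrence).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .stats import adjust_pvalues, fisher_exact_2x2, poisson_binomial_cdf

logger = logging.getLogger(__name__)

EXCLUSIVE = "exclusive"
COOCCURRING = "cooccurring"

#: BH-adjusted significance threshold for the Fisher screen
FISHER_SCREEN_ALPHA = 0.01

PASSING_CLASSES = frozenset({"missense", "stopgain", "frameshift", "nonstop", "splice"})
BENIGN_LABELS = frozenset({"benign", "likely_benign"})


def build_alteration_matrix(
    mutations: pd.DataFrame,
    genes: Sequence[str],
    samples: Sequence[str] | None = None,
    strata: Mapping[str, str] | None = None,
    passing_classes: frozenset[str] = PASSING_CLASSES,
    exclude_benign: bool = True,
) -> dict[str, pd.DataFrame]:
    """Binarize mutation calls into per-stratum genes x samples matrices.

    An entry is 1 iff the sample carries at least one variant of a
    passing class (nonbenign, exonic/splice) in the gene. ``strata``
    maps sample -> stratum (e.g. WES vs panel); strata are kept as
    separate matrices, mirroring separate construction per sequencing
    technology.
    """
    if not genes:
        raise ValueError("gene list must be non-empty")
    if samples is None:
        samples = sorted(mutations["sample"].unique()) if len(mutations) else []
    if len(mutations) == 0:
        logger.warning("empty mutation table: alteration matrix is all zero")
        passing = mutations
    else:
        keep = mutations["variant_class"].isin(passing_classes)
        if exclude_benign and "pathogenicity_label" in mutations.columns:
            keep &= ~mutations["pathogenicity_label"].astype(str).str.lower().isin(
                BENIGN_LABELS
            )
        passing = mutations[keep]

    if strata is None:
        strata = {s: "all" for s in samples}
    matrices: dict[str, pd.DataFrame] = {}
    for stratum in sorted(set(strata.values())):
        cols = [s for s in samples if strata.get(s) == stratum]
        mat = pd.DataFrame(0, index=list(genes), columns=cols, dtype=np.int8)
        if len(passing):
            sub = passing[
                passing["sample"].isin(cols) & passing["gene"].isin(genes)
            ]
            for _, row in sub.iterrows():
                mat.loc[row["gene"], row["sample"]] = 1
        matrices[stratum] = mat
    return matrices


@dataclass
class BackgroundModel:
    """Margin-matching logistic background: p_ij = sigmoid(mu_i + nu_j)."""

    p: pd.DataFrame  # genes x samples alteration probabilities
    mu: pd.Series
    nu: pd.Series
    tol_achieved: float
    degenerate_genes: tuple[str, ...] = ()
    degenerate_samples: tuple[str, ...] = ()

    def q_pair(self, gene_a: str, gene_b: str) -> np.ndarray:
        return self.p.loc[gene_a].to_numpy() * self.p.loc[gene_b].to_numpy()


def fit_background(
    matrix: pd.DataFrame, tol: float = 1e-8, max_iter: int = 500
) -> BackgroundModel:
    """Fit the maximum-entropy background by alternating Newton sweeps.

    Gene parameters mu_i and sample parameters nu_j are updated in turn
    (each a monotone 1-D root-finding problem, one safeguarded Newton
    step per sweep, zero initialization) until both expected margins
    match the observed row and column sums within ``tol`` in max norm.
    Rows or columns that are entirely 0 or 1 have no finite parameter;
    they are fixed at their observed value and reported.
    """
    M = matrix.to_numpy(dtype=float)
    m, n = M.shape
    row_sums = M.sum(axis=1)
    col_sums = M.sum(axis=0)
    deg_rows = np.flatnonzero((row_sums == 0) | (row_sums == n))
    deg_cols = np.flatnonzero((col_sums == 0) | (col_sums == m))
    if deg_rows.size or deg_cols.size:
        logger.info(
            "degenerate margins excluded from fit: %d genes, %d samples",
            deg_rows.size,
            deg_cols.size,
        )
    keep_r = np.setdiff1d(np.arange(m), deg_rows)
    keep_c = np.setdiff1d(np.arange(n), deg_cols)
    A = M[np.ix_(keep_r, keep_c)]
    r = A.sum(axis=1)
    c = A.sum(axis=0)
    mr, nc = A.shape

    mu = np.zeros(mr)
    nu = np.zeros(nc)
    resid = np.inf
    for _ in range(max_iter):
        P = 1.0 / (1.0 + np.exp(-(mu[:, None] + nu[None, :])))
        # Newton step on each mu_i: f = sum_j P_ij - r_i, f' = sum_j P(1-P)
        f = P.sum(axis=1) - r
        fp = (P * (1 - P)).sum(axis=1)
        mu -= np.clip(f / np.maximum(fp, 1e-12), -5.0, 5.0)
        P = 1.0 / (1.0 + np.exp(-(mu[:, None] + nu[None, :])))
        g = P.sum(axis=0) - c
        gp = (P * (1 - P)).sum(axis=0)
        nu -= np.clip(g / np.maximum(gp, 1e-12), -5.0, 5.0)
        P = 1.0 / (1.0 + np.exp(-(mu[:, None] + nu[None, :])))
        resid = max(
            np.abs(P.sum(axis=1) - r).max(initial=0.0),
            np.abs(P.sum(axis=0) - c).max(initial=0.0),
        )
        if resid < tol:
            break
    else:
        raise RuntimeError(
            f"background fit did not converge in {max_iter} sweeps; "
            f"max margin residual {resid:.3g}"
        )

    p_full = np.empty((m, n))
    # degenerate rows/columns: probability equals the constant observed value
    p_full[:] = np.nan
    P = 1.0 / (1.0 + np.exp(-(mu[:, None] + nu[None, :])))
    p_full[np.ix_(keep_r, keep_c)] = P
    for i in deg_rows:
        p_full[i, :] = M[i, :].mean()
    for j in deg_cols:
        p_full[:, j] = M[:, j]
    mu_s = pd.Series(np.nan, index=matrix.index, dtype=float)
    mu_s.iloc[keep_r] = mu
    nu_s = pd.Series(np.nan, index=matrix.columns, dtype=float)
    nu_s.iloc[keep_c] = nu
    return BackgroundModel(
        p=pd.DataFrame(p_full, index=matrix.index, columns=matrix.columns),
        mu=mu_s,
        nu=nu_s,
        tol_achieved=float(resid),
        degenerate_genes=tuple(matrix.index[deg_rows]),
        degenerate_samples=tuple(matrix.columns[deg_cols]),
    )


@dataclass
class PairTestResult:
    gene_a: str
    gene_b: str
    direction: str
    overlap: int
    p: float
    p_adjusted: float | None = None
    stratum: str = "all"
    method: str = "discover"
    significant: bool | None = None

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def discover_pair_test(
    matrix: pd.DataFrame,
    background: BackgroundModel,
    gene_a: str,
    gene_b: str,
    direction: str = EXCLUSIVE,
    stratum: str = "all",
) -> PairTestResult:
    """Margin-aware pair test: overlap count vs its Poisson-binomial null.

    Exclusivity: p = P(X <= k); cooccurrence: p = P(X >= k), with
    X ~ PoissonBinomial(q_j), q_j = p_Aj * p_Bj.
    """
    for g in (gene_a, gene_b):
        if g not in matrix.index:
            raise KeyError(f"gene {g!r} not in matrix")
    if direction not in (EXCLUSIVE, COOCCURRING):
        raise ValueError(f"unknown direction {direction!r}")
    a = matrix.loc[gene_a].to_numpy().astype(bool)
    b = matrix.loc[gene_b].to_numpy().astype(bool)
    k = int((a & b).sum())
    q = background.q_pair(gene_a, gene_b)
    lower, upper = poisson_binomial_cdf(q, k)
    p = lower if direction == EXCLUSIVE else upper
    return PairTestResult(
        gene_a=gene_a, gene_b=gene_b, direction=direction,
        overlap=k, p=p, stratum=stratum, method="discover",
    )


def discover_screen(
    matrices: Mapping[str, pd.DataFrame],
    pairs: Sequence[tuple[str, str]],
    direction: str = EXCLUSIVE,
    tol: float = 1e-8,
    adjust: str = "BH",
) -> list[PairTestResult]:
    """Run the margin-aware test per stratum with BH adjustment per
    direction x stratum family."""
    results: list[PairTestResult] = []
    for stratum, matrix in matrices.items():
        background = fit_background(matrix, tol=tol)
        stratum_results = [
            discover_pair_test(matrix, background, a, b, direction, stratum=stratum)
            for a, b in pairs
        ]
        adj = adjust_pvalues([r.p for r in stratum_results], adjust)
        for r, pa in zip(stratum_results, adj):
            r.p_adjusted = float(pa)
            r.significant = pa < FISHER_SCREEN_ALPHA
        results.extend(stratum_results)
    return results


def fisher_cooccurrence_screen(
    matrix: pd.DataFrame,
    pairs: Sequence[tuple[str, str]],
    stratum: str = "all",
    alpha: float = FISHER_SCREEN_ALPHA,
) -> list[PairTestResult]:
    """Fisher's exact test per pair with BH adjustment.

    Direction is read off the cross-tabulation (cooccurring if the
    overlap exceeds its margin expectation); significance is flagged at
    BH-adjusted p < 0.01.
    """
    results = []
    n = matrix.shape[1]
    for gene_a, gene_b in pairs:
        a = matrix.loc[gene_a].to_numpy().astype(bool)
        b = matrix.loc[gene_b].to_numpy().astype(bool)
        both = int((a & b).sum())
        only_a = int((a & ~b).sum())
        only_b = int((~a & b).sum())
        neither = n - both - only_a - only_b
        res = fisher_exact_2x2([[both, only_a], [only_b, neither]])
        expected = a.sum() * b.sum() / n if n else 0.0
        results.append(
            PairTestResult(
                gene_a=gene_a, gene_b=gene_b,
                direction=COOCCURRING if both >= expected else EXCLUSIVE,
                overlap=both, p=res.p, stratum=stratum, method="fisher",
            )
        )
    adj = adjust_pvalues([r.p for r in results], "BH")
    for r, pa in zip(results, adj):
        r.p_adjusted = float(pa)
        r.significant = pa < alpha
    return results


def fisher_pair_test(
    matrix: pd.DataFrame, gene_a: str, gene_b: str, direction: str = EXCLUSIVE
) -> PairTestResult:
    """One-sided Fisher test of a pair in a stated direction.

    Uses the hypergeometric tail of the overlap count given the margins
    (the directional analogue of the two-sided screen).
    """
    from math import exp

    from .stats import _log_hypergeom_pmf

    a = matrix.loc[gene_a].to_numpy().astype(bool)
    b = matrix.loc[gene_b].to_numpy().astype(bool)
    n = a.size
    k = int((a & b).sum())
    na, nb = int(a.sum()), int(b.sum())
    lo, hi = max(0, na + nb - n), min(na, nb)
    if direction == EXCLUSIVE:
        support = range(lo, k + 1)
    else:
        support = range(k, hi + 1)
    p = sum(exp(_log_hypergeom_pmf(x, na, n - na, nb)) for x in support)
    return PairTestResult(
        gene_a=gene_a, gene_b=gene_b, direction=direction,
        overlap=k, p=min(p, 1.0), method="fisher_onesided",
    )


def results_to_frame(results: Sequence[PairTestResult]) -> pd.DataFrame:
    df = pd.DataFrame([r.to_dict() for r in results])
    cols = [
        "gene_a", "gene_b", "direction", "overlap",
        "p", "p_adjusted", "stratum", "method", "significant",
    ]
    return df[cols]
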