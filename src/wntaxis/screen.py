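"""Tissue-stratified pan-cancer screen of signature genes against a target.

For each tissue with enough cell lines the screen computes, per signature
gene, the Spearman correlation between that gene and the target ligand, a
significance mask at unadjusted p > 0.05, and a one-sided rank-sum test of
target expression between the highest (Q1) and lowest (Q4) quartiles of the
signature gene's expression. Genes are then clustered on their binary
significance profiles (asymmetric binary / Jaccard distance, average
linkage), and a gene is called positive when its correlation is positive and
significant in at least ``min_tissues`` tissues.

Conventions fixed here and tested: Q1 is the HIGHEST quartile; tissue
eligibility is strictly more than ``min_lines`` lines; masking uses the
unadjusted two-sided correlation p-value (an optional Benjamini-Hochberg
mode exists but is off by default, since the original procedure
applies no correction).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.stats import rankdata

from . import stats
from .io_formats import ExpressionMatrix
from .stats import TestResult, UndefinedStatisticError

__all__ = [
    "TissueScreenResult",
    "eligible_tissues",
    "quartile_stratify",
    "q1_vs_q4_test",
    "spearman_screen",
    "binary_cluster",
    "positive_tissue_count",
    "mean_target_expression",
    "run_screen",
]

ALPHA = 0.05


@dataclass
class TissueScreenResult:
    """Long-format screen outcomes plus the per-tissue and per-gene summaries."""

    table: pd.DataFrame  # columns: tissue, gene, rho, rho_p, masked, q1q4_p
    mean_target: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    positive_counts: pd.Series = field(default_factory=lambda: pd.Series(dtype=int))
    flagged_genes: list[str] = field(default_factory=list)
    gene_order: list[str] = field(default_factory=list)
    target_gene: str = ""
    alpha: float = ALPHA


def eligible_tissues(em: ExpressionMatrix, min_lines: int = 20) -> list[str]:
    """Tissues represented by strictly more than ``min_lines`` cell lines."""
    counts = em.sample_tissue.value_counts()
    return [t for t in em.tissues() if counts.get(t, 0) > min_lines]


def quartile_stratify(values: pd.Series) -> pd.Series:
    """Assign samples to quartiles Q1..Q4 with Q1 the highest expression.

    Samples are ranked descending; ties break deterministically by sample id.
    Quartile sizes differ by at most one, extras going to the top quartiles
    (n=10 gives sizes 3,3,2,2 from Q1).
    """
    if values.size < 4:
        raise ValueError("need at least 4 samples for quartiles")
    order = sorted(values.index, key=lambda s: (-values[s], s))
    n = len(order)
    sizes = [n // 4 + (1 if i < n % 4 else 0) for i in range(4)]
    labels = {}
    pos = 0
    for qi, size in enumerate(sizes, start=1):
        for s in order[pos : pos + size]:
            labels[s] = f"Q{qi}"
        pos += size
    return pd.Series(labels).reindex(values.index)


def q1_vs_q4_test(target_values: pd.Series, qa: pd.Series, exact: bool = False) -> TestResult:
    """One-sided rank-sum test of target expression, Q1 (high) vs Q4 (low)."""
    q1 = target_values[qa.index[qa == "Q1"]]
    q4 = target_values[qa.index[qa == "Q4"]]
    if q1.empty or q4.empty:
        raise ValueError("Q1 and Q4 must be non-empty")
    return stats.rank_sum_test(q1.to_numpy(), q4.to_numpy(), alternative="greater", exact=exact)


def _spearman_tissue_block(
    gene_values: np.ndarray, target_values: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised Spearman rho and two-sided t-approximation p of many genes
    against one target vector (identical formulas to :func:`stats.spearman`
    for n > 10; constant genes yield NaN)."""
    n = target_values.size
    rt = rankdata(target_values)
    rg = rankdata(gene_values, axis=1)
    rt_c = rt - rt.mean()
    rg_c = rg - rg.mean(axis=1, keepdims=True)
    denom = np.sqrt((rg_c**2).sum(axis=1) * (rt_c**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (rg_c @ rt_c) / denom
    rho[denom == 0] = np.nan
    p = np.full(rho.shape, np.nan)
    ok = np.isfinite(rho)
    p[ok] = stats._spearman_t_p(rho[ok], n)
    return rho, np.maximum(p, 1e-12)


def spearman_screen(
    em: ExpressionMatrix,
    signature_genes: list[str],
    target_gene: str,
    min_lines: int = 20,
    alpha: float = ALPHA,
    adjust: str | None = None,
    with_quartile_test: bool = True,
) -> TissueScreenResult:
    """Per-(tissue, gene) Spearman correlations against the target gene.

    Signature genes absent from the matrix are recorded as missing (NaN)
    rather than failing; constant vectors likewise yield NaN and are masked.
    ``adjust='bh'`` switches masking to Benjamini-Hochberg adjusted p-values
    across the gene x tissue grid (off by default).
    """
    if target_gene not in em.values.index:
        raise ValueError(f"target gene {target_gene!r} not in matrix")
    present = [g for g in signature_genes if g in em.values.index]
    if not present:
        raise ValueError("no signature gene present in the matrix")
    tissues = eligible_tissues(em, min_lines=min_lines)
    rows = []
    for tissue in tissues:
        samples = em.samples_of(tissue)
        n = len(samples)
        tv = em.values.loc[target_gene, samples].to_numpy()
        block = em.values.loc[present, samples].to_numpy()
        if n > 10 and np.ptp(tv) > 0:
            rho_vec, p_vec = _spearman_tissue_block(block, tv)
        else:
            rho_vec = np.full(len(present), np.nan)
            p_vec = np.full(len(present), np.nan)
            for i, g in enumerate(present):
                try:
                    res = stats.spearman(block[i], tv)
                    rho_vec[i], p_vec[i] = res.statistic, res.p_value
                except UndefinedStatisticError:
                    pass
        target_series = em.values.loc[target_gene, samples]
        for i, g in enumerate(present):
            q1q4_p = np.nan
            if with_quartile_test:
                gene_series = em.values.loc[g, samples]
                try:
                    q1q4_p = q1_vs_q4_test(target_series, quartile_stratify(gene_series)).p_value
                except ValueError:
                    pass
            rows.append(
                {
                    "tissue": tissue,
                    "gene": g,
                    "rho": rho_vec[i],
                    "rho_p": p_vec[i],
                    "q1q4_p": q1q4_p,
                }
            )
        for g in signature_genes:
            if g not in em.values.index:
                rows.append(
                    {"tissue": tissue, "gene": g, "rho": np.nan, "rho_p": np.nan, "q1q4_p": np.nan}
                )
    table = pd.DataFrame(rows)
    pcol = table["rho_p"].to_numpy()
    if adjust == "bh":
        ok = np.isfinite(pcol)
        adj = pcol.copy()
        adj[ok] = stats.adjust_pvalues(pcol[ok], method="bh")
        table["mask_p"] = adj
    else:
        table["mask_p"] = pcol
    table["masked"] = ~(table["mask_p"] <= alpha)  # NaN -> masked
    return TissueScreenResult(table=table, target_gene=target_gene, alpha=alpha)


def binary_cluster(result: TissueScreenResult) -> list[str]:
    """Average-linkage clustering of genes on binary significance profiles.

    The binary matrix holds 1 where the correlation p-value is below alpha;
    distance between two genes is the asymmetric binary (Jaccard) distance —
    mismatches over positions where either is 1 — with the all-zero/all-zero
    pair defined as distance 0 so the clustering stays total. Returns the
    dendrogram leaf order (input order for a single gene).
    """
    table = result.table
    binary = (
        table.assign(sig=(~table["masked"]).astype(int))
        .pivot_table(index="gene", columns="tissue", values="sig", sort=False)
        .fillna(0)
        .astype(int)
    )
    genes = list(binary.index)
    if len(genes) < 2:
        return genes
    mat = binary.to_numpy()
    m = len(genes)
    condensed = np.zeros(m * (m - 1) // 2)
    k = 0
    for i in range(m):
        for j in range(i + 1, m):
            either = np.logical_or(mat[i], mat[j]).sum()
            mism = np.logical_xor(mat[i], mat[j]).sum()
            condensed[k] = mism / either if either > 0 else 0.0
            k += 1
    link = sch.linkage(condensed, method="average")
    order = sch.leaves_list(link)
    return [genes[i] for i in order]


def positive_tissue_count(
    result: TissueScreenResult,
    min_tissues: int = 5,
) -> tuple[pd.Series, list[str]]:
    """Per-gene count of tissues with positive, significant correlation, and
    the genes reaching at least ``min_tissues`` such tissues."""
    table = result.table
    positive = (table["rho"] > 0) & (~table["masked"])
    counts = positive.groupby(table["gene"], sort=False).sum().astype(int)
    flagged = [g for g in counts.index if counts[g] >= min_tissues]
    return counts, flagged


def mean_target_expression(
    em: ExpressionMatrix, target_gene: str, min_lines: int = 20
) -> pd.Series:
    """Arithmetic mean of the target gene per eligible tissue."""
    if target_gene not in em.values.index:
        raise ValueError(f"target gene {target_gene!r} not in matrix")
    tissues = eligible_tissues(em, min_lines=min_lines)
    return pd.Series(
        {t: float(em.values.loc[target_gene, em.samples_of(t)].mean()) for t in tissues}
    )


def run_screen(
    em: ExpressionMatrix,
    signature_genes: list[str],
    target_gene: str,
    min_lines: int = 20,
    min_tissues: int = 5,
    alpha: float = ALPHA,
    adjust: str | None = None,
    with_quartile_test: bool = True,
) -> TissueScreenResult:
    """Full screen: correlations, quartile tests, clustering and positivity."""
    result = spearman_screen(
        em,
        signature_genes,
        target_gene,
        min_lines=min_lines,
        alpha=alpha,
        adjust=adjust,
        with_quartile_test=with_quartile_test,
    )
    result.mean_target = mean_target_expression(em, target_gene, min_lines=min_lines)
    result.positive_counts, result.flagged_genes = positive_tissue_count(
        result, min_tissues=min_tissues
    )
    result.gene_order = binary_cluster(result)
    return result
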