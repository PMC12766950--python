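"""Derivation of a KRAS signature gene set from single-cell counts.

The procedure is threshold-and-intersect: differential expression between a
KRAS-active and a matched control genotype, strict thresholds on adjusted
p-value and fold change, mapping of the surviving (mouse) genes to human
orthologs, and intersection with a hallmark KRAS-up style gene set. The DE
step itself is a rank-sum stand-in for a hurdle-model test: per gene,
counts are normalised to counts-per-10k and log1p-transformed, the two
genotypes compared with a two-sided rank-sum test, and the fold change taken
as the ratio of CP10K means with a small pseudocount. An externally produced
DE table (TSV with gene, log2_fold_change, p_value[, adj_p]) can be injected
instead via :func:`read_deg_table`.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import stats
from .io_formats import GeneSet, OrthologMap, SingleCellCounts

logger = logging.getLogger(__name__)

__all__ = [
    "SignatureResult",
    "differential_expression",
    "select_degs",
    "map_orthologs",
    "intersect_signature",
    "derive_signature",
    "read_deg_table",
    "write_deg_table",
    "write_signature",
]

PSEUDOCOUNT = 1e-9  # on CP10K means, for fold-change stability


@dataclass
class SignatureResult:
    """Final signature genes (target-species symbols, hallmark order) plus
    the counts surviving each filter stage."""

    genes: list[str]
    provenance: dict[str, int] = field(default_factory=dict)


def _cp10k_log1p(counts: np.ndarray) -> np.ndarray:
    lib = counts.sum(axis=1, keepdims=True).astype(float)
    lib[lib == 0] = 1.0
    return np.log1p(counts / lib * 1e4)


def differential_expression(
    sc: SingleCellCounts,
    genotype_a: str,
    genotype_b: str,
    adjust_method: str = "bonferroni",
) -> pd.DataFrame:
    """Per-gene rank-sum differential expression of genotype_a vs genotype_b.

    Returns a table with gene_id, log2_fold_change (a relative to b, on
    CP10K means), p_value, adj_p and direction. Both genotypes need at
    least 20 cells.
    """
    labels = sc.cell_genotype.values
    mask_a = labels == genotype_a
    mask_b = labels == genotype_b
    for g, m in ((genotype_a, mask_a), (genotype_b, mask_b)):
        if m.sum() == 0:
            raise ValueError(f"genotype {g!r} absent")
        if m.sum() < 20:
            raise ValueError(f"genotype {g!r} has fewer than 20 cells")
    if len(sc.gene_ids) < 2:
        raise ValueError("need at least 2 genes")
    norm = _cp10k_log1p(sc.counts)
    cp10k = np.expm1(norm)
    mean_a = cp10k[mask_a].mean(axis=0)
    mean_b = cp10k[mask_b].mean(axis=0)
    lfc = np.log2((mean_a + PSEUDOCOUNT) / (mean_b + PSEUDOCOUNT))
    pvals = np.empty(len(sc.gene_ids))
    for j in range(len(sc.gene_ids)):
        col = norm[:, j]
        if np.ptp(col) == 0:
            pvals[j] = 1.0
            continue
        res = stats.rank_sum_test(col[mask_a], col[mask_b], alternative="two_sided")
        pvals[j] = res.p_value
    adj = stats.adjust_pvalues(pvals, method=adjust_method)
    tbl = pd.DataFrame(
        {
            "gene_id": sc.gene_ids,
            "log2_fold_change": lfc,
            "p_value": pvals,
            "adj_p": np.maximum(adj, pvals),
            "direction": np.where(lfc > 0, "up", "down"),
        }
    )
    return tbl


def select_degs(
    tbl: pd.DataFrame,
    adj_p_max: float = 0.01,
    lfc_min: float = 1.0,
    direction: str = "up",
) -> list[str]:
    """Genes passing the strict thresholds adj_p < adj_p_max and, for the
    'up' direction, log2FC > lfc_min (both inequalities strict, matching the
    printed selection rule)."""
    if tbl.empty:
        return []
    keep = tbl["adj_p"] < adj_p_max
    if direction == "up":
        keep &= tbl["log2_fold_change"] > lfc_min
    elif direction == "down":
        keep &= tbl["log2_fold_change"] < -lfc_min
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return tbl.loc[keep, "gene_id"].tolist()


def map_orthologs(genes: list[str], m: OrthologMap) -> tuple[list[str], list[str]]:
    """Map genes through an ortholog table.

    Returns (mapped, unmapped): unmapped genes are dropped and reported;
    duplicate targets after mapping are collapsed, order preserved.
    """
    mapped: list[str] = []
    unmapped: list[str] = []
    for g in genes:
        target = m.get(g)
        if target is None:
            unmapped.append(g)
        elif target not in mapped:
            mapped.append(target)
    if unmapped:
        logger.warning("%d genes had no ortholog and were dropped", len(unmapped))
    return mapped, unmapped


def intersect_signature(
    mapped: list[str],
    hallmark: GeneSet,
    provenance: dict[str, int] | None = None,
) -> SignatureResult:
    """Intersect ortholog-mapped genes with a hallmark set, hallmark order."""
    mapped_set = set(mapped)
    genes = [g for g in sorted(hallmark.members) if g in mapped_set]
    prov = dict(provenance or {})
    prov.setdefault("n_mapped", len(mapped))
    prov["n_hallmark"] = len(hallmark.members)
    prov["n_signature"] = len(genes)
    if not genes:
        logger.warning("signature intersection is empty")
    return SignatureResult(genes=genes, provenance=prov)


def derive_signature(
    sc: SingleCellCounts,
    genotype_a: str,
    genotype_b: str,
    ortholog_map: OrthologMap,
    hallmark: GeneSet,
    adj_p_max: float = 0.01,
    lfc_min: float = 1.0,
    adjust_method: str = "bonferroni",
    deg_table: pd.DataFrame | None = None,
) -> SignatureResult:
    """Full pipeline: DE -> threshold -> ortholog map -> hallmark intersect.

    ``deg_table`` can carry an externally computed DE table, bypassing the
    built-in rank-sum stand-in.
    """
    tbl = deg_table if deg_table is not None else differential_expression(
        sc, genotype_a, genotype_b, adjust_method=adjust_method
    )
    degs = select_degs(tbl, adj_p_max=adj_p_max, lfc_min=lfc_min, direction="up")
    mapped, unmapped = map_orthologs(degs, ortholog_map)
    prov = {
        "n_genes_tested": len(tbl),
        "n_degs": len(degs),
        "n_unmapped": len(unmapped),
        "n_mapped": len(mapped),
    }
    return intersect_signature(mapped, hallmark, provenance=prov)


# ---------------------------------------------------------------------------
# table IO


def read_deg_table(path: str | os.PathLike) -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    tbl = pd.read_csv(path, sep=sep)
    required = {"gene_id", "log2_fold_change", "p_value"}
    if not required.issubset(tbl.columns):
        raise ValueError(f"DE table requires columns {sorted(required)}")
    if "adj_p" not in tbl.columns:
        tbl["adj_p"] = stats.adjust_pvalues(tbl["p_value"].to_numpy())
    if (tbl["adj_p"] + 1e-12 < tbl["p_value"]).any():
        raise ValueError("adjusted p-values must not undercut raw p-values")
    if "direction" not in tbl.columns:
        tbl["direction"] = np.where(tbl["log2_fold_change"] > 0, "up", "down")
    return tbl


def write_deg_table(tbl: pd.DataFrame, path: str | os.PathLike) -> None:
    sep = "," if str(path).endswith(".csv") else "\t"
    tbl.to_csv(path, sep=sep, index=False)


def write_signature(result: SignatureResult, path_tsv: str | os.PathLike, path_gmt: str | os.PathLike | None = None, name: str = "KRAS_SIGNATURE") -> None:
    """Write the signature as a one-column TSV and optionally a one-line GMT."""
    pd.DataFrame({"gene_id": result.genes}).to_csv(path_tsv, sep="\t", index=False)
    if path_gmt is not None:
        with open(path_gmt, "w") as fh:
            fh.write("\t".join([name, "na", *result.genes]) + "\n")
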