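"""Pseudo-bulk aggregation and single-sample GSEA with a permutation null.

Single-cell counts are aggregated into pseudo-bulk profiles by summing the
UMI counts of randomly selected cells of one genotype (sampling without
replacement within a replicate, independently across replicates). Each
profile is normalised (counts per 10k, log1p) and scored against gene sets
with a weighted Kolmogorov-Smirnov running sum:

genes are ranked by profile value descending (ties broken by gene id); at a
set member the running sum increases by |v|^w / sum_hits |v|^w (w = 1 by
default) and at a non-member it decreases by 1/(N - n_hits). The enrichment
score ES is the running sum at its maximum absolute deviation. Signed sets
are scored as ES(positive members) - ES(negative members) by default (an
alternative mode folds the weights into the hit increments). The one-sided
permutation p permutes gene labels of the profile: p = (k+1)/(times+1) with
k the number of permutations reaching ES >= observed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import stats
from .io_formats import GeneSet, SignedGeneSet, SingleCellCounts
from .stats import TestResult

__all__ = [
    "PseudoBulkSample",
    "make_pseudobulks",
    "ssgsea_score",
    "score_pathways",
    "compare_pathway_activity",
]


@dataclass
class PseudoBulkSample:
    genotype: str
    replicate: int
    gene_totals: np.ndarray
    cells_used: list[str]
    seed: int

    @property
    def sample_id(self) -> str:
        return f"{self.genotype}_pb{self.replicate:02d}"


def make_pseudobulks(
    sc: SingleCellCounts,
    genotype: str,
    n_cells: int = 500,
    n_reps: int = 10,
    seed: int = 0,
) -> list[PseudoBulkSample]:
    """Sum the counts of ``n_cells`` randomly selected cells of one genotype,
    ``n_reps`` times (cells distinct within a replicate, replicates may
    overlap)."""
    idx = np.flatnonzero(sc.cell_genotype.values == genotype)
    if idx.size < n_cells:
        raise ValueError(
            f"genotype {genotype!r} has {idx.size} cells, fewer than n_cells={n_cells}"
        )
    rng = np.random.default_rng(seed)
    out = []
    for rep in range(1, n_reps + 1):
        chosen = rng.choice(idx, size=n_cells, replace=False)
        chosen.sort()
        totals = sc.counts[chosen].sum(axis=0)
        out.append(
            PseudoBulkSample(
                genotype=genotype,
                replicate=rep,
                gene_totals=np.asarray(totals, dtype=np.int64),
                cells_used=[sc.cell_ids[i] for i in chosen],
                seed=seed,
            )
        )
    return out


# ---------------------------------------------------------------------------
# enrichment score


def _ranked_profile(profile: pd.Series) -> tuple[np.ndarray, pd.Index]:
    """Values sorted by profile descending, ties broken by gene id."""
    order = np.lexsort((profile.index.to_numpy(), -profile.to_numpy()))
    return profile.to_numpy()[order], profile.index[order]


def _es_from_mask(values: np.ndarray, hit_mask: np.ndarray, weight: float) -> float:
    """Running-sum enrichment score for one hit mask over ranked values."""
    n = values.size
    nh = int(hit_mask.sum())
    if nh == 0 or nh == n:
        # degenerate: no miss (or no hit) steps; the sum ramps to 1 (or stays 0)
        return 1.0 if nh == n else 0.0
    w = np.abs(values) ** weight
    denom = w[hit_mask].sum()
    steps = np.where(hit_mask, (w / denom) if denom > 0 else (1.0 / nh), -1.0 / (n - nh))
    if denom <= 0:
        steps = np.where(hit_mask, 1.0 / nh, -1.0 / (n - nh))
    running = np.cumsum(steps)
    i = int(np.argmax(np.abs(running)))
    return float(running[i])


def _perm_es(
    values: np.ndarray,
    n_pos: int,
    n_neg: int,
    weight: float,
    times: int,
    rng: np.random.Generator,
    chunk: int = 2000,
) -> np.ndarray:
    """Enrichment scores of ``times`` random (disjoint) hit subsets.

    For unsigned sets pass n_neg=0; for signed difference scoring the positive
    and negative subsets are drawn disjointly from one permutation.
    """
    n = values.size
    w = (np.abs(values) ** weight).astype(np.float64)
    out = np.empty(times)
    done = 0
    while done < times:
        b = min(chunk, times - done)
        perms = rng.permuted(np.tile(np.arange(n), (b, 1)), axis=1)
        es = _es_batch(w, perms[:, :n_pos])
        if n_neg > 0:
            es = es - _es_batch(w, perms[:, n_pos : n_pos + n_neg])
        out[done : done + b] = es
        done += b
    return out


def _es_batch(w: np.ndarray, hit_idx: np.ndarray) -> np.ndarray:
    """Vectorised ES for a batch of hit-index sets over shared rank weights."""
    b, nh = hit_idx.shape
    n = w.size
    if nh == 0:
        return np.zeros(b)
    if nh == n:
        return np.ones(b)
    miss = -1.0 / (n - nh)
    steps = np.full((b, n), miss, dtype=np.float64)
    vals = w[hit_idx]
    denom = vals.sum(axis=1, keepdims=True)
    safe = denom > 0
    hit_steps = np.where(safe, vals / np.where(safe, denom, 1.0), 1.0 / nh)
    rows = np.repeat(np.arange(b), nh)
    steps[rows, hit_idx.ravel()] = hit_steps.ravel()
    running = np.cumsum(steps, axis=1)
    idx = np.argmax(np.abs(running), axis=1)
    return running[np.arange(b), idx]


def ssgsea_score(
    profile: pd.Series,
    gene_set: GeneSet | SignedGeneSet,
    min_set_size: int = 5,
    times: int = 10_000,
    seed: int | None = None,
    weight: float = 1.0,
    signed_mode: str = "difference",
) -> tuple[float, float]:
    """Enrichment score and one-sided permutation p for one profile and set.

    Raises ValueError when the overlap with the profile's genes is below
    ``min_set_size`` (callers treat that as "set absent"). ``signed_mode``
    chooses between 'difference' (ES+ minus ES-) and 'weighted' (weights fold
    into the hit increments of a single running sum).
    """
    if profile.index.has_duplicates:
        raise ValueError("profile gene ids must be unique")
    values, genes = _ranked_profile(profile)
    gene_pos = {g: i for i, g in enumerate(genes)}
    signed = isinstance(gene_set, SignedGeneSet)
    if signed:
        pos = [g for g, w in gene_set.weights.items() if w > 0 and g in gene_pos]
        neg = [g for g, w in gene_set.weights.items() if w < 0 and g in gene_pos]
        overlap = len(pos) + len(neg)
    else:
        pos = [g for g in gene_set.members if g in gene_pos]
        neg = []
        overlap = len(pos)
    if overlap < min_set_size:
        raise ValueError(
            f"set {gene_set.name!r}: {overlap} genes overlap the profile, "
            f"fewer than min_set_size={min_set_size}"
        )
    rng = np.random.default_rng(seed)
    if signed and signed_mode == "weighted":
        # fold |weights| into the hit increments of a single running sum
        mask = np.zeros(values.size, dtype=bool)
        wvec = np.ones(values.size)
        for g, w in gene_set.weights.items():
            if g in gene_pos:
                mask[gene_pos[g]] = True
                wvec[gene_pos[g]] = abs(w)
        es = _es_from_mask(values * wvec, mask, weight)
        perm = _perm_es(values, int(mask.sum()), 0, weight, times, rng)
    else:
        mask_pos = np.zeros(values.size, dtype=bool)
        mask_pos[[gene_pos[g] for g in pos]] = True
        es = _es_from_mask(values, mask_pos, weight)
        if neg:
            mask_neg = np.zeros(values.size, dtype=bool)
            mask_neg[[gene_pos[g] for g in neg]] = True
            es -= _es_from_mask(values, mask_neg, weight)
        perm = _perm_es(values, len(pos), len(neg), weight, times, rng)
    k = int(np.sum(perm >= es - 1e-12))
    p = (k + 1) / (times + 1)
    return float(es), float(p)


def cp10k_log1p_profile(pb: PseudoBulkSample, gene_ids: Sequence[str]) -> pd.Series:
    totals = pb.gene_totals.astype(float)
    lib = totals.sum()
    norm = np.log1p(totals / (lib if lib > 0 else 1.0) * 1e4)
    return pd.Series(norm, index=list(gene_ids))


def score_pathways(
    pbs: list[PseudoBulkSample],
    sets: Sequence[GeneSet | SignedGeneSet],
    gene_ids: Sequence[str],
    normalization: str = "cp10k_log1p",
    min_set_size: int = 5,
    times: int = 10_000,
    seed: int = 0,
    weight: float = 1.0,
) -> pd.DataFrame:
    """Score every pseudo-bulk against every set; sets falling below
    ``min_set_size`` genes in the profile are absent from the table."""
    if not pbs:
        raise ValueError("need at least one pseudo-bulk sample")
    if normalization != "cp10k_log1p":
        raise ValueError(f"unknown normalization {normalization!r}")
    rows = []
    for si, gene_set in enumerate(sets):
        for pb in pbs:
            profile = cp10k_log1p_profile(pb, gene_ids)
            try:
                es, p = ssgsea_score(
                    profile,
                    gene_set,
                    min_set_size=min_set_size,
                    times=times,
                    seed=seed + 7919 * si,
                    weight=weight,
                )
            except ValueError:
                break
            n_used = sum(1 for g in gene_set.members if g in profile.index)
            rows.append(
                {
                    "sample": pb.sample_id,
                    "genotype": pb.genotype,
                    "replicate": pb.replicate,
                    "set": gene_set.name,
                    "es": es,
                    "perm_p": p,
                    "n_genes_used": n_used,
                }
            )
    return pd.DataFrame(rows)


def compare_pathway_activity(
    tbl: pd.DataFrame,
    genotype_a: str,
    genotype_b: str,
    set_name: str,
    exact: bool = False,
) -> TestResult:
    """One-sided rank-sum test of per-replicate enrichment scores,
    H1: higher in ``genotype_a``."""
    sub = tbl[tbl["set"] == set_name]
    if sub.empty:
        raise ValueError(f"set {set_name!r} not present in score table")
    a = sub.loc[sub["genotype"] == genotype_a, "es"].to_numpy()
    b = sub.loc[sub["genotype"] == genotype_b, "es"].to_numpy()
    if a.size == 0 or b.size == 0:
        raise ValueError("both genotypes must be scored")
    return stats.rank_sum_test(a, b, alternative="greater", exact=exact)
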