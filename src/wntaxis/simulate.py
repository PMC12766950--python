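"""Seeded generators for every input the pipeline consumes, with planted truth.

Three generators emulate the pipeline's data types:

* :func:`simulate_cell_line_matrix` — a pan-cancer cell-line expression matrix
  (tissue-labelled samples on a log2(TPM+1)-like scale) in which a chosen
  fraction of tissues carries a planted rank correlation between each
  signature gene and the target WNT ligand. Correlation is planted through a
  latent Gaussian copula, so the implied Spearman correlation is
  (6/pi)*asin(rho/2) and is reported in the truth table.
* :func:`simulate_single_cell` — genotype- and cluster-labelled UMI counts
  with negative-binomial background genes, a target gene whose nonzero
  fraction per (genotype, cluster) is planted exactly, and a designated
  pathway gene set whose means are shifted in one genotype.
* :func:`simulate_ish` — per-cell in-situ-hybridization dot counts (Poisson)
  with Bernoulli-gated clustered-dot fractions per condition.

All generators are deterministic under a fixed seed (numpy Generator with
PCG64). Synthetic mouse symbols are the capitalised form of their human
orthologs (e.g. ``Sig001`` vs ``SIG001``) so the ortholog-mapping step is
exercised nontrivially.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .io_formats import ExpressionMatrix, GeneSet, OrthologMap, SingleCellCounts
from .ish import IshObservation

__all__ = [
    "ScreenSimConfig",
    "ScSimConfig",
    "IshSimConfig",
    "simulate_cell_line_matrix",
    "simulate_single_cell",
    "simulate_ish",
    "implied_spearman",
    "TARGET_GENE_HUMAN",
    "TARGET_GENE_MOUSE",
]

TARGET_GENE_HUMAN = "WNT7B"
TARGET_GENE_MOUSE = "Wnt7b"


def implied_spearman(rho: float) -> float:
    """Spearman correlation implied by a Gaussian copula with parameter rho."""
    return float((6.0 / np.pi) * np.arcsin(rho / 2.0))


# ---------------------------------------------------------------------------
# pan-cancer screen input


@dataclass
class ScreenSimConfig:
    """Study conditions for the cell-line screen: 22 tissues, >20 lines each,
    33 signature genes correlated with the target in a subset of tissues."""

    n_tissues: int = 22
    lines_per_tissue: int = 30
    n_signature_genes: int = 33
    n_null_genes: int = 100
    planted_rho: float = 0.6
    planted_tissue_fraction: float = 6 / 22
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lines_per_tissue < 4:
            raise ValueError("lines_per_tissue must be >= 4 (quartiles must be non-empty)")
        if not (-1.0 < self.planted_rho < 1.0):
            raise ValueError("planted_rho must lie in (-1, 1)")
        if not (0.0 <= self.planted_tissue_fraction <= 1.0):
            raise ValueError("planted_tissue_fraction must lie in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


def _softplus_log2(z: np.ndarray) -> np.ndarray:
    # strictly monotone map onto a non-negative log2(TPM+1)-like scale
    return np.logaddexp(0.0, z) / np.log(2.0)


def simulate_cell_line_matrix(cfg: ScreenSimConfig) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Simulate the screen's expression matrix and its planted-effect truth.

    Returns the matrix and a long truth table with one row per
    (gene, tissue): whether the correlation was planted there and the
    copula-implied Spearman value. The planted tissues and gene roles are in
    ``truth.attrs``.
    """
    rng = np.random.default_rng(cfg.seed)
    tissues = [f"tissue{i + 1:02d}" for i in range(cfg.n_tissues)]
    sig_genes = [f"KSIG{i + 1:03d}" for i in range(cfg.n_signature_genes)]
    null_genes = [f"NULL{i + 1:03d}" for i in range(cfg.n_null_genes)]
    genes = [TARGET_GENE_HUMAN] + sig_genes + null_genes

    n_planted = int(round(cfg.planted_tissue_fraction * cfg.n_tissues))
    planted_tissues = sorted(
        rng.choice(cfg.n_tissues, size=n_planted, replace=False).tolist()
    )
    planted_set = {tissues[i] for i in planted_tissues}

    baselines = rng.uniform(1.0, 6.0, size=len(genes))
    rho = cfg.planted_rho
    cols: dict[str, np.ndarray] = {}
    sample_ids: list[str] = []
    tissue_labels: list[str] = []
    blocks = []
    for ti, tissue in enumerate(tissues):
        n = cfg.lines_per_tissue
        z_target = rng.standard_normal(n)
        z = np.empty((len(genes), n))
        z[0] = z_target
        eps = rng.standard_normal((cfg.n_signature_genes, n))
        if tissue in planted_set:
            z[1 : 1 + cfg.n_signature_genes] = rho * z_target + np.sqrt(1 - rho**2) * eps
        else:
            z[1 : 1 + cfg.n_signature_genes] = eps
        z[1 + cfg.n_signature_genes :] = rng.standard_normal((cfg.n_null_genes, n))
        vals = _softplus_log2(baselines[:, None] + cfg.noise_sd * z)
        blocks.append(vals)
        sample_ids.extend(f"{tissue}_line{j + 1:03d}" for j in range(n))
        tissue_labels.extend([tissue] * n)
    values = pd.DataFrame(np.concatenate(blocks, axis=1), index=genes, columns=sample_ids)
    em = ExpressionMatrix(
        values=values,
        sample_tissue=pd.Series(tissue_labels, index=sample_ids),
    )

    rows = []
    for gene in sig_genes + null_genes:
        is_sig = gene in set(sig_genes)
        for tissue in tissues:
            planted = is_sig and tissue in planted_set
            rows.append(
                {
                    "gene": gene,
                    "tissue": tissue,
                    "planted": planted,
                    "implied_spearman": implied_spearman(rho) if planted else 0.0,
                }
            )
    truth = pd.DataFrame(rows)
    truth.attrs["planted_tissues"] = sorted(planted_set)
    truth.attrs["signature_genes"] = sig_genes
    truth.attrs["null_genes"] = null_genes
    truth.attrs["target_gene"] = TARGET_GENE_HUMAN
    truth.attrs["implied_spearman"] = implied_spearman(rho)
    return em, truth


# ---------------------------------------------------------------------------
# single-cell counts

_CLUSTERS = ("S1", "S2", "N", "Pr", "PreP", "P", "W")

_DEFAULT_CLUSTER_PROPS: dict[str, dict[str, float]] = {
    # organoid cell-state mix; the KRAS-active genotype shifts toward
    # pit/WNT-producing states at the expense of neck cells
    "RZ": {"S1": 0.16, "S2": 0.14, "N": 0.20, "Pr": 0.10, "PreP": 0.15, "P": 0.15, "W": 0.10},
    "RZK": {"S1": 0.14, "S2": 0.12, "N": 0.10, "Pr": 0.10, "PreP": 0.20, "P": 0.19, "W": 0.15},
}

_DEFAULT_EXPRESSING_FRACTION: dict[tuple[str, str], float] = {
    # fraction of cells with a nonzero target-gene UMI count; highest in the
    # WNT-producing cluster and raised genotype-wide by KRAS activation,
    # except in terminally differentiated pit cells
    **{("RZ", c): 0.05 for c in _CLUSTERS},
    ("RZ", "W"): 0.30,
    **{("RZK", c): 0.15 for c in _CLUSTERS},
    ("RZK", "W"): 0.60,
    ("RZK", "P"): 0.05,
}


@dataclass
class ScSimConfig:
    """Study conditions for genotype-labelled UMI counts (RZ vs RZK-like)."""

    n_cells_per_genotype: int = 5000
    n_genes: int = 600
    cluster_proportions: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {g: dict(p) for g, p in _DEFAULT_CLUSTER_PROPS.items()}
    )
    expressing_fraction: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: dict(_DEFAULT_EXPRESSING_FRACTION)
    )
    pathway_gene_shift: Mapping[str, float] = field(
        default_factory=lambda: {"RZK": float(np.log(2.0))}
    )
    n_pathway_genes: int = 100
    dispersion: float = 0.5
    seed: int = 0
    target_gene: str = TARGET_GENE_MOUSE

    def __post_init__(self) -> None:
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        for g, props in self.cluster_proportions.items():
            tot = float(sum(props.values()))
            if abs(tot - 1.0) > 1e-8:
                raise ValueError(f"cluster proportions of {g!r} sum to {tot}, not 1")
        for key, f in self.expressing_fraction.items():
            if not (0.0 <= f <= 1.0):
                raise ValueError(f"expressing fraction {key} outside [0, 1]")
        if self.n_pathway_genes >= self.n_genes:
            raise ValueError("n_pathway_genes must be smaller than n_genes")

    @property
    def genotypes(self) -> list[str]:
        return list(self.cluster_proportions)


def mouse_gene_names(cfg: ScSimConfig) -> tuple[list[str], list[str], str]:
    """(pathway genes, background genes, target) in mouse symbol style."""
    pathway = [f"Mapk{i + 1:03d}" for i in range(cfg.n_pathway_genes)]
    n_bg = cfg.n_genes - cfg.n_pathway_genes - 1
    background = [f"Bgd{i + 1:04d}" for i in range(n_bg)]
    return pathway, background, cfg.target_gene


def default_ortholog_map(cfg: ScSimConfig) -> OrthologMap:
    """Mouse->human map for every simulated gene (human = upper-case symbol)."""
    pathway, background, target = mouse_gene_names(cfg)
    return OrthologMap(pairs={g: g.upper() for g in pathway + background + [target]})


def simulate_single_cell(cfg: ScSimConfig) -> tuple[SingleCellCounts, dict]:
    """Simulate labelled UMI counts with planted expressing fractions and a
    pathway shift; returns the counts and a truth dictionary."""
    rng = np.random.default_rng(cfg.seed)
    pathway, background, target = mouse_gene_names(cfg)
    genes = pathway + [target] + background
    target_idx = len(pathway)
    base_mu = rng.lognormal(mean=-0.5, sigma=1.0, size=len(genes))
    base_mu[target_idx] = 0.0  # target handled by the planted-fraction model

    r = 1.0 / cfg.dispersion  # NB size parameter; var = mu + dispersion*mu^2
    all_counts = []
    cell_ids: list[str] = []
    genotype_labels: list[str] = []
    cluster_labels: list[str] = []
    for genotype in cfg.genotypes:
        props = cfg.cluster_proportions[genotype]
        clusters = list(props)
        pvec = np.array([props[c] for c in clusters], dtype=float)
        n = cfg.n_cells_per_genotype
        for _attempt in range(100):
            assign = rng.choice(len(clusters), size=n, p=pvec)
            counts_per_cluster = np.bincount(assign, minlength=len(clusters))
            if np.all(counts_per_cluster[pvec > 0] > 0):
                break
            warnings.warn(f"empty cluster for genotype {genotype!r}; resampling")
        mu = np.broadcast_to(base_mu, (n, len(genes))).copy()
        shift = float(cfg.pathway_gene_shift.get(genotype, 0.0))
        if shift != 0.0:
            mu[:, : len(pathway)] *= np.exp(shift)
        with np.errstate(divide="ignore"):
            p_nb = r / (r + mu)
        counts = rng.negative_binomial(r, np.clip(p_nb, 1e-12, 1.0))
        # target gene: exact planted nonzero fraction per (genotype, cluster)
        tcol = np.zeros(n, dtype=np.int64)
        for ci, cl in enumerate(clusters):
            idx = np.flatnonzero(assign == ci)
            f = float(cfg.expressing_fraction.get((genotype, cl), 0.0))
            expressing = idx[rng.random(idx.size) < f]
            tcol[expressing] = 1 + rng.poisson(1.0, size=expressing.size)
        counts[:, target_idx] = tcol
        all_counts.append(counts)
        cell_ids.extend(f"{genotype}_cell{j + 1:05d}" for j in range(n))
        genotype_labels.extend([genotype] * n)
        cluster_labels.extend(clusters[a] for a in assign)
    sc = SingleCellCounts(
        counts=np.concatenate(all_counts, axis=0).astype(np.int64),
        cell_ids=cell_ids,
        gene_ids=genes,
        cell_genotype=pd.Series(genotype_labels, index=cell_ids),
        cell_cluster=pd.Series(cluster_labels, index=cell_ids),
    )
    truth = {
        "target_gene": target,
        "pathway_genes_mouse": pathway,
        "pathway_genes_human": [g.upper() for g in pathway],
        "pathway_set": GeneSet(name="MAPK_PROGRAM", members=frozenset(pathway)),
        "expressing_fraction": dict(cfg.expressing_fraction),
        "pathway_gene_shift": dict(cfg.pathway_gene_shift),
        "ortholog_map": default_ortholog_map(cfg),
    }
    return sc, truth


# ---------------------------------------------------------------------------
# in-situ hybridization dots


@dataclass
class IshSimConfig:
    """Study conditions for RNAscope-style dot counts per condition.

    Defaults emulate a control epithelium (sparse signal), an RSPO-independent
    genotype (low signal) and a KRAS-active genotype (strong, clustered
    signal)."""

    n_cells: int = 300
    dot_rate: Mapping[str, float] = field(
        default_factory=lambda: {"CTRL": 0.5, "RZ": 2.0, "RZK": 12.0}
    )
    cluster_prob: Mapping[str, float] = field(
        default_factory=lambda: {"CTRL": 0.02, "RZ": 0.05, "RZK": 0.5}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for cond, rate in self.dot_rate.items():
            if rate <= 0:
                raise ValueError(f"dot rate for {cond!r} must be positive")
        for cond, p in self.cluster_prob.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"cluster probability for {cond!r} outside [0, 1]")

    @property
    def conditions(self) -> list[str]:
        return list(self.dot_rate)


def simulate_ish(cfg: IshSimConfig) -> tuple[list[IshObservation], dict]:
    """Simulate per-cell dot counts and clustered-dot fractions per condition."""
    rng = np.random.default_rng(cfg.seed)
    obs: list[IshObservation] = []
    for cond in cfg.conditions:
        dots = rng.poisson(cfg.dot_rate[cond], size=cfg.n_cells)
        clustered = rng.random(cfg.n_cells) < cfg.cluster_prob.get(cond, 0.0)
        fractions = np.where(
            (dots > 0) & clustered, rng.uniform(0.12, 0.6, size=cfg.n_cells), 0.0
        )
        for j in range(cfg.n_cells):
            obs.append(
                IshObservation(
                    cell_id=f"{cond}_cell{j + 1:04d}",
                    condition=cond,
                    dots=int(dots[j]),
                    cluster_fraction=float(fractions[j]),
                )
            )
    truth = {"dot_rate": dict(cfg.dot_rate), "cluster_prob": dict(cfg.cluster_prob)}
    return obs, truth
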