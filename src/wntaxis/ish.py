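"""Semi-quantitative RNAscope scoring and expressing-cell-fraction statistics.

Cells are scored into ordinal classes 0-4 from their dot count and the
fraction of dots sitting in clusters:

* Class 4: more than 15 dots per cell;
* Class 3: 10-15 dots, or at least 4 dots with >10% of them clustered;
* Class 2: 4-9 dots with no or very few clusters (<=10%);
* Class 1: 1-3 dots;
* Class 0: no dots.

The clauses overlap in the original semi-quantitative scheme, so a fixed
precedence (4 -> 3 -> 2 -> 1 -> 0) makes the classifier total and mutually
exclusive. The cluster escalator requires at least 4 dots so that isolated
1-3-dot cells with a nominally high cluster fraction remain Class 1. The
"fewer than 1 dot per 10 cells" reading of Class 0 is a field-level average;
an optional field-level mode reassigns Class 1 cells to Class 0 when a
condition's mean dot count falls below 0.1.

Between-condition comparison uses Fisher's exact test on the class
contingency table; expressing-cell fractions in single-cell counts (nonzero
UMI for the target gene) are compared with 2x2 Fisher tests per cluster.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import stats
from .io_formats import SingleCellCounts
from .stats import TestResult

__all__ = [
    "IshObservation",
    "CLASS_LABELS",
    "classify_ish_cell",
    "class_distribution",
    "compare_class_distributions",
    "expressing_fraction",
    "expressing_fraction_test",
]

CLASS_LABELS = (0, 1, 2, 3, 4)
CLUSTER_FRACTION_CUTOFF = 0.10  # "no or very few clusters" interpreted as <= 10%


@dataclass(frozen=True)
class IshObservation:
    cell_id: str
    condition: str
    dots: int
    cluster_fraction: float

    def __post_init__(self) -> None:
        if self.dots < 0:
            raise ValueError("dot count must be >= 0")
        if not (0.0 <= self.cluster_fraction <= 1.0):
            raise ValueError("cluster_fraction must lie in [0, 1]")
        if self.dots == 0 and self.cluster_fraction != 0.0:
            raise ValueError("cluster_fraction must be 0 when there are no dots")


def classify_ish_cell(obs: IshObservation | None = None, *, dots: int | None = None, cluster_fraction: float | None = None) -> int:
    """Ordinal class 0-4 for one cell; accepts an observation or raw fields."""
    if obs is not None:
        dots, cluster_fraction = obs.dots, obs.cluster_fraction
    if dots is None or cluster_fraction is None:
        raise ValueError("provide an IshObservation or dots and cluster_fraction")
    if dots > 15:
        return 4
    if (10 <= dots <= 15) or (cluster_fraction > CLUSTER_FRACTION_CUTOFF and dots >= 4):
        return 3
    if 4 <= dots <= 9:
        return 2
    if 1 <= dots <= 3:
        return 1
    return 0


def class_distribution(
    observations: Iterable[IshObservation],
    field_level_class0: bool = False,
) -> pd.DataFrame:
    """Tally of cells per (condition, class); rows are conditions in order of
    first appearance, columns the classes 0-4.

    With ``field_level_class0`` the Class 0 definition "fewer than 1 dot per
    10 cells" is applied at condition level: Class 1 cells of a condition
    whose mean dot count is below 0.1 are reassigned to Class 0.
    """
    obs = list(observations)
    conditions = list(dict.fromkeys(o.condition for o in obs))
    table = pd.DataFrame(0, index=conditions, columns=list(CLASS_LABELS))
    mean_dots = {
        cond: float(np.mean([o.dots for o in obs if o.condition == cond] or [0.0]))
        for cond in conditions
    }
    for o in obs:
        cls = classify_ish_cell(o)
        if field_level_class0 and cls == 1 and mean_dots[o.condition] < 0.1:
            cls = 0
        table.loc[o.condition, cls] += 1
    table.index.name = "condition"
    return table


def compare_class_distributions(
    cd: pd.DataFrame,
    cond_a: str,
    cond_b: str,
    n_mc: int = 10_000,
    seed: int | None = None,
) -> TestResult:
    """Fisher's exact test on the 2 x 5 class table of two conditions.

    All-zero classes are dropped inside the r x c routine (with a warning);
    the test is two-sided and symmetric in condition order.
    """
    for cond in (cond_a, cond_b):
        if cond not in cd.index:
            raise KeyError(f"condition {cond!r} not present")
    table = cd.loc[[cond_a, cond_b]].to_numpy()
    return stats.fisher_exact_rxc(table, n_mc=n_mc, seed=seed)


def expressing_fraction(
    sc: SingleCellCounts,
    gene: str,
    by: Sequence[str] = ("genotype", "cluster"),
) -> pd.DataFrame:
    """Fraction of cells with a nonzero UMI count for ``gene`` per group.

    ``by`` picks the grouping labels among ``genotype`` and ``cluster``.
    """
    gi = sc.gene_index(gene)
    nonzero = sc.counts[:, gi] > 0
    frame = pd.DataFrame(
        {
            "genotype": sc.cell_genotype.values,
            "cluster": sc.cell_cluster.values,
            "expressing": nonzero,
        }
    )
    keys = list(by)
    for key in keys:
        if key not in ("genotype", "cluster"):
            raise ValueError(f"unknown grouping key {key!r}")
    grouped = frame.groupby(keys, sort=False)["expressing"]
    out = grouped.agg(n_cells="size", n_expressing="sum").reset_index()
    out["fraction"] = out["n_expressing"] / out["n_cells"]
    return out


def expressing_fraction_test(
    sc: SingleCellCounts,
    gene: str,
    cluster: str,
    genotype_a: str,
    genotype_b: str,
    alternative: str = "two_sided",
) -> TestResult:
    """2x2 Fisher test of expressing vs non-expressing cells between genotypes
    within one cluster."""
    gi = sc.gene_index(gene)
    nonzero = sc.counts[:, gi] > 0
    in_cluster = sc.cell_cluster.values == cluster
    table = []
    for genotype in (genotype_a, genotype_b):
        mask = in_cluster & (sc.cell_genotype.values == genotype)
        n = int(mask.sum())
        if n == 0:
            raise ValueError(f"no cells for genotype {genotype!r} in cluster {cluster!r}")
        k = int(nonzero[mask].sum())
        table.append([k, n - k])
    return stats.fisher_exact_2x2(np.array(table), alternative=alternative)
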