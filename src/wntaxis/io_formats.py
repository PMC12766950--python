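"""Readers, writers and validated container types for the pipeline's file formats.

Expression matrices are plain delimited text (genes in rows, one header row of
sample identifiers) with a separate sample->tissue metadata table. Gene sets
come as GMT; signed gene sets as three-column TSV (set, gene, weight).
Single-cell UMI counts are MatrixMarket triplets with ``barcodes.tsv`` /
``features.tsv`` companions (or a dense CSV), plus a per-cell metadata table
carrying genotype and cluster labels. Ortholog maps are two-column TSV.

Gene and sample identifiers are treated as opaque, case-sensitive strings;
parsing preserves file order. The delimiter is inferred from the extension
(``.csv`` -> comma, otherwise tab) and can be overridden.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "GeneSet",
    "SignedGeneSet",
    "SingleCellCounts",
    "OrthologMap",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_gmt",
    "write_gmt",
    "read_signed_sets",
    "write_signed_sets",
    "read_sc_counts",
    "write_sc_counts",
    "read_ortholog_map",
    "write_ortholog_map",
]


def _sep_for(path: str | os.PathLike, sep: str | None = None) -> str:
    if sep is not None:
        return sep
    return "," if str(path).endswith(".csv") else "\t"


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = pd.Index(ids)
    if seen.has_duplicates:
        dups = seen[seen.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what} identifiers: {dups[:5]}")


@dataclass
class ExpressionMatrix:
    """Genes x samples continuous expression on a log2(TPM+1)-like scale.

    ``values`` is a DataFrame indexed by gene id with sample ids as columns;
    ``sample_tissue`` maps every sample id to a tissue label.
    """

    values: pd.DataFrame
    sample_tissue: pd.Series

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "gene")
        _check_unique(self.values.columns, "sample")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("expression values must be numeric")
        if not np.all(np.isfinite(arr)):
            raise ValueError("expression values must be finite")
        if np.any(arr < 0):
            raise ValueError("expression values must be >= 0")
        missing = self.values.columns.difference(self.sample_tissue.index)
        if len(missing) > 0:
            raise ValueError(f"samples missing tissue labels: {list(missing)[:5]}")
        self.sample_tissue = self.sample_tissue.reindex(self.values.columns)
        if self.sample_tissue.isna().any():
            raise ValueError("tissue labels may not be NA")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def tissues(self) -> list[str]:
        """Tissue labels in order of first appearance."""
        return list(dict.fromkeys(self.sample_tissue))

    def samples_of(self, tissue: str) -> list[str]:
        return list(self.sample_tissue.index[self.sample_tissue == tissue])


@dataclass(frozen=True)
class GeneSet:
    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.name!r} has no members")
        object.__setattr__(self, "members", frozenset(self.members))


@dataclass(frozen=True)
class SignedGeneSet:
    """Gene set whose members carry signed, nonzero weights."""

    name: str
    weights: Mapping[str, float]

    def __post_init__(self) -> None:
        if not self.weights:
            raise ValueError(f"signed gene set {self.name!r} has no members")
        w = dict(self.weights)
        vals = np.array(list(w.values()), dtype=float)
        if not np.all(np.isfinite(vals)) or np.any(vals == 0):
            raise ValueError(f"weights of {self.name!r} must be finite and nonzero")
        object.__setattr__(self, "weights", w)

    @property
    def members(self) -> frozenset[str]:
        return frozenset(self.weights)


@dataclass
class SingleCellCounts:
    """Cells x genes non-negative integer UMI matrix with per-cell labels."""

    counts: np.ndarray  # (n_cells, n_genes), integer
    cell_ids: list[str]
    gene_ids: list[str]
    cell_genotype: pd.Series
    cell_cluster: pd.Series

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D cells x genes matrix")
        if not np.issubdtype(self.counts.dtype, np.integer):
            as_int = self.counts.astype(np.int64)
            if not np.array_equal(as_int, self.counts):
                raise ValueError("counts must be integers")
            self.counts = as_int
        if np.any(self.counts < 0):
            raise ValueError("counts must be >= 0")
        _check_unique(self.cell_ids, "cell")
        _check_unique(self.gene_ids, "gene")
        if self.counts.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise ValueError("counts shape does not match cell/gene ids")
        for name, lab in (("genotype", self.cell_genotype), ("cluster", self.cell_cluster)):
            lab = lab.reindex(self.cell_ids)
            if lab.isna().any():
                raise ValueError(f"cells missing {name} labels")
            setattr(self, f"cell_{name}", lab)

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    def gene_index(self, gene: str) -> int:
        try:
            return self.gene_ids.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not present") from None

    def subset_cells(self, mask: np.ndarray) -> "SingleCellCounts":
        idx = np.flatnonzero(np.asarray(mask))
        cells = [self.cell_ids[i] for i in idx]
        return SingleCellCounts(
            counts=self.counts[idx],
            cell_ids=cells,
            gene_ids=list(self.gene_ids),
            cell_genotype=self.cell_genotype.iloc[idx],
            cell_cluster=self.cell_cluster.iloc[idx],
        )

    def to_anndata(self):
        import anndata

        obs = pd.DataFrame(
            {"genotype": self.cell_genotype.values, "cluster": self.cell_cluster.values},
            index=self.cell_ids,
        )
        return anndata.AnnData(
            X=scipy.sparse.csr_matrix(self.counts),
            obs=obs,
            var=pd.DataFrame(index=self.gene_ids),
        )


@dataclass
class OrthologMap:
    """Source->target gene symbol map (e.g. mouse -> human)."""

    pairs: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for k, v in self.pairs.items():
            if not v:
                raise ValueError(f"empty ortholog target for {k!r}")

    def get(self, gene: str) -> str | None:
        return self.pairs.get(gene)


# ---------------------------------------------------------------------------
# expression matrices


def read_expression_matrix(
    path_matrix: str | os.PathLike,
    path_metadata: str | os.PathLike,
    sep: str | None = None,
) -> ExpressionMatrix:
    """Read a delimited genes x samples matrix plus a sample metadata table.

    The metadata table must have ``sample_id`` and ``tissue`` columns; samples
    present in the matrix but absent from the metadata are an error.
    """
    values = pd.read_csv(path_matrix, sep=_sep_for(path_matrix, sep), index_col=0)
    values.index = values.index.astype(str)
    values.columns = values.columns.astype(str)
    if values.shape[1] == 0:
        raise ValueError("expression matrix has no sample columns")
    for col in values.columns:
        if not np.issubdtype(values[col].dtype, np.number):
            raise ValueError(f"non-numeric expression values in column {col!r}")
    meta = pd.read_csv(path_metadata, sep=_sep_for(path_metadata, sep))
    if not {"sample_id", "tissue"}.issubset(meta.columns):
        raise ValueError("metadata requires columns sample_id, tissue")
    _check_unique(meta["sample_id"].astype(str), "metadata sample")
    tissue = pd.Series(
        meta["tissue"].astype(str).values, index=meta["sample_id"].astype(str)
    )
    return ExpressionMatrix(values=values, sample_tissue=tissue)


def write_expression_matrix(
    em: ExpressionMatrix,
    path_matrix: str | os.PathLike,
    path_metadata: str | os.PathLike,
    sep: str | None = None,
) -> None:
    em.values.to_csv(path_matrix, sep=_sep_for(path_matrix, sep), index_label="gene_id")
    meta = pd.DataFrame(
        {"sample_id": em.sample_ids, "tissue": em.sample_tissue.values}
    )
    meta.to_csv(path_metadata, sep=_sep_for(path_metadata, sep), index=False)


# ---------------------------------------------------------------------------
# gene sets


def read_gmt(path: str | os.PathLike) -> list[GeneSet]:
    """Parse a GMT file: ``name<TAB>description<TAB>member...`` per line."""
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"GMT line {lineno}: fewer than 3 fields")
            name, _desc, *members = fields
            members = [m for m in members if m]
            if len(set(members)) < len(members):
                logger.warning("GMT set %r line %d: duplicate members collapsed", name, lineno)
            sets.append(GeneSet(name=name, members=frozenset(members)))
    return sets


def write_gmt(sets: Sequence[GeneSet], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, "na", *sorted(gs.members)]) + "\n")


def read_signed_sets(path: str | os.PathLike, sep: str | None = None) -> list[SignedGeneSet]:
    """Read signed sets from a (set, gene, weight) table, order preserved."""
    df = pd.read_csv(path, sep=_sep_for(path, sep))
    if not {"set", "gene", "weight"}.issubset(df.columns):
        raise ValueError("signed set table requires columns set, gene, weight")
    out = []
    for name in dict.fromkeys(df["set"]):
        sub = df[df["set"] == name]
        if sub["gene"].duplicated().any():
            raise ValueError(f"signed set {name!r} repeats a gene")
        out.append(SignedGeneSet(name=str(name), weights=dict(zip(sub["gene"], sub["weight"]))))
    return out


def write_signed_sets(sets: Sequence[SignedGeneSet], path: str | os.PathLike, sep: str | None = None) -> None:
    rows = [
        {"set": s.name, "gene": g, "weight": w}
        for s in sets
        for g, w in s.weights.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep=_sep_for(path, sep), index=False)


# ---------------------------------------------------------------------------
# single-cell counts


def _read_cell_meta(path_cell_meta: str | os.PathLike) -> pd.DataFrame:
    meta = pd.read_csv(path_cell_meta, sep=_sep_for(path_cell_meta))
    if not {"cell_id", "genotype", "cluster"}.issubset(meta.columns):
        raise ValueError("cell metadata requires columns cell_id, genotype, cluster")
    return meta.set_index(meta["cell_id"].astype(str))


def read_sc_counts(
    path_counts: str | os.PathLike,
    path_cell_meta: str | os.PathLike,
) -> SingleCellCounts:
    """Read UMI counts (MTX triplet with companions, or dense CSV) plus labels.

    For MTX, ``<stem>.barcodes.tsv`` and ``<stem>.features.tsv`` companions are
    expected next to the matrix (one id per line, file order = matrix order,
    1-based indices inside the MTX per the MatrixMarket standard).
    """
    path = str(path_counts)
    if path.endswith(".mtx"):
        mat = scipy.io.mmread(path)
        stem = path[: -len(".mtx")]
        with open(stem + ".barcodes.tsv") as fh:
            cells = [line.strip() for line in fh if line.strip()]
        with open(stem + ".features.tsv") as fh:
            genes = [line.strip() for line in fh if line.strip()]
        dense = np.asarray(mat.todense())
        if dense.shape != (len(cells), len(genes)):
            raise ValueError("MTX shape does not match barcodes/features")
    else:
        df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
        cells = [str(c) for c in df.index]
        genes = [str(g) for g in df.columns]
        dense = df.to_numpy()
    if not np.all(np.isfinite(dense)):
        raise ValueError("counts must be finite")
    as_int = np.round(dense).astype(np.int64)
    if not np.allclose(as_int, dense, rtol=0, atol=0):
        raise ValueError("counts must be non-negative integers")
    meta = _read_cell_meta(path_cell_meta)
    missing = set(cells) - set(meta.index)
    if missing:
        raise ValueError(f"cells missing metadata: {sorted(missing)[:5]}")
    meta = meta.loc[cells]
    return SingleCellCounts(
        counts=as_int,
        cell_ids=cells,
        gene_ids=genes,
        cell_genotype=meta["genotype"].astype(str),
        cell_cluster=meta["cluster"].astype(str),
    )


def write_sc_counts(
    sc: SingleCellCounts,
    path_counts: str | os.PathLike,
    path_cell_meta: str | os.PathLike,
) -> None:
    path = str(path_counts)
    if path.endswith(".mtx"):
        scipy.io.mmwrite(path, scipy.sparse.coo_matrix(sc.counts))
        stem = path[: -len(".mtx")]
        with open(stem + ".barcodes.tsv", "w") as fh:
            fh.write("\n".join(sc.cell_ids) + "\n")
        with open(stem + ".features.tsv", "w") as fh:
            fh.write("\n".join(sc.gene_ids) + "\n")
    else:
        pd.DataFrame(sc.counts, index=sc.cell_ids, columns=sc.gene_ids).to_csv(
            path, sep=_sep_for(path), index_label="cell_id"
        )
    meta = pd.DataFrame(
        {
            "cell_id": sc.cell_ids,
            "genotype": sc.cell_genotype.values,
            "cluster": sc.cell_cluster.values,
        }
    )
    meta.to_csv(path_cell_meta, sep=_sep_for(path_cell_meta), index=False)


# ---------------------------------------------------------------------------
# ortholog maps


def read_ortholog_map(path: str | os.PathLike, sep: str | None = None) -> OrthologMap:
    df = pd.read_csv(path, sep=_sep_for(path, sep), header=0)
    if df.shape[1] < 2:
        raise ValueError("ortholog map requires two columns (source, target)")
    src = df.iloc[:, 0].astype(str)
    tgt = df.iloc[:, 1].astype(str)
    _check_unique(src, "ortholog source")
    return OrthologMap(pairs=dict(zip(src, tgt)))


def write_ortholog_map(m: OrthologMap, path: str | os.PathLike, sep: str | None = None) -> None:
    pd.DataFrame(
        {"source": list(m.pairs), "target": list(m.pairs.values())}
    ).to_csv(path, sep=_sep_for(path, sep), index=False)
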