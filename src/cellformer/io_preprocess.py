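"""Expression-matrix I/O and the preprocessing pipeline.

Reads cell × gene expression data from h5ad, 10x MTX triplets or CSV,
applies fraction-based quality-control filtering, library-size
normalisation with log1p, binned-dispersion highly-variable-gene (HVG)
selection, and aligns the gene spaces of a reference and a query dataset
to their intersection.  Matrices travel through the pipeline inside
:class:`ExpressionMatrix`, which carries cell/gene identifiers and a
processing-stage tag enforcing the forward order
raw → filtered → normalized → hvg.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scanpy as sc
import scipy.sparse as sp

__all__ = [
    "ExpressionMatrix",
    "LabelSet",
    "read_expression",
    "write_expression",
    "qc_filter",
    "normalize_log",
    "select_hvg",
    "align_genes",
    "encode_labels",
    "DEFAULT_HVG_CAP",
]

_STAGES = ("raw", "filtered", "normalized", "hvg")

#: Default cap on the number of highly variable genes kept.  The selection
#: adapts to the matrix dimensionality: min(cap, genes surviving QC).
DEFAULT_HVG_CAP = 4000


@dataclass(frozen=True)
class ExpressionMatrix:
    """A cells × genes expression matrix with identifiers and a stage tag."""

    values: np.ndarray | sp.spmatrix
    cell_ids: tuple[str, ...]
    gene_ids: tuple[str, ...]
    stage: str = "raw"

    def __post_init__(self):
        n, g = self.values.shape
        if n != len(self.cell_ids) or g != len(self.gene_ids):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.cell_ids)} cells × {len(self.gene_ids)} genes"
            )
        if self.stage not in _STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        for name, ids in (("cell", self.cell_ids), ("gene", self.gene_ids)):
            if len(set(ids)) != len(ids):
                dupes = sorted({x for x in ids if list(ids).count(x) > 1})
                raise ValueError(f"duplicate {name} ids: {dupes[:10]}")
        if self.dense().size and self.dense().min() < 0:
            raise ValueError("expression values must be nonnegative")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def dense(self) -> np.ndarray:
        """Values as a dense float64 array."""
        if sp.issparse(self.values):
            return np.asarray(self.values.todense(), dtype=np.float64)
        return np.asarray(self.values, dtype=np.float64)

    def _advance(self, values, stage: str, gene_ids=None, cell_ids=None) -> "ExpressionMatrix":
        if _STAGES.index(stage) < _STAGES.index(self.stage):
            raise ValueError(f"stage may only move forward, not {self.stage}→{stage}")
        return ExpressionMatrix(
            values=values,
            cell_ids=cell_ids if cell_ids is not None else self.cell_ids,
            gene_ids=gene_ids if gene_ids is not None else self.gene_ids,
            stage=stage,
        )


@dataclass(frozen=True)
class LabelSet:
    """Per-cell categorical labels with a fixed vocabulary and integer codes."""

    labels: tuple[str, ...]
    vocabulary: tuple[str, ...]
    codes: np.ndarray = field(compare=False)

    def __post_init__(self):
        if len(self.labels) != len(self.codes):
            raise ValueError("labels and codes length mismatch")
        lut = {name: i for i, name in enumerate(self.vocabulary)}
        expected = np.array([lut[x] for x in self.labels], dtype=np.int64)
        if not np.array_equal(expected, np.asarray(self.codes)):
            raise ValueError("codes inconsistent with vocabulary order")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def n_classes(self) -> int:
        return len(self.vocabulary)

    def subset(self, idx: np.ndarray) -> "LabelSet":
        labels = tuple(self.labels[i] for i in np.asarray(idx))
        return LabelSet(labels, self.vocabulary, np.asarray(self.codes)[idx])


def encode_labels(
    labels: Sequence[str], reference_vocabulary: Optional[Sequence[str]] = None
) -> LabelSet:
    """Encode string labels against a sorted (or supplied) vocabulary.

    Raises ``ValueError`` naming any label absent from a supplied
    reference vocabulary, so query datasets cannot silently introduce
    classes the model never saw.
    """
    labels = tuple(str(x) for x in labels)
    if reference_vocabulary is None:
        vocab = tuple(sorted(set(labels)))
    else:
        vocab = tuple(reference_vocabulary)
        unseen = sorted(set(labels) - set(vocab))
        if unseen:
            raise ValueError(f"labels not in reference vocabulary: {unseen}")
    lut = {name: i for i, name in enumerate(vocab)}
    codes = np.array([lut[x] for x in labels], dtype=np.int64)
    return LabelSet(labels, vocab, codes)


# ---------------------------------------------------------------------------
# Reading / writing


def read_expression(
    path: str | os.PathLike,
    format: str,
    label_key: Optional[str] = None,
) -> tuple[ExpressionMatrix, Optional[LabelSet]]:
    """Read an expression matrix (stage=raw) and, if present, its labels.

    Parameters
    ----------
    path
        File (h5ad, csv) or directory (mtx triplet) to read.
    format
        One of ``h5ad``, ``mtx``, ``csv``.
    label_key
        Per-cell column holding labels (h5ad ``obs`` column or CSV column).
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if format == "h5ad":
        adata = ad.read_h5ad(path)
        labels = None
        if label_key is not None and label_key in adata.obs:
            labels = encode_labels([str(x) for x in adata.obs[label_key]])
        x = ExpressionMatrix(
            values=adata.X.copy() if sp.issparse(adata.X) else np.asarray(adata.X),
            cell_ids=tuple(map(str, adata.obs_names)),
            gene_ids=tuple(map(str, adata.var_names)),
            stage="raw",
        )
        return x, labels
    if format == "mtx":
        if os.path.exists(os.path.join(path, "genes.tsv")) or os.path.exists(
            os.path.join(path, "features.tsv.gz")
        ):
            adata = sc.read_10x_mtx(path, var_names="gene_ids")
            values = adata.X.copy()
            cell_ids = tuple(map(str, adata.obs_names))
            gene_ids = tuple(map(str, adata.var_names))
        else:
            # plain triplet with an uncompressed features.tsv
            import scipy.io as sio

            mat = sio.mmread(os.path.join(path, "matrix.mtx")).tocsr().T  # cells × genes
            feats = pd.read_csv(
                os.path.join(path, "features.tsv"), sep="\t", header=None
            )
            codes = pd.read_csv(
                os.path.join(path, "barcodes.tsv"), sep="\t", header=None
            )
            values = mat
            cell_ids = tuple(map(str, codes[0]))
            gene_ids = tuple(map(str, feats[0]))
        x = ExpressionMatrix(
            values=values, cell_ids=cell_ids, gene_ids=gene_ids, stage="raw"
        )
        return x, None
    if format == "csv":
        try:
            df = pd.read_csv(path, index_col=0)
        except Exception as exc:  # pragma: no cover - message wrapping
            raise ValueError(f"malformed CSV {path}: {exc}") from exc
        labels = None
        if label_key is not None and label_key in df.columns:
            labels = encode_labels([str(x) for x in df[label_key]])
            df = df.drop(columns=[label_key])
        x = ExpressionMatrix(
            values=df.to_numpy(dtype=np.float64),
            cell_ids=tuple(map(str, df.index)),
            gene_ids=tuple(map(str, df.columns)),
            stage="raw",
        )
        return x, labels
    raise ValueError(f"unknown format {format!r}; expected h5ad, mtx or csv")


def write_expression(
    x: ExpressionMatrix,
    path: str | os.PathLike,
    format: str = "h5ad",
    labels: Optional[LabelSet] = None,
    label_key: str = "cell_type",
) -> None:
    """Write an expression matrix (and optional labels) to h5ad or CSV."""
    path = os.fspath(path)
    if format == "h5ad":
        adata = to_anndata(x, labels, label_key)
        adata.write_h5ad(path)
    elif format == "csv":
        df = pd.DataFrame(x.dense(), index=list(x.cell_ids), columns=list(x.gene_ids))
        if labels is not None:
            df[label_key] = list(labels.labels)
        df.to_csv(path)
    else:
        raise ValueError(f"unknown format {format!r}")


def to_anndata(
    x: ExpressionMatrix, labels: Optional[LabelSet] = None, label_key: str = "cell_type"
) -> ad.AnnData:
    adata = ad.AnnData(
        X=x.values.copy() if sp.issparse(x.values) else np.asarray(x.values, dtype=np.float64),
        obs=pd.DataFrame(index=pd.Index(list(x.cell_ids), name="cell_id")),
        var=pd.DataFrame(index=pd.Index(list(x.gene_ids), name="gene_id")),
    )
    adata.uns["stage"] = x.stage
    if labels is not None:
        adata.obs[label_key] = pd.Categorical(
            list(labels.labels), categories=list(labels.vocabulary)
        )
    return adata


# ---------------------------------------------------------------------------
# Pipeline steps


def qc_filter(
    x: ExpressionMatrix,
    min_cell_frac: float = 0.01,
    min_gene_frac: float = 0.01,
) -> ExpressionMatrix:
    """Drop genes expressed in ≤ ``min_cell_frac`` of cells, then cells
    expressed in ≤ ``min_gene_frac`` of the remaining genes.

    Both thresholds are strict: a gene survives only if its nonzero
    fraction strictly exceeds ``min_cell_frac``.  Gene filtering runs
    first; cell fractions are recomputed on the kept genes.
    """
    if x.stage != "raw" and x.stage != "filtered":
        raise ValueError(f"qc_filter expects raw input, got stage={x.stage}")
    dense = x.dense()
    n, g = dense.shape
    gene_frac = (dense > 0).sum(axis=0) / n
    keep_genes = gene_frac > min_cell_frac
    if not keep_genes.any():
        raise ValueError("empty after QC: no gene passes the cell-fraction filter")
    dense = dense[:, keep_genes]
    cell_frac = (dense > 0).sum(axis=1) / dense.shape[1]
    keep_cells = cell_frac > min_gene_frac
    if not keep_cells.any():
        raise ValueError("empty after QC: no cell passes the gene-fraction filter")
    return x._advance(
        dense[keep_cells],
        "filtered",
        gene_ids=tuple(gid for gid, k in zip(x.gene_ids, keep_genes) if k),
        cell_ids=tuple(cid for cid, k in zip(x.cell_ids, keep_cells) if k),
    )


def normalize_log(x: ExpressionMatrix, target_sum: float = 1e4) -> ExpressionMatrix:
    """Scale each cell to ``target_sum`` total counts, then apply log1p.

    Uses scanpy's normalize_total/log1p; all-zero cells stay zero.
    """
    if x.stage != "filtered":
        raise ValueError(f"normalize_log expects filtered input, got stage={x.stage}")
    dense = x.dense()
    if dense.size and dense.min() < 0:
        raise ValueError("negative expression value")
    adata = ad.AnnData(X=dense)
    sc.pp.normalize_total(adata, target_sum=target_sum)
    sc.pp.log1p(adata)
    return x._advance(np.asarray(adata.X, dtype=np.float64), "normalized")


def _binned_dispersion(values: np.ndarray, n_bins: int = 20) -> np.ndarray:
    """Per-gene dispersion: variance of log-normalised expression,
    standardised within ``n_bins`` mean-expression bins."""
    mean = values.mean(axis=0)
    var = values.var(axis=0, ddof=1) if values.shape[0] > 1 else np.zeros(values.shape[1])
    bins = pd.cut(mean, bins=n_bins, labels=False, duplicates="drop")
    if np.isscalar(bins) or bins is None:  # degenerate: all means identical
        bins = np.zeros(values.shape[1], dtype=int)
    bins = np.asarray(bins)
    disp = np.zeros_like(var)
    for b in np.unique(bins):
        mask = bins == b
        mu, sd = var[mask].mean(), var[mask].std(ddof=0)
        disp[mask] = (var[mask] - mu) / sd if sd > 0 else 0.0
    # constant genes can never outrank varying ones
    disp[var == 0] = -np.inf
    return disp


def select_hvg(
    x: ExpressionMatrix, n_top: int
) -> tuple[ExpressionMatrix, np.ndarray]:
    """Keep the ``n_top`` most variable genes by binned normalized dispersion.

    Returns the reduced matrix (stage=hvg, original column order preserved)
    and the strictly increasing indices of the kept genes.
    """
    if x.stage != "normalized":
        raise ValueError(f"select_hvg expects normalized input, got stage={x.stage}")
    if n_top <= 0:
        raise ValueError("n_top must be positive")
    dense = x.dense()
    g = dense.shape[1]
    n_top = min(n_top, g)
    disp = _binned_dispersion(dense)
    # stable selection: rank by (-dispersion, gene index)
    order = np.lexsort((np.arange(g), -disp))
    kept = np.sort(order[:n_top])
    out = x._advance(
        dense[:, kept], "hvg", gene_ids=tuple(x.gene_ids[i] for i in kept)
    )
    return out, kept


def align_genes(
    reference: ExpressionMatrix, query: ExpressionMatrix
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Restrict both matrices to their shared genes, in reference order."""
    for m, name in ((reference, "reference"), (query, "query")):
        if m.stage not in ("filtered", "normalized"):
            raise ValueError(f"{name} stage must be filtered or normalized, got {m.stage}")
    shared = [g for g in reference.gene_ids if g in set(query.gene_ids)]
    if not shared:
        raise ValueError("no shared genes between reference and query")
    ref_pos = {g: i for i, g in enumerate(reference.gene_ids)}
    qry_pos = {g: i for i, g in enumerate(query.gene_ids)}
    ridx = np.array([ref_pos[g] for g in shared])
    qidx = np.array([qry_pos[g] for g in shared])
    ref_out = ExpressionMatrix(
        reference.dense()[:, ridx], reference.cell_ids, tuple(shared), reference.stage
    )
    qry_out = ExpressionMatrix(
        query.dense()[:, qidx], query.cell_ids, tuple(shared), query.stage
    )
    return ref_out, qry_out


def preprocess(
    x: ExpressionMatrix,
    n_hvg: int = DEFAULT_HVG_CAP,
    target_sum: float = 1e4,
    min_cell_frac: float = 0.01,
    min_gene_frac: float = 0.01,
) -> tuple[ExpressionMatrix, np.ndarray]:
    """QC → normalize → HVG in one call; returns (hvg matrix, kept gene idx)."""
    filtered = qc_filter(x, min_cell_frac, min_gene_frac)
    normalized = normalize_log(filtered, target_sum)
    return select_hvg(normalized, n_top=min(n_hvg, normalized.n_genes))
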