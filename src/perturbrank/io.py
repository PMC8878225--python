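"""Expression-matrix containers, GCT/TSV readers and writers, consensus
signatures, and gene-space harmonization.

The central container is :class:`ExpressionMatrix`: perturbation (or drug)
identifiers on the rows, gene identifiers on the columns, continuous
differential-expression values in the cells, plus optional per-row metadata
(the gene symbol targeted by a perturbation and its type, OE or KD).

Gene identifiers are opaque, case-sensitive strings; no symbol-alias
resolution is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "read_expression_matrix",
    "write_expression_matrix",
    "consensus_signature",
    "harmonize_genes",
    "read_labels",
    "read_target_scores",
    "write_labels",
    "write_target_scores",
]


def _check_unique(ids: Iterable[str], what: str) -> None:
    seen = pd.Index(ids)
    if seen.has_duplicates:
        dup = seen[seen.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what} id(s): {dup}")


@dataclass
class ExpressionMatrix:
    """A (perturbations x genes) matrix of differential-expression values.

    Parameters
    ----------
    data:
        DataFrame with perturbation/drug ids on the index and gene ids on
        the columns. Values must be finite floats.
    meta:
        Optional per-row metadata aligned to ``data.index`` (e.g. columns
        ``gene_symbol`` and ``pert_type``).
    """

    data: pd.DataFrame
    meta: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        self.data = self.data.astype(float)
        self.data.index = self.data.index.astype(str)
        self.data.columns = self.data.columns.astype(str)
        self.data.index.name = None
        self.data.columns.name = None
        _check_unique(self.data.index, "row")
        _check_unique(self.data.columns, "column")
        values = self.data.to_numpy()
        if not np.isfinite(values).all():
            r, c = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                f"non-finite value at row {self.data.index[r]!r}, "
                f"column {self.data.columns[c]!r}"
            )
        if self.meta is not None:
            self.meta = self.meta.copy()
            self.meta.index = self.meta.index.astype(str)
            if not self.meta.index.equals(self.data.index):
                self.meta = self.meta.reindex(self.data.index)

    @property
    def row_ids(self) -> pd.Index:
        return self.data.index

    @property
    def col_ids(self) -> pd.Index:
        return self.data.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def restrict_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        """Return a copy restricted to ``genes`` in the given order."""
        return ExpressionMatrix(self.data.loc[:, list(genes)].copy(),
                                None if self.meta is None else self.meta.copy())

    def equals(self, other: "ExpressionMatrix") -> bool:
        same = self.data.equals(other.data)
        if self.meta is None or other.meta is None:
            return same and self.meta is None and other.meta is None
        return same and self.meta.equals(other.meta)


# ---------------------------------------------------------------------------
# GCT v1.3 / TSV
# ---------------------------------------------------------------------------

def _parse_float(token: str, row_id: str, col_id: str) -> float:
    try:
        return float(token)
    except ValueError:
        raise ValueError(
            f"non-numeric cell at row {row_id!r}, column {col_id!r}: {token!r}"
        ) from None


def _read_gct(path: Path) -> ExpressionMatrix:
    with open(path, "r", encoding="utf-8") as fh:
        version = fh.readline().strip()
        if version != "#1.3":
            raise ValueError(f"{path}: expected GCT version header '#1.3', got {version!r}")
        dims = fh.readline().strip().split("\t")
        if len(dims) < 2:
            raise ValueError(f"{path}: malformed GCT dimension line")
        n_rows, n_cols = int(dims[0]), int(dims[1])
        n_rmeta = int(dims[2]) if len(dims) > 2 else 0
        n_cmeta = int(dims[3]) if len(dims) > 3 else 0
        header = fh.readline().rstrip("\n").split("\t")
        rmeta_names = header[1 : 1 + n_rmeta]
        col_ids = header[1 + n_rmeta :]
        if len(col_ids) != n_cols:
            raise ValueError(f"{path}: header declares {len(col_ids)} columns, expected {n_cols}")
        for _ in range(n_cmeta):  # column metadata rows are not modelled
            fh.readline()
        row_ids, meta_rows, data_rows = [], [], []
        for _ in range(n_rows):
            parts = fh.readline().rstrip("\n").split("\t")
            row_ids.append(parts[0])
            meta_rows.append(parts[1 : 1 + n_rmeta])
            data_rows.append(
                [_parse_float(tok, parts[0], col)
                 for tok, col in zip(parts[1 + n_rmeta :], col_ids)]
            )
    data = pd.DataFrame(data_rows, index=row_ids, columns=col_ids)
    meta = None
    if n_rmeta:
        meta = pd.DataFrame(meta_rows, index=row_ids, columns=rmeta_names)
    return ExpressionMatrix(data, meta)


def _read_tsv_matrix(path: Path) -> ExpressionMatrix:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    _check_unique(header, "column")  # pandas would silently de-duplicate
    raw = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str, comment=None)
    _check_unique(raw.index.astype(str), "row")
    try:
        data = raw.astype(float)
    except ValueError:
        # slow path only to report the offending cell's coordinates
        for col in raw.columns:
            for rid, tok in raw[col].items():
                _parse_float(tok, str(rid), col)
        raise
    data.index = data.index.astype(str)
    return ExpressionMatrix(data)


def read_expression_matrix(path: str | Path, format: str | None = None) -> ExpressionMatrix:
    """Read an :class:`ExpressionMatrix` from a GCT v1.3 or TSV file.

    ``format`` is ``"gct"`` or ``"tsv"``; when omitted it is inferred from
    the file extension. The TSV dialect is a header row of gene ids with
    row ids in the first column.
    """
    path = Path(path)
    if format is None:
        format = "gct" if path.suffix.lower() == ".gct" else "tsv"
    if format == "gct":
        return _read_gct(path)
    if format == "tsv":
        return _read_tsv_matrix(path)
    raise ValueError(f"unknown format {format!r} (expected 'gct' or 'tsv')")


def write_expression_matrix(mat: ExpressionMatrix, path: str | Path,
                            format: str | None = None) -> None:
    """Write a matrix as GCT v1.3 (row metadata preserved) or plain TSV."""
    path = Path(path)
    if format is None:
        format = "gct" if path.suffix.lower() == ".gct" else "tsv"
    if format == "tsv":
        mat.data.to_csv(path, sep="\t", index_label="id")
        return
    if format != "gct":
        raise ValueError(f"unknown format {format!r} (expected 'gct' or 'tsv')")
    meta = mat.meta
    rmeta_names = [] if meta is None else list(meta.columns)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#1.3\n")
        fh.write(f"{mat.shape[0]}\t{mat.shape[1]}\t{len(rmeta_names)}\t0\n")
        fh.write("\t".join(["id", *rmeta_names, *mat.col_ids]) + "\n")
        for rid in mat.row_ids:
            fields = [rid]
            if meta is not None:
                fields.extend(str(meta.at[rid, name]) for name in rmeta_names)
            fields.extend(repr(float(v)) for v in mat.data.loc[rid].to_numpy())
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Consensus signatures
# ---------------------------------------------------------------------------

def consensus_signature(replicates: Sequence[np.ndarray],
                        return_weights: bool = False):
    """Collapse replicate signatures into one consensus signature.

    Each replicate is weighted by its mean Spearman correlation with the
    other replicates; negative mean correlations are clipped to zero
    (discordant replicates contribute nothing), weights are renormalized to
    sum to one, and the consensus is the weighted elementwise average. If
    every clipped weight is zero the replicates are equally weighted.
    """
    reps = [np.asarray(r, dtype=float) for r in replicates]
    if len(reps) < 2:
        raise ValueError("consensus requires at least 2 replicates")
    length = reps[0].size
    if any(r.ndim != 1 or r.size != length for r in reps):
        raise ValueError("replicates must be 1-D vectors of equal length")
    if length < 3:
        raise ValueError("replicates must have length >= 3 for Spearman weighting")
    n = len(reps)
    corr = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            rho = stats.spearmanr(reps[i], reps[j]).statistic
            if np.isnan(rho):  # constant replicate: no rank information
                rho = 0.0
            corr[i, j] = corr[j, i] = rho
    mean_corr = (corr.sum(axis=1) - 1.0) / (n - 1)
    weights = np.clip(mean_corr, 0.0, None)
    if weights.sum() == 0:
        weights = np.full(n, 1.0 / n)
    else:
        weights = weights / weights.sum()
    consensus = np.einsum("i,ij->j", weights, np.vstack(reps))
    if return_weights:
        return consensus, weights
    return consensus


# ---------------------------------------------------------------------------
# Gene-space harmonization
# ---------------------------------------------------------------------------

def harmonize_genes(*matrices: ExpressionMatrix) -> tuple[ExpressionMatrix, ...]:
    """Restrict two or more matrices to their common genes.

    The intersection is taken across all arguments and every output carries
    the shared genes in lexicographic order, so that models trained on one
    matrix can be applied to the others column-for-column. Row sets are
    unchanged.
    """
    if len(matrices) < 2:
        raise ValueError("harmonize_genes needs at least two matrices")
    common: set[str] = set(matrices[0].col_ids)
    for m in matrices[1:]:
        common &= set(m.col_ids)
    if not common:
        raise ValueError("empty gene intersection: incompatible gene universes")
    order = sorted(common)
    return tuple(m.restrict_genes(order) for m in matrices)


# ---------------------------------------------------------------------------
# Label and score tables
# ---------------------------------------------------------------------------

def read_labels(path: str | Path,
                matrix: ExpressionMatrix | None = None) -> pd.Series:
    """Read binary indication labels (TSV columns ``drug_id``, ``label``).

    Labels must be 0 or 1. When ``matrix`` is given, drugs absent from the
    matrix are dropped with a logged warning.
    """
    df = pd.read_csv(path, sep="\t", dtype={"drug_id": str}, comment="#")
    if not {"drug_id", "label"}.issubset(df.columns):
        raise ValueError(f"{path}: expected columns 'drug_id' and 'label'")
    _check_unique(df["drug_id"], "drug")
    labels = pd.to_numeric(df["label"], errors="raise")
    bad = labels[~labels.isin([0, 1])]
    if len(bad):
        raise ValueError(f"labels must be 0 or 1; offending value(s): {bad.tolist()}")
    out = pd.Series(labels.astype(int).to_numpy(), index=df["drug_id"], name="label")
    if matrix is not None:
        missing = out.index.difference(matrix.row_ids)
        if len(missing):
            logger.warning("dropping %d labelled drug(s) absent from the matrix: %s",
                           len(missing), list(missing))
            out = out.drop(missing)
    return out


def write_labels(labels: pd.Series, path: str | Path) -> None:
    labels.rename("label").rename_axis("drug_id").to_frame().to_csv(path, sep="\t")


def read_target_scores(path: str | Path) -> pd.Series:
    """Read a gene -> relevance-score table (TSV columns ``gene``, ``score``).

    Scores must lie in [0, 1] inclusive, one per gene.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene": str}, comment="#")
    if not {"gene", "score"}.issubset(df.columns):
        raise ValueError(f"{path}: expected columns 'gene' and 'score'")
    _check_unique(df["gene"], "gene")
    scores = pd.to_numeric(df["score"], errors="raise").astype(float)
    bad = scores[(scores < 0) | (scores > 1)]
    if len(bad):
        raise ValueError(f"scores must lie in [0, 1]; offending value(s): {bad.tolist()}")
    return pd.Series(scores.to_numpy(), index=df["gene"], name="score")


def write_target_scores(scores: pd.Series, path: str | Path) -> None:
    scores.rename("score").rename_axis("gene").to_frame().to_csv(path, sep="\t")
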