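"""Transfer fitted drug classifiers to perturbation profiles.

``predict_perturbations`` applies each trained classifier (and optionally
the ensemble) to an OE/KD expression matrix, yielding one treatment-
potential probability per perturbation per method. ``rank_targets`` turns
a prediction table into top/bottom target calls with direction of
regulation: a high probability after overexpression means upregulating
the gene mimics disease-treating drugs; a high probability after
knockdown means *down*regulating it does (and conversely at the bottom of
the ranking).
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import ExpressionMatrix
from .train import METHODS, TrainedModelBundle, EnsembleModel

logger = logging.getLogger(__name__)

__all__ = ["predict_perturbations", "rank_targets", "model_correlations",
           "gene_probabilities"]


def predict_perturbations(bundles: Mapping[str, TrainedModelBundle],
                          pert_mat: ExpressionMatrix,
                          ensemble: EnsembleModel | None = None) -> pd.DataFrame:
    """Score every perturbation with every trained method.

    Returns a DataFrame indexed by perturbation id with columns ``gene``,
    ``pert_type``, one probability column per method, and ``ensemble``
    when an ensemble model is supplied. The perturbation matrix must
    already share the training gene space (same columns, same order).
    """
    if not bundles:
        raise ValueError("no trained bundles supplied")
    methods = tuple(m for m in METHODS if m in bundles) or tuple(bundles)
    table = pd.DataFrame(index=pert_mat.row_ids.copy())
    meta = pert_mat.meta
    if meta is not None and "gene_symbol" in meta.columns:
        table["gene"] = meta["gene_symbol"]
    else:
        table["gene"] = table.index
    if meta is not None and "pert_type" in meta.columns:
        table["pert_type"] = meta["pert_type"]
    else:
        table["pert_type"] = "OE"
    for m in methods:
        table[m] = bundles[m].predict_matrix(pert_mat.data)
    if ensemble is not None:
        table["ensemble"] = ensemble.predict(table[list(ensemble.methods)])
    return table


def _require_single_type(table: pd.DataFrame, pert_type: str | None) -> pd.DataFrame:
    if pert_type is not None:
        sub = table[table["pert_type"] == pert_type]
        if sub.empty:
            raise ValueError(f"no rows of perturbation type {pert_type!r}")
        return sub
    types = table["pert_type"].unique()
    if len(types) > 1:
        raise ValueError("mixed perturbation types; pass pert_type='OE' or 'KD'")
    return table


def rank_targets(table: pd.DataFrame, k: int, method: str,
                 pert_type: str | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Top-k and bottom-k target calls for one method and perturbation type.

    Probability ties are broken by gene identifier so published lists are
    reproducible. The per-type median probability is attached for context
    (``median_ref``), since "lower than expected" is defined relative to
    the ranking, not an absolute cutoff.
    """
    sub = _require_single_type(table, pert_type)
    if method not in sub.columns:
        raise ValueError(f"no probability column for method {method!r}")
    if k > len(sub) // 2:
        raise ValueError(f"k={k} too large for {len(sub)} perturbations (need k <= n/2)")
    ptype = sub["pert_type"].iloc[0]
    ordered = sub.sort_values([method, "gene"], ascending=[False, True])
    median_ref = float(sub[method].median())

    def _calls(rows: pd.DataFrame, high_end: bool) -> pd.DataFrame:
        if ptype == "OE":
            direction = "up" if high_end else "down"
        else:  # knockdown flips the direction of regulation
            direction = "down" if high_end else "up"
        out = rows[["gene", method]].rename(columns={method: "p_hat"}).copy()
        out["pert_type"] = ptype
        out["direction"] = direction
        out["rank"] = (np.arange(1, len(out) + 1) if high_end
                       else np.arange(len(sub), len(sub) - len(out), -1))
        out["median_ref"] = median_ref
        return out.reset_index(names="perturbation")

    top = _calls(ordered.head(k), high_end=True)
    bottom = _calls(ordered.tail(k).iloc[::-1], high_end=False)
    return top, bottom


def gene_probabilities(table: pd.DataFrame, method: str,
                       pert_type: str | None = None) -> pd.Series:
    """Collapse a prediction table to one probability per gene (mean over
    replicate perturbations of the same gene)."""
    sub = _require_single_type(table, pert_type)
    if method not in sub.columns:
        raise ValueError(f"no probability column for method {method!r}")
    return sub.groupby("gene")[method].mean()


def model_correlations(table: pd.DataFrame,
                       methods: Sequence[str] | None = None
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson and Spearman correlations of the probability columns.

    Pairs involving a constant column are reported as NaN with a logged
    warning rather than raising.
    """
    if methods is None:
        methods = [c for c in table.columns
                   if c in (*METHODS, "ensemble") and pd.api.types.is_numeric_dtype(table[c])]
    if len(methods) < 2:
        raise ValueError("need at least two probability columns")
    if len(table) < 3:
        raise ValueError("need at least three perturbations")
    probs = table[list(methods)]
    constant = [m for m in methods if probs[m].nunique() <= 1]
    if constant:
        logger.warning("constant probability column(s), correlations undefined: %s",
                       constant)
    pearson = probs.corr(method="pearson")
    spearman = probs.corr(method="spearman")
    for mat in (pearson, spearman):
        np.fill_diagonal(mat.values, 1.0)
        for m in constant:
            mat.loc[m, [c for c in methods if c != m]] = np.nan
            mat.loc[[c for c in methods if c != m], m] = np.nan
    return pearson, spearman
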