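"""Validate target rankings against an external relevance-score table.

Following the gene-set logic of MAGMA's competitive test, genes whose
relevance score exceeds a cutoff form the "valid" target set, and a
two-tailed Welch t-test compares the mean predicted treatment-potential
probability inside the set against the genes outside it. The cutoff is
swept from 1 down to 0 in steps of 0.2 to avoid committing to one
arbitrary threshold, and Benjamini-Hochberg FDR corrects across the
sweep (all cutoffs and methods of one run, per perturbation type).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

DEFAULT_CUTOFFS = (1.0, 0.8, 0.6, 0.4, 0.2, 0.0)

__all__ = ["DEFAULT_CUTOFFS", "EnrichmentResult", "valid_target_set",
           "enrichment_test", "threshold_sweep", "sweep_methods", "bh_fdr"]


@dataclass
class EnrichmentResult:
    """One competitive enrichment test at one relevance-score cutoff."""

    cutoff: float
    n_in: int
    n_out: int
    mean_in: float
    mean_out: float
    t: float
    p: float
    q: float = field(default=np.nan)
    testable: bool = True
    note: str = ""

    def as_dict(self) -> dict:
        return {"cutoff": self.cutoff, "n_in": self.n_in, "n_out": self.n_out,
                "mean_in": self.mean_in, "mean_out": self.mean_out,
                "t": self.t, "p": self.p, "q": self.q,
                "testable": self.testable, "note": self.note}


def valid_target_set(scores: pd.Series, cutoff: float) -> set[str]:
    """Genes counted as 'valid' targets at a cutoff.

    Inclusion is strict (score > cutoff) except at the maximal cutoff 1,
    where genes scoring exactly 1 are included — a strict rule at 1 would
    always yield an empty set and make the top of the sweep vacuous.
    """
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError(f"cutoff must lie in [0, 1], got {cutoff}")
    if cutoff == 1.0:
        mask = scores >= 1.0
    else:
        mask = scores > cutoff
    return set(scores.index[mask])


def enrichment_test(predprobs: pd.Series, target_set: Iterable[str],
                    cutoff: float = np.nan,
                    equal_var: bool = False) -> EnrichmentResult:
    """Welch (default) two-tailed t-test of mean probability, in-set vs out.

    Genes named in the target set but absent from ``predprobs`` are
    ignored (counted in the log). Degenerate variance cases never raise:
    zero variance in both groups with equal means gives t=0, p=1; with
    unequal means the smallest positive p is reported and flagged.
    """
    target_set = set(target_set)
    missing = target_set - set(predprobs.index)
    if missing:
        logger.info("%d target(s) absent from the prediction table ignored", len(missing))
        target_set -= missing
    in_mask = predprobs.index.isin(target_set)
    x = predprobs.to_numpy()[in_mask]
    y = predprobs.to_numpy()[~in_mask]
    n_in, n_out = x.size, y.size
    if n_in < 2 or n_out < 2:
        return EnrichmentResult(cutoff, n_in, n_out,
                                float(np.mean(x)) if n_in else np.nan,
                                float(np.mean(y)) if n_out else np.nan,
                                np.nan, np.nan, testable=False,
                                note="group with < 2 members")
    mean_in, mean_out = float(x.mean()), float(y.mean())
    if x.var(ddof=1) == 0.0 and y.var(ddof=1) == 0.0:
        if mean_in == mean_out:
            return EnrichmentResult(cutoff, n_in, n_out, mean_in, mean_out, 0.0, 1.0)
        tiny = float(np.nextafter(0.0, 1.0))
        t_val = np.inf if mean_in > mean_out else -np.inf
        return EnrichmentResult(cutoff, n_in, n_out, mean_in, mean_out,
                                t_val, tiny, note="degenerate: zero variance")
    res = stats.ttest_ind(x, y, equal_var=equal_var)
    return EnrichmentResult(cutoff, n_in, n_out, mean_in, mean_out,
                            float(res.statistic), float(res.pvalue))


def threshold_sweep(predprobs: pd.Series, scores: pd.Series,
                    cutoffs: Sequence[float] = DEFAULT_CUTOFFS,
                    equal_var: bool = False) -> list[EnrichmentResult]:
    """One enrichment test per cutoff for a single method's probabilities.

    Only genes present in both tables participate; q-values are left NaN
    here and filled by the caller once the FDR pool is assembled.
    """
    cut = [float(c) for c in cutoffs]
    if any(not 0.0 <= c <= 1.0 for c in cut):
        raise ValueError("cutoffs must lie in [0, 1]")
    if any(b >= a for a, b in zip(cut, cut[1:])):
        raise ValueError("cutoffs must be strictly decreasing")
    scores = scores[scores.index.isin(predprobs.index)]
    results = []
    for c in cut:
        results.append(enrichment_test(predprobs, valid_target_set(scores, c),
                                       cutoff=c, equal_var=equal_var))
    return results


def bh_fdr(pvalues: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, order-preserving)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def sweep_methods(table: pd.DataFrame, scores: pd.Series,
                  methods: Sequence[str],
                  cutoffs: Sequence[float] = DEFAULT_CUTOFFS,
                  pert_type: str | None = None,
                  equal_var: bool = False,
                  fdr_pool: str = "per-run") -> pd.DataFrame:
    """Sweep every method, pool the testable p-values, attach q-values.

    ``table`` is a prediction table (see
    :func:`perturbrank.score.predict_perturbations`); probabilities are
    collapsed to one value per gene first. ``fdr_pool`` is ``"per-run"``
    (all methods and cutoffs corrected together, the default) or
    ``"per-method"``.
    """
    from .score import gene_probabilities

    rows = []
    for m in methods:
        probs = gene_probabilities(table, m, pert_type=pert_type)
        for res in threshold_sweep(probs, scores, cutoffs, equal_var=equal_var):
            row = res.as_dict()
            row["method"] = m
            rows.append(row)
    out = pd.DataFrame(rows)
    out["q"] = np.nan
    if fdr_pool not in ("per-run", "per-method"):
        raise ValueError("fdr_pool must be 'per-run' or 'per-method'")
    groups = [out.index[out["testable"]]] if fdr_pool == "per-run" else \
        [out.index[out["testable"] & (out["method"] == m)] for m in methods]
    for idx in groups:
        if len(idx):
            out.loc[idx, "q"] = bh_fdr(out.loc[idx, "p"].to_numpy())
    return out
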