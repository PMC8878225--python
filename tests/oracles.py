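"""Independent brute-force implementations used only as test oracles.

Each function recomputes a statistic from first principles (pair counting,
explicit enumeration, closed forms) without touching the library code
paths it is used to check.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def roc_auc_pairs(scores, labels) -> float:
    """ROC-AUC by exhaustive positive/negative pair counting; ties count 1/2."""
    s = np.asarray(scores, float)
    y = np.asarray(labels)
    pos = s[y == 1]
    neg = s[y == 0]
    total = 0.0
    for a in pos:
        for b in neg:
            if a > b:
                total += 1.0
            elif a == b:
                total += 0.5
    return total / (len(pos) * len(neg))


def average_precision_enum(scores, labels) -> float:
    """Average precision by explicit precision-recall enumeration over
    distinct thresholds in descending order (step-wise integral)."""
    s = np.asarray(scores, float)
    y = np.asarray(labels)
    n_pos = int((y == 1).sum())
    thresholds = np.unique(s)[::-1]
    ap, prev_recall = 0.0, 0.0
    for t in thresholds:
        called = s >= t
        tp = int(((y == 1) & called).sum())
        precision = tp / called.sum()
        recall = tp / n_pos
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap


def welch_ttest(x, y) -> tuple[float, float]:
    """Welch two-sample t and two-tailed p from the closed-form formulas
    (means, unbiased variances, Welch-Satterthwaite degrees of freedom)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    nx, ny = len(x), len(y)
    mx, my = x.mean(), y.mean()
    vx = ((x - mx) ** 2).sum() / (nx - 1)
    vy = ((y - my) ** 2).sum() / (ny - 1)
    se2 = vx / nx + vy / ny
    t = (mx - my) / np.sqrt(se2)
    df = se2 ** 2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return t, p


def bh_stepup(pvalues) -> np.ndarray:
    """Benjamini-Hochberg q-values by the step-up formula computed by hand:
    q_(i) = min_{j >= i} p_(j) * n / j over the ascending order."""
    p = np.asarray(pvalues, float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    q_sorted = np.empty(n)
    running = np.inf
    for i in range(n - 1, -1, -1):
        running = min(running, p[order[i]] * n / (i + 1))
        q_sorted[i] = min(running, 1.0)
    q = np.empty(n)
    q[order] = q_sorted
    return q


def _average_ranks(v: np.ndarray) -> np.ndarray:
    """1-based ranks with ties sharing their average rank."""
    order = np.argsort(v, kind="mergesort")
    ranks = np.empty(len(v))
    i = 0
    while i < len(v):
        j = i
        while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def consensus_bruteforce(replicates) -> tuple[np.ndarray, np.ndarray]:
    """Spearman-weighted consensus: exact average ranks, Pearson of ranks,
    mean correlation with the other replicates clipped at 0, renormalized,
    weighted elementwise average."""
    reps = [np.asarray(r, float) for r in replicates]
    n = len(reps)
    ranked = [_average_ranks(r) for r in reps]
    mean_corr = np.zeros(n)
    for i in range(n):
        cs = []
        for j in range(n):
            if j == i:
                continue
            ri, rj = ranked[i], ranked[j]
            num = ((ri - ri.mean()) * (rj - rj.mean())).sum()
            den = np.sqrt(((ri - ri.mean()) ** 2).sum() * ((rj - rj.mean()) ** 2).sum())
            cs.append(0.0 if den == 0 else num / den)
        mean_corr[i] = np.mean(cs)
    w = np.clip(mean_corr, 0.0, None)
    w = np.full(n, 1.0 / n) if w.sum() == 0 else w / w.sum()
    consensus = sum(wi * ri for wi, ri in zip(w, reps))
    return consensus, w
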