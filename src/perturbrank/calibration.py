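"""Type-I error calibration of the competitive enrichment test.

Under the null — no treatment signal in the drugs (effect size 0) and
relevance scores assigned independently of everything the classifier can
see — the enrichment t-test should reject at its nominal rate. The study
here regenerates data, refits a classifier, rescores the perturbations
and reruns the test for every replicate, so the whole path from profiles
to p-value is exercised, not just the t statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.exceptions import ConvergenceWarning

from .enrich import enrichment_test, valid_target_set
from .score import gene_probabilities, predict_perturbations
from .simulate import SynthConfig, generate_dataset, _scores_from_truth
from .train import TrainedModelBundle, make_estimator, _fit, _proba

__all__ = ["NullCalibration", "null_rejection_rate", "binomial_interval"]


@dataclass
class NullCalibration:
    n_reps: int
    alpha: float
    rejections: int
    pvalues: np.ndarray

    @property
    def rate(self) -> float:
        return self.rejections / self.n_reps


def binomial_interval(n: int, prob: float, level: float = 0.99) -> tuple[float, float]:
    """Exact central binomial interval for the rejection *rate*."""
    lo = stats.binom.ppf((1 - level) / 2, n, prob) / n
    hi = stats.binom.ppf(1 - (1 - level) / 2, n, prob) / n
    return float(lo), float(hi)


def null_rejection_rate(n_reps: int = 400, seed: int = 0, alpha: float = 0.05,
                        n_drugs: int = 200, n_genes: int = 200,
                        n_pert: int = 500, cutoff: float = 0.5,
                        target_frac: float = 0.05) -> NullCalibration:
    """Fraction of null replicates in which the enrichment test rejects.

    Each replicate: draw a signal-free dataset (effect size 0), fit one
    class-weighted elastic-net classifier on the drugs, score the OE
    perturbations, assign relevance scores from an independently drawn
    pseudo-target vector, and run the enrichment test at ``cutoff``.
    """
    seeds = np.random.SeedSequence(seed).generate_state(2 * n_reps) % (2 ** 31)
    pvals = np.empty(n_reps)
    # loose solver tolerance: under the null only independence from the
    # scores matters, not the quality of the fitted direction
    params = {"C": 1.0, "l1_ratio": 0.5, "max_iter": 300, "tol": 1e-2}
    for r in range(n_reps):
        cfg = SynthConfig(n_drugs=n_drugs, n_genes_feature=n_genes,
                          n_oe=n_pert, n_kd=2, effect_size=0.0,
                          target_frac_up=0.0, target_frac_down=0.0,
                          seed=int(seeds[2 * r]))
        bundle = generate_dataset(cfg)
        with warnings.catch_warnings():
            # the loose iteration cap above is deliberate
            warnings.simplefilter("ignore", ConvergenceWarning)
            est = _fit(make_estimator("en", params, seed=int(seeds[2 * r])),
                       bundle.drug_matrix.data.to_numpy(),
                       bundle.labels.to_numpy())
        probs = pd.Series(_proba(est, bundle.oe_matrix.data.to_numpy()),
                          index=bundle.oe_matrix.meta["gene_symbol"].to_numpy())
        # pseudo-targets drawn independently of the data the model saw
        rng = np.random.default_rng(int(seeds[2 * r + 1]))
        fake_truth = np.zeros(n_pert)
        fake_truth[rng.choice(n_pert, size=int(round(target_frac * n_pert)),
                              replace=False)] = 1.0
        scores = pd.Series(_scores_from_truth(fake_truth, cfg, rng),
                           index=probs.index)
        res = enrichment_test(probs, valid_target_set(scores, cutoff), cutoff=cutoff)
        pvals[r] = res.p if res.testable else np.nan
    ok = np.isfinite(pvals)
    rejections = int((pvals[ok] < alpha).sum())
    return NullCalibration(n_reps=int(ok.sum()), alpha=alpha,
                           rejections=rejections, pvalues=pvals[ok])
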