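"""Synthetic drug / OE / KD expression data with planted treatment signal.

The generator emulates the statistical structure the transfer-learning
framework assumes: a single latent "treatment signature" ``w`` (a unit
vector over the feature genes) that is shared between disease-treating
drugs and the perturbations of true targets.

* A drug indicated for the disease has expression profile
  ``beta * w + noise``; a non-indicated drug is pure noise.
* Overexpressing a true up-target (alignment coefficient ``a_g = +beta``)
  reproduces the treatment signature; overexpressing a down-target
  (``a_g = -beta``) produces its mirror image. Null genes produce noise.
* Knockdown flips the sign of the planted signal and carries inflated
  noise (``kd_noise_multiplier``), encoding the hypothesis that off-target
  effects degrade shRNA profiles relative to cDNA overexpression.
* Relevance scores are a zero/one-inflated noisy monotone function of the
  target status, mimicking aggregate gene-disease association scores that
  pile up at 0 and 1.

Class imbalance is controlled by ``prevalence``; with the defaults roughly
one drug in ten is indicated, so downstream classifiers must be
class-weighted to learn anything.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (ExpressionMatrix, write_expression_matrix, read_expression_matrix,
                 write_labels, read_labels, write_target_scores, read_target_scores)

__all__ = ["SynthConfig", "SynthBundle", "generate_dataset", "generate_replicates",
           "write_bundle", "load_bundle"]


@dataclass
class SynthConfig:
    """Parameters of the planted-signal generator.

    ``effect_size`` is the separation along the latent signature in noise
    units per gene is ``effect_size / noise_sd`` along ``w``; the defaults
    give a strongly separable problem (ratio 5) with heavy class imbalance.
    """

    n_drugs: int = 300
    n_genes_feature: int = 200
    n_oe: int = 800
    n_kd: int = 800
    prevalence: float = 0.1
    effect_size: float = 1.0
    target_frac_up: float = 0.05
    target_frac_down: float = 0.0
    noise_sd: float = 0.2
    kd_noise_multiplier: float = 3.0
    score_noise: float = 0.05
    seed: int = 1
    # score-shape knobs: steepness of the monotone map and the zero/one inflation
    score_steepness: float = 3.0
    score_zero_frac: float = 0.6
    score_one_frac: float = 0.25

    def validate(self) -> None:
        if not (0.0 < self.prevalence < 1.0):
            raise ValueError("prevalence must lie strictly between 0 and 1")
        if self.target_frac_up < 0 or self.target_frac_down < 0 or \
                self.target_frac_up + self.target_frac_down > 1:
            raise ValueError("target fractions must be non-negative and sum to <= 1")
        for name in ("n_drugs", "n_genes_feature", "n_oe", "n_kd"):
            if getattr(self, name) < 2:
                raise ValueError(f"{name} must be >= 2")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.kd_noise_multiplier < 1:
            raise ValueError("kd_noise_multiplier must be >= 1")
        if self.score_noise < 0:
            raise ValueError("score_noise must be >= 0")


@dataclass
class SynthBundle:
    """Everything one pipeline run consumes, plus the generating truth."""

    drug_matrix: ExpressionMatrix
    labels: pd.Series                 # drug_id -> {0,1}
    oe_matrix: ExpressionMatrix
    kd_matrix: ExpressionMatrix
    scores: pd.Series                 # perturbed gene -> relevance score in [0,1]
    truth: pd.Series                  # perturbed gene -> alignment coefficient a_g
    signature: np.ndarray             # latent treatment signature w (unit norm)
    config: SynthConfig | None = field(default=None)


def _scores_from_truth(truth: np.ndarray, cfg: SynthConfig,
                       rng: np.random.Generator) -> np.ndarray:
    """Zero/one-inflated noisy monotone map from |a_g| to a [0,1] score.

    The rescaled logistic 2*sigma(k|a|) - 1 maps null genes to 0 and strong
    targets towards 1; Gaussian noise is added, the result clipped to
    [0, 1], and a configurable fraction of nulls / targets is then pinned
    to exactly 0 / exactly 1.
    """
    mag = np.abs(truth)
    base = 2.0 / (1.0 + np.exp(-cfg.score_steepness * mag)) - 1.0
    s = np.clip(base + cfg.score_noise * rng.standard_normal(mag.size), 0.0, 1.0)
    nulls = np.flatnonzero(mag == 0)
    targets = np.flatnonzero(mag > 0)
    if nulls.size:
        n_zero = int(round(cfg.score_zero_frac * nulls.size))
        s[rng.choice(nulls, size=n_zero, replace=False)] = 0.0
    if targets.size:
        n_one = int(round(cfg.score_one_frac * targets.size))
        s[rng.choice(targets, size=n_one, replace=False)] = 1.0
    return s


def generate_dataset(config: SynthConfig) -> SynthBundle:
    """Draw one synthetic bundle. Bit-reproducible given ``config.seed``."""
    config.validate()
    root = np.random.SeedSequence(config.seed)
    streams = root.spawn(6)
    rng_w, rng_lab, rng_drug, rng_pert, rng_truth, rng_score = \
        (np.random.default_rng(s) for s in streams)

    G = config.n_genes_feature
    genes = [f"G{i:04d}" for i in range(G)]
    w = rng_w.standard_normal(G)
    w /= np.linalg.norm(w)

    # indication labels: seeded shuffle, first round(prevalence * n) drugs indicated
    n_pos = int(round(config.prevalence * config.n_drugs))
    if n_pos < 2 or config.n_drugs - n_pos < 2:
        raise ValueError(
            f"degenerate configuration: {n_pos} indicated / "
            f"{config.n_drugs - n_pos} non-indicated drugs (need >= 2 each)")
    drug_ids = [f"D{i:04d}" for i in range(config.n_drugs)]
    order = rng_lab.permutation(config.n_drugs)
    y = np.zeros(config.n_drugs, dtype=int)
    y[order[:n_pos]] = 1
    labels = pd.Series(y, index=drug_ids, name="label")

    drug_values = (np.outer(y * config.effect_size, w)
                   + rng_drug.normal(0.0, config.noise_sd, (config.n_drugs, G)))
    drug_matrix = ExpressionMatrix(pd.DataFrame(drug_values, index=drug_ids, columns=genes))

    # perturbed-gene pool shared by OE and KD; targets planted by seeded shuffle
    pool = max(config.n_oe, config.n_kd)
    pert_genes = np.array([f"PG{i:04d}" for i in range(pool)])
    n_up = int(round(config.target_frac_up * pool))
    n_down = int(round(config.target_frac_down * pool))
    c = np.zeros(pool)
    shuffled = rng_truth.permutation(pool)
    c[shuffled[:n_up]] = 1.0
    c[shuffled[n_up:n_up + n_down]] = -1.0
    a = c * config.effect_size
    truth = pd.Series(a, index=pert_genes, name="a_g")

    oe_genes = pert_genes[: config.n_oe]
    kd_genes = pert_genes[: config.n_kd]
    oe_values = (np.outer(a[: config.n_oe], w)
                 + rng_pert.normal(0.0, config.noise_sd, (config.n_oe, G)))
    kd_sd = config.noise_sd * config.kd_noise_multiplier
    kd_values = (np.outer(-a[: config.n_kd], w)
                 + rng_pert.normal(0.0, kd_sd, (config.n_kd, G)))
    oe_matrix = ExpressionMatrix(
        pd.DataFrame(oe_values, index=[f"OE_{g}" for g in oe_genes], columns=genes),
        pd.DataFrame({"gene_symbol": oe_genes, "pert_type": "OE"},
                     index=[f"OE_{g}" for g in oe_genes]))
    kd_matrix = ExpressionMatrix(
        pd.DataFrame(kd_values, index=[f"KD_{g}" for g in kd_genes], columns=genes),
        pd.DataFrame({"gene_symbol": kd_genes, "pert_type": "KD"},
                     index=[f"KD_{g}" for g in kd_genes]))

    scores = pd.Series(_scores_from_truth(a, config, rng_score),
                       index=pert_genes, name="score")

    return SynthBundle(drug_matrix, labels, oe_matrix, kd_matrix,
                       scores, truth, w, config)


def generate_replicates(base_signature: np.ndarray, n_reps: int,
                        noise_sd: float, seed: int) -> np.ndarray:
    """Noisy copies of one signature, e.g. to exercise consensus weighting."""
    base = np.asarray(base_signature, dtype=float)
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    rng = np.random.default_rng(seed)
    return base[None, :] + rng.normal(0.0, noise_sd, (n_reps, base.size))


# ---------------------------------------------------------------------------
# On-disk bundle format: GCT matrices + TSV tables + config echo
# ---------------------------------------------------------------------------

def write_bundle(bundle: SynthBundle, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_expression_matrix(bundle.drug_matrix, out / "drug.gct")
    write_expression_matrix(bundle.oe_matrix, out / "oe.gct")
    write_expression_matrix(bundle.kd_matrix, out / "kd.gct")
    write_labels(bundle.labels, out / "labels.tsv")
    write_target_scores(bundle.scores, out / "scores.tsv")
    bundle.truth.rename("a_g").rename_axis("gene").to_frame().to_csv(
        out / "truth.tsv", sep="\t")
    pd.Series(bundle.signature, index=bundle.drug_matrix.col_ids, name="w") \
        .rename_axis("gene").to_frame().to_csv(out / "signature.tsv", sep="\t")
    if bundle.config is not None:
        with open(out / "config.txt", "w", encoding="utf-8") as fh:
            for key, val in asdict(bundle.config).items():
                fh.write(f"{key}={val}\n")
    return out


def load_bundle(bundle_dir: str | Path) -> SynthBundle:
    d = Path(bundle_dir)
    config = None
    if (d / "config.txt").exists():
        kv = {}
        for line in (d / "config.txt").read_text().splitlines():
            key, _, val = line.partition("=")
            kv[key] = val
        fields = {f.name: f.type for f in SynthConfig.__dataclass_fields__.values()}
        typed = {k: (int(float(v)) if fields[k] == "int" else float(v))
                 for k, v in kv.items() if k in fields}
        config = SynthConfig(**typed)
    drug = read_expression_matrix(d / "drug.gct")
    truth = pd.read_csv(d / "truth.tsv", sep="\t", index_col="gene")["a_g"]
    truth.index = truth.index.astype(str)
    sig = pd.read_csv(d / "signature.tsv", sep="\t", index_col="gene")["w"].to_numpy()
    return SynthBundle(
        drug_matrix=drug,
        labels=read_labels(d / "labels.tsv", matrix=drug),
        oe_matrix=read_expression_matrix(d / "oe.gct"),
        kd_matrix=read_expression_matrix(d / "kd.gct"),
        scores=read_target_scores(d / "scores.tsv"),
        truth=truth,
        signature=sig,
        config=config,
    )
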