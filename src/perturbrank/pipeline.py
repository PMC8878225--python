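"""End-to-end orchestration: simulate -> train -> score -> validate.

Every stage is a pure function of the input files, the configuration and
one global seed; independent substreams are derived from the seed for
data generation, fold assignment and model randomness, so repeated runs
produce byte-identical artifacts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .enrich import DEFAULT_CUTOFFS, sweep_methods
from .io import (harmonize_genes, read_expression_matrix, read_labels,
                 read_target_scores)
from .score import model_correlations, predict_perturbations, rank_targets
from .simulate import SynthConfig, SynthBundle, generate_dataset, load_bundle, write_bundle
from .train import METHODS, build_cv_plan, fit_ensemble, nested_cv_train

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "robustness_check",
           "train_all", "PipelineResult"]


class PipelineError(RuntimeError):
    """Raised when a stage fails; the message names the stage and cause."""


@dataclass
class PipelineConfig:
    out_dir: str | Path = "perturbrank_run"
    seed: int = 1
    methods: tuple[str, ...] = METHODS
    top_k: int = 10
    cutoffs: tuple[float, ...] = DEFAULT_CUTOFFS
    rank_method: str = "ensemble"
    scale: bool = False
    equal_var: bool = False
    fdr_pool: str = "per-run"
    folds: int = 5
    # inputs: either a synthetic config, a bundle directory, or explicit paths
    simulate: SynthConfig | None = None
    bundle_dir: str | Path | None = None
    drug_matrix: str | Path | None = None
    labels: str | Path | None = None
    oe_matrix: str | Path | None = None
    kd_matrix: str | Path | None = None
    scores: str | Path | None = None
    grids: dict | None = None

    def echo(self) -> dict:
        d = dataclasses.asdict(self)
        d["simulate"] = None if self.simulate is None else dataclasses.asdict(self.simulate)
        return {k: (str(v) if isinstance(v, Path) else v) for k, v in d.items()}


@dataclass
class PipelineResult:
    out_dir: Path
    bundle: SynthBundle | None
    trained: dict
    ensemble: object
    cv_report: pd.DataFrame
    predictions: pd.DataFrame
    sweeps: dict[str, pd.DataFrame]


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc
        return inner
    return wrap


def _write_tsv(df: pd.DataFrame, path: Path, seed: int, index: bool = False) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# seed={seed}\n")
        df.to_csv(fh, sep="\t", index=index)


@_stage("load")
def _load_inputs(config: PipelineConfig, out: Path):
    if config.simulate is not None:
        sim = dataclasses.replace(config.simulate, seed=config.seed)
        bundle = generate_dataset(sim)
        write_bundle(bundle, out / "bundle")
        return bundle
    if config.bundle_dir is not None:
        return load_bundle(config.bundle_dir)
    needed = {"drug_matrix": config.drug_matrix, "labels": config.labels,
              "oe_matrix": config.oe_matrix, "kd_matrix": config.kd_matrix,
              "scores": config.scores}
    missing = [k for k, v in needed.items() if v is None]
    if missing:
        raise ValueError(f"missing input path(s): {missing}")
    for k, v in needed.items():
        if not Path(v).exists():
            raise FileNotFoundError(f"{k} file not found: {v}")
    drug = read_expression_matrix(needed["drug_matrix"])
    return SynthBundle(
        drug_matrix=drug,
        labels=read_labels(needed["labels"], matrix=drug),
        oe_matrix=read_expression_matrix(needed["oe_matrix"]),
        kd_matrix=read_expression_matrix(needed["kd_matrix"]),
        scores=read_target_scores(needed["scores"]),
        truth=pd.Series(dtype=float), signature=np.array([]), config=None)


@_stage("train")
def train_all(drug_matrix, labels: pd.Series, methods: Sequence[str] = METHODS,
              seed: int = 1, folds: int = 5, scale: bool = False,
              grids: dict | None = None):
    """Nested-CV train every method on one shared fold plan + the ensemble."""
    plan = build_cv_plan(len(labels), seed, labels, n_folds=folds)
    trained, reports = {}, []
    for m in methods:
        grid = None if grids is None else grids.get(m)
        bundle, report = nested_cv_train(drug_matrix, labels, m, grid=grid,
                                         plan=plan, seed=seed, scale=scale)
        trained[m] = bundle
        report.insert(0, "method", m)
        reports.append(report)
    ensemble = fit_ensemble(trained, labels, seed=seed) if len(trained) > 1 else None
    return trained, ensemble, pd.concat(reports, ignore_index=True)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full pipeline and write all artifacts under ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed

    bundle = _load_inputs(config, out)

    @_stage("harmonize")
    def _harmonize():
        return harmonize_genes(bundle.drug_matrix, bundle.oe_matrix, bundle.kd_matrix)

    drug, oe, kd = _harmonize()

    trained, ensemble, cv_report = train_all(
        drug, bundle.labels, methods=config.methods, seed=seed,
        folds=config.folds, scale=config.scale, grids=config.grids)
    _write_tsv(cv_report, out / "cv_report.tsv", seed)

    @_stage("score")
    def _score():
        parts = [predict_perturbations(trained, mat, ensemble=ensemble)
                 for mat in (oe, kd)]
        return pd.concat(parts)

    predictions = _score()
    _write_tsv(predictions.reset_index(names="perturbation"),
               out / "predictions.tsv", seed)
    pearson, spearman = model_correlations(predictions)
    _write_tsv(pearson.reset_index(names="method"), out / "correlations_pearson.tsv", seed)
    _write_tsv(spearman.reset_index(names="method"), out / "correlations_spearman.tsv", seed)

    @_stage("rank")
    def _rank():
        for ptype in ("OE", "KD"):
            top, bottom = rank_targets(predictions, config.top_k,
                                       config.rank_method, pert_type=ptype)
            _write_tsv(top, out / f"targets_top_{ptype.lower()}.tsv", seed)
            _write_tsv(bottom, out / f"targets_bottom_{ptype.lower()}.tsv", seed)

    _rank()

    @_stage("validate")
    def _validate():
        sweeps = {}
        for ptype in ("OE", "KD"):
            sweep = sweep_methods(predictions, bundle.scores, config.methods,
                                  cutoffs=config.cutoffs, pert_type=ptype,
                                  equal_var=config.equal_var,
                                  fdr_pool=config.fdr_pool)
            sweeps[ptype] = sweep
            _write_tsv(sweep, out / f"enrichment_{ptype.lower()}.tsv", seed)
            wide = sweep.pivot(index="cutoff", columns="method", values="p") \
                        .sort_index(ascending=False)[list(config.methods)]
            _write_tsv(wide.reset_index(), out / f"enrichment_{ptype.lower()}_pvalues.tsv",
                       seed)
        return sweeps

    sweeps = _validate()

    manifest = {"seed": seed, "perturbrank_version": __version__,
                "config": config.echo()}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    return PipelineResult(out_dir=out, bundle=bundle, trained=trained,
                          ensemble=ensemble, cv_report=cv_report,
                          predictions=predictions, sweeps=sweeps)


def robustness_check(config: PipelineConfig, seeds: Sequence[int],
                     pert_type: str = "OE"):
    """Re-run the pipeline under several seeds and compare the sweep tables.

    Returns the per-seed enrichment tables and the pairwise Spearman rank
    correlation of their p-values (aligned on method x cutoff).
    """
    if len(seeds) < 2:
        raise ValueError("robustness check needs at least 2 seeds")
    if config.simulate is not None:
        # fix the dataset once (the generator keeps its own seed) so the
        # seeds below vary only sample splitting and model randomness
        shared = Path(config.out_dir) / "shared_bundle"
        write_bundle(generate_dataset(config.simulate), shared)
        config = dataclasses.replace(config, simulate=None, bundle_dir=shared)
    tables = {}
    for s in seeds:
        cfg = dataclasses.replace(config, seed=int(s),
                                  out_dir=Path(config.out_dir) / f"seed_{s}")
        result = run_pipeline(cfg)
        tables[s] = result.sweeps[pert_type].set_index(["method", "cutoff"])["p"]
    corr = pd.DataFrame(np.eye(len(seeds)), index=list(seeds), columns=list(seeds))
    for i, a in enumerate(seeds):
        for j, b in enumerate(seeds):
            if j <= i:
                continue
            merged = pd.concat([tables[a], tables[b]], axis=1, join="inner").dropna()
            rho = 1.0 if merged.iloc[:, 0].equals(merged.iloc[:, 1]) else \
                stats.spearmanr(merged.iloc[:, 0], merged.iloc[:, 1]).statistic
            corr.iloc[i, j] = corr.iloc[j, i] = float(rho)
    return tables, corr
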