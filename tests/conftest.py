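import pandas as pd
import pytest

from perturbrank.pipeline import train_all
from perturbrank.score import predict_perturbations
from perturbrank.simulate import SynthConfig, generate_dataset

# single-point grids so unit tests exercise the nested-CV machinery cheaply
TINY_GRIDS = {
    "en": [{"C": 1.0, "l1_ratio": 0.5}],
    "svm": [{"C": 1.0, "gamma": "scale"}],
    "rf": [{"n_estimators": 60, "max_features": "sqrt"}],
    "gbm": [{"n_estimators": 60, "max_depth": 2, "learning_rate": 0.1}],
}


def small_config(**overrides) -> SynthConfig:
    base = dict(n_drugs=80, n_genes_feature=30, n_oe=60, n_kd=60,
                prevalence=0.15, target_frac_up=0.1, target_frac_down=0.05,
                seed=11)
    base.update(overrides)
    return SynthConfig(**base)


@pytest.fixture(scope="session")
def small_bundle():
    return generate_dataset(small_config())


@pytest.fixture(scope="session")
def small_trained(small_bundle):
    trained, ensemble, report = train_all(
        small_bundle.drug_matrix, small_bundle.labels, seed=11, grids=TINY_GRIDS)
    return trained, ensemble, report


@pytest.fixture(scope="session")
def small_predictions(small_bundle, small_trained):
    trained, ensemble, _ = small_trained
    return pd.concat([
        predict_perturbations(trained, small_bundle.oe_matrix, ensemble=ensemble),
        predict_perturbations(trained, small_bundle.kd_matrix, ensemble=ensemble),
    ])


@pytest.fixture(scope="session")
def strong_run():
    """The strong-signal study: default generator, full grids, all methods."""
    bundle = generate_dataset(SynthConfig())
    trained, ensemble, report = train_all(bundle.drug_matrix, bundle.labels, seed=1)
    predictions = pd.concat([
        predict_perturbations(trained, bundle.oe_matrix, ensemble=ensemble),
        predict_perturbations(trained, bundle.kd_matrix, ensemble=ensemble),
    ])
    return {"bundle": bundle, "trained": trained, "ensemble": ensemble,
            "report": report, "predictions": predictions}
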