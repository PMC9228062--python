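import numpy as np
import pytest

from thyscreen import (AggregatedConformalClassifier, GaussianSpec,
                       MoleculeRuleSpec, SplitPlan, curate_dataframe,
                       fit_aggregated, gen_gaussian, gen_molecules,
                       train_endpoint)
from thyscreen.screening import EndpointBattery, GENERAL_GROUP, THYROID_GROUP


@pytest.fixture(scope="session")
def gaussian_dataset():
    """Moderately separated two-class Gaussian data, 30% actives."""
    X, y = gen_gaussian(GaussianSpec(n=600, active_fraction=0.3,
                                     class_separation=2.0, seed=11))
    return X, y


@pytest.fixture(scope="session")
def small_model(gaussian_dataset):
    """A quickly trained aggregate plus its validation partition."""
    X, y = gaussian_dataset
    model, X_val, y_val = fit_aggregated(
        X, y, SplitPlan(base_seed=5), n_models=10, n_estimators=100)
    return model, X_val, y_val


@pytest.fixture(scope="session")
def molecule_training_table():
    """A curated rule-labeled molecule dataset for pipeline tests."""
    df = gen_molecules(MoleculeRuleSpec(n=250, active_fraction=0.3,
                                        label_noise=0.05, seed=31))
    curated, _ = curate_dataframe(df[["id", "smiles", "activity"]])
    return curated


@pytest.fixture(scope="session")
def molecule_battery(molecule_training_table):
    """Three thyroid-specific endpoints plus one general endpoint, all
    trained on the same rule so active calls correlate across models."""
    battery = EndpointBattery()
    for name, group, seed in [("TPO", THYROID_GROUP, 0),
                              ("TTR", THYROID_GROUP, 100),
                              ("DIO1", THYROID_GROUP, 200),
                              ("PXR", GENERAL_GROUP, 300)]:
        trained = train_endpoint(
            molecule_training_table, name=name, group=group,
            plan=SplitPlan(base_seed=seed), n_models=5, n_estimators=60)
        battery.add(trained.endpoint)
    return battery
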