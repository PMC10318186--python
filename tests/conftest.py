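import numpy as np
import pytest

from gaitbalance.classifier import ModelConfig, build_classifier, train_classifier
from gaitbalance.evaluation import make_loso_folds
from gaitbalance.preprocessing import preprocess_dataset
from gaitbalance.simulator import SimulationConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """4 subjects x 2 trials x 3 levels = 24 sequences."""
    return generate_dataset(SimulationConfig(n_subjects=4, n_trials=2, seed=7))


@pytest.fixture(scope="session")
def default_dataset():
    """The full default study layout: 10 x 10 x 3 = 300 sequences."""
    return generate_dataset(SimulationConfig(seed=1))


@pytest.fixture()
def quick_config():
    """A small, fast model configuration for unit tests."""
    return ModelConfig(channels=8, n_blocks=1, max_epochs=8, patience=4,
                       dropout_rate=0.2, learning_rate=1e-3, seed=11)


@pytest.fixture(scope="session")
def trained_default_model(default_dataset):
    """Default-configuration classifier trained on fold 0 of the default
    dataset (A0 joints), shared across tests that need a realistic trained
    network."""
    samples = preprocess_dataset(default_dataset, "A0")
    fold = make_loso_folds(default_dataset)[0]
    tr = [s for s in samples if s.subject_id in fold.train_subjects]
    va = [s for s in samples if s.subject_id == fold.val_subject]
    config = ModelConfig(seed=1)
    model = build_classifier(config, 21)
    model, _ = train_classifier(model, tr, va, config)
    return model, samples, fold
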