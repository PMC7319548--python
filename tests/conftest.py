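import logging

import pytest

from shiftcrypt import (
    GeneratorConfig, calibrate_orientation, generate, labeled_vectors, train,
)

logging.getLogger("shiftcrypt").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def native_corpus():
    """300 synthetic native-state proteins with structure labels."""
    tables, labels = generate(GeneratorConfig(n_proteins=300, seed=2))
    return tables, labels


@pytest.fixture(scope="session")
def trained(native_corpus):
    """Reduced-scheme model trained and orientation-calibrated on the corpus."""
    tables, labels = native_corpus
    model, report = train(tables, "reduced", seed=3)
    calibrate_orientation(model, labeled_vectors(tables, labels, model))
    return model, report


@pytest.fixture(scope="session")
def small_corpus():
    """A cheap 40-protein corpus for structural (non-performance) checks."""
    return generate(GeneratorConfig(n_proteins=40, seed=77))
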