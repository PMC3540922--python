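import numpy as np
import pytest

from pupsyl import calculator, features, synth, twostep_cluster


@pytest.fixture(scope="session")
def default_repertoire():
    """Default synthetic repertoire: 4000 syllables, equal mix, seed 1."""
    return synth.generate_repertoire(synth.RepertoireSpec(n_syllables=4000, seed=1))


@pytest.fixture(scope="session")
def default_features(default_repertoire):
    return features.features_from_table(default_repertoire)


@pytest.fixture(scope="session")
def fitted_model(default_features):
    """Two-step clustering of the default repertoire (shared: ~6 s to fit)."""
    return twostep_cluster.fit(default_features)


@pytest.fixture(scope="session")
def calculator_labels(default_features):
    labels, proportions, flagged = calculator.classify_table(
        default_features, calculator.strain_preset("CBA/CaJ")
    )
    return labels


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
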