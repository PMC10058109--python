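import numpy as np
import pytest

from pullulanopt import cart, load_fixture, run_case_study


@pytest.fixture(scope="session")
def fixture_table():
    return load_fixture()


@pytest.fixture(scope="session")
def report():
    """The full case-study report; computed once per session."""
    return run_case_study()


@pytest.fixture(scope="session")
def training_arrays(fixture_table):
    """(X, y) of the 53 printed Training cases, plus the 28 Test cases."""
    fx = fixture_table
    names = fx.design.names
    merged = fx.observations.merge(fx.design.decoded().reset_index(), on="run")
    train = merged[merged["partition"] == "Training"]
    test = merged[merged["partition"] == "Test"]
    return (
        train[names].to_numpy(float),
        train["response"].to_numpy(),
        test[names].to_numpy(float),
        test["response"].to_numpy(),
        names,
    )


@pytest.fixture(scope="session")
def fixture_tree(training_arrays):
    X_train, y_train, _, _, names = training_arrays
    return cart.grow(X_train, y_train, names)
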