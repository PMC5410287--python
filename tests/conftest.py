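import numpy as np
import pytest

from angiosched import (
    CYTOTOXIC,
    ANTIANGIOGENIC,
    ModelParams,
    default_model_params,
    default_pk,
    experiment_2,
)


@pytest.fixture(scope="session")
def pk_pair():
    """(cytotoxic, antiangiogenic) default PK constants."""
    pk = default_pk()
    return pk[CYTOTOXIC], pk[ANTIANGIOGENIC]


@pytest.fixture(scope="session")
def expe2():
    return experiment_2()


@pytest.fixture(scope="session")
def params_m1() -> ModelParams:
    return default_model_params(1)


@pytest.fixture(scope="session")
def params_m2() -> ModelParams:
    return default_model_params(2)


@pytest.fixture(scope="session")
def growth_only() -> ModelParams:
    """Drug-free Gompertz/Hahnfeldt parameters for oracle checks."""
    return ModelParams(
        a=0.148, b=1.0, d=0.0257, e_txl=0.0, e_beva=0.0, k=1.0, K0=1.85, t_I=8.0
    )


def rel_err(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    return np.max(np.abs(x - y) / np.maximum(np.abs(y), 1e-300))
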