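import dataclasses

import numpy as np
import pandas as pd
import pytest

from polypillce.parameters import load_parameters, packaged_basecase_path
from polypillce.risk_models import LifeTable
from polypillce.synthetic_data import make_fixture


@pytest.fixture(scope="session")
def base_params():
    return load_parameters(packaged_basecase_path())


@pytest.fixture()
def tiny_params():
    return make_fixture(scale="tiny")


def zero_mortality_table(max_age: int = 160) -> LifeTable:
    """A life table with no background mortality below the absorbing cap."""
    ages = np.arange(0, max_age + 1)
    q = np.zeros(len(ages))
    q[-1] = 1.0
    table = LifeTable(pd.DataFrame({"age": ages, "qx_male": q,
                                    "qx_female": q}))
    table.validate()
    return table


@pytest.fixture()
def deathless_params(base_params):
    """Base case with event risk and background mortality switched off:
    cohort occupancy is frozen in the stable states."""
    p = base_params.copy()
    p.risk_models["smart"].baseline_survival = 1.0
    p.epi.life_table = zero_mortality_table()
    p.profile = dataclasses.replace(p.profile, post_chd_weight=1.0,
                                    post_stroke_weight=0.0)
    return p
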