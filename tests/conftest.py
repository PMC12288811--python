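import numpy as np
import pandas as pd
import pytest

from fgmi.dgm import (
    CensoringSpec,
    FGCorrectParams,
    MissingnessSpec,
    apply_censoring,
    gen_fg_correct,
    induce_missingness,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture
def small_competing_risks(rng) -> pd.DataFrame:
    """A modest censored competing-risks dataset from the FG-correct mechanism."""
    data = gen_fg_correct(400, FGCorrectParams(p=0.3), rng)
    return apply_censoring(data, CensoringSpec(kind="random"), rng)


@pytest.fixture
def missing_x_dataset(rng) -> pd.DataFrame:
    """Censored competing-risks data with ~40% MAR missingness in x."""
    data = gen_fg_correct(600, FGCorrectParams(p=0.3), rng)
    data = apply_censoring(data, CensoringSpec(kind="random"), rng)
    return induce_missingness(data, MissingnessSpec("mar_z"), rng)


def random_survival(rng, n=50, censor_frac=0.4):
    t = rng.exponential(size=n) + 0.01
    s = (rng.uniform(size=n) > censor_frac).astype(int)
    if s.sum() == 0:
        s[0] = 1
    return t, s
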