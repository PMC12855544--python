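import numpy as np
import pandas as pd
import pytest

from behavnet import default_schema
from behavnet.schema import VariableSpec


@pytest.fixture(scope="session")
def schema():
    return default_schema()


def binary_spec(name, p1=0.5):
    return VariableSpec(name=name, scale="binary", levels=[0, 1],
                        reference_level=0, gen_params={"probs": [1 - p1, p1]})


@pytest.fixture(scope="session")
def toy_linear_system():
    """5-variable table with a planted noiseless x -> y dependence."""
    rng = np.random.default_rng(42)
    n = 400
    x = rng.uniform(size=n)
    df = pd.DataFrame({
        "x": x,
        "y": (x > 0.5).astype(int),
        "v0": rng.integers(0, 2, n),
        "v1": rng.integers(0, 2, n),
        "v2": rng.integers(0, 2, n),
    })
    toy_schema = [
        VariableSpec(name="x", scale="continuous", cox_encoding="ordinal_numeric",
                     ann_encoding="minmax_continuous", gen_params={"range": [0, 1]}),
        binary_spec("y"), binary_spec("v0"), binary_spec("v1"), binary_spec("v2"),
    ]
    return df, toy_schema


def survival_frame(betas, n, seed, scale=10.0, shape=1.0, censor=None):
    """Exponential/Weibull PH survival data on explicit design columns.

    ``betas`` maps column names to coefficients; covariates are iid
    Bernoulli(0.5) (columns ending in '_u' are Uniform(0,1)).  ``censor``
    is an administrative cutoff (None = no censoring).
    """
    rng = np.random.default_rng(seed)
    cols = {}
    lp = np.zeros(n)
    for name, b in betas.items():
        x = (rng.uniform(size=n) if name.endswith("_u")
             else rng.integers(0, 2, n).astype(float))
        cols[name] = x
        lp += b * x
    u = rng.uniform(size=n)
    T = scale * (-np.log(u) * np.exp(-lp)) ** (1.0 / shape)
    if censor is None:
        event = np.ones(n, int)
        follow = T
    else:
        event = (T <= censor).astype(int)
        follow = np.minimum(T, censor)
    cols["follow_up_years"] = follow
    cols["event"] = event
    return pd.DataFrame(cols)
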