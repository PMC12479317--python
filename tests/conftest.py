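import numpy as np
import pandas as pd
import pytest

from aiekit.estimands import Contrast, EstimandSpec, VertexWeight
from aiekit.nuisance import NuisanceFits


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


def binary_ate_spec(confounders=("W",), covariates=(), family="gaussian"):
    return EstimandSpec(
        kind="ate",
        outcome="Y",
        treatments=("A",),
        contrast=Contrast(pairs=(((0, 1)),)),
        confounders=tuple(confounders),
        covariates=tuple(covariates),
        outcome_family=family,
    )


def make_manual_fits(y, a, g1, qbar_obs, q0, q1, family="gaussian", g_obs=None):
    """Hand-assembled single-binary-treatment nuisance fits (contrast 0->1).

    g1: P(A=1|W) per individual; q0/q1: vertex predictions.
    """
    y = np.asarray(y, dtype=float)
    a = np.asarray(a)
    g1 = np.asarray(g1, dtype=float)
    if g_obs is None:
        g_obs = np.where(a == 1, g1, 1 - g1)
    return NuisanceFits(
        y=y,
        family=family,
        qbar_obs=np.asarray(qbar_obs, dtype=float),
        qbar_vertices={(0,): np.asarray(q0, dtype=float),
                       (1,): np.asarray(q1, dtype=float)},
        g_vertices={(0,): 1 - g1, (1,): g1},
        g_obs=np.asarray(g_obs, dtype=float),
        indicators={(0,): a == 0, (1,): a == 1},
    )


def binary_vertices():
    return [
        VertexWeight(s=(0,), assignment=(0,), sign=-1),
        VertexWeight(s=(1,), assignment=(1,), sign=1),
    ]


@pytest.fixture
def toy_confounded(rng):
    """Small confounded cohort with binary treatment and one binary W."""
    n = 400
    w = rng.binomial(1, 0.5, n)
    p = 0.3 + 0.4 * w
    a = rng.binomial(1, p)
    y = 1.0 + 0.7 * a + 0.5 * w + rng.standard_normal(n)
    return pd.DataFrame({"Y": y, "A": a, "W": w})
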