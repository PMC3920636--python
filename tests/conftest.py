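import numpy as np
import pandas as pd
import pytest

from ratiomi import ColumnRoles, IncompleteDataset


@pytest.fixture
def rng():
    return np.random.default_rng(20130806)


@pytest.fixture
def sim_roles():
    return ColumnRoles(numerator="a1", denominator="a2", ratio="x", outcome="y")


def make_mcar_ratio_dataset(
    n=300,
    miss=0.25,
    cv_a2=0.1,
    seed=11,
    beta1=2.0,
    r2=0.3,
):
    """Small bivariate-lognormal ratio dataset with MCAR component missingness."""
    g = np.random.default_rng(seed)
    s2 = np.sqrt(np.log(1 + cv_a2**2))
    l1 = 4.0 + 0.21 * g.standard_normal(n)
    l2 = 0.97 + s2 * g.standard_normal(n)
    a1, a2 = np.exp(l1), np.exp(l2)
    x = a1 / a2
    sd_y = abs(beta1) * np.std(x) * np.sqrt((1 - r2) / r2)
    y = beta1 * x + sd_y * g.standard_normal(n)
    r1 = g.random(n) > miss
    r2m = g.random(n) > miss
    df = pd.DataFrame(
        {
            "a1": np.where(r1, a1, np.nan),
            "a2": np.where(r2m, a2, np.nan),
            "x": np.where(r1 & r2m, x, np.nan),
            "y": y,
        }
    )
    roles = ColumnRoles(numerator="a1", denominator="a2", ratio="x", outcome="y")
    return IncompleteDataset(df, df.notna(), roles)


@pytest.fixture
def mcar_ds():
    return make_mcar_ratio_dataset()
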