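import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def small_degs() -> pd.DataFrame:
    """Six genes spanning both signs, as in the worked top-K example."""
    return pd.DataFrame(
        {
            "gene": list("ABCDEF"),
            "zscore": [3.1, 2.0, 0.5, -0.4, -1.9, -3.3],
            "pvalue": [0.002, 0.04, 0.6, 0.7, 0.06, 0.001],
        }
    )


@pytest.fixture
def random_degs() -> pd.DataFrame:
    rng = np.random.default_rng(42)
    n = 400
    z = rng.normal(0, 2, n)
    from scipy import stats

    return pd.DataFrame(
        {
            "gene": [f"G{i:04d}" for i in range(n)],
            "zscore": z,
            "pvalue": np.clip(2 * stats.norm.sf(np.abs(z)), 1e-300, 1.0),
        }
    )


@pytest.fixture(scope="session")
def scenario_dir(tmp_path_factory) -> str:
    """A full synthetic input bundle shared across end-to-end tests."""
    from repurpose.synthetic import gen_scenario

    outdir = tmp_path_factory.mktemp("bundle")
    gen_scenario(outdir, seed=11)
    return str(outdir)


def brute_force_bh(pvalues: np.ndarray) -> np.ndarray:
    """Textbook BH: sort, scale by n/rank, cumulative min from the largest
    rank, cap at 1; independent of the statsmodels-backed implementation."""
    p = np.asarray(pvalues, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    scaled = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out
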