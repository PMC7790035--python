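import numpy as np
import pandas as pd
import pytest

from crosstrait import GenerativeParams, harmonize_pair, simulate_pair


def make_sumstats(n=5, seed=0, **overrides):
    """Small well-formed SummaryStats frame for unit tests."""
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({
        "SNP": [f"rs{i}" for i in range(n)],
        "CHR": ["1"] * n,
        "BP": np.arange(1, n + 1) * 1000,
        "A1": ["A"] * n,
        "A2": ["G"] * n,
        "Z": rng.standard_normal(n),
        "N": [10_000.0] * n,
    })
    from scipy import stats
    df["P"] = 2 * stats.norm.sf(np.abs(df["Z"]))
    for k, v in overrides.items():
        df[k] = v
    return df


@pytest.fixture(scope="session")
def overlap_sim():
    """One small planted-overlap simulation shared across tests:
    5e4 SNPs, default LD, strongly correlated shared component."""
    gp = GenerativeParams(m=50_000, pi_a=1e-3, pi_b=1e-3, pi_ab=2e-3,
                          rho_beta=0.9, seed=101)
    sa, sb, ld, effects = simulate_pair(gp)
    pair = harmonize_pair(sa, sb)
    return gp, pair, ld, effects


@pytest.fixture(scope="session")
def null_sim_small():
    """Independent null traits, 2e4 SNPs, default LD."""
    gp = GenerativeParams(m=20_000, n_blocks=400, pi_a=0.0, pi_b=0.0,
                          pi_ab=0.0, seed=77)
    sa, sb, ld, effects = simulate_pair(gp)
    pair = harmonize_pair(sa, sb)
    return gp, pair, ld
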