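import pandas as pd
import pytest

from orgrowth import simulate


@pytest.fixture(scope="session")
def morpho_df() -> pd.DataFrame:
    """Default simulated growth experiment (3 lines x 7 organoids, 1.5-fold)."""
    return simulate.gen_morphometry(simulate.MorphoSimConfig(seed=1))


@pytest.fixture(scope="session")
def small_expr() -> simulate.ExpressionSim:
    """Scaled-down expression simulation for fast unit tests."""
    cfg = simulate.ExprSimConfig(
        n_genes=2000, n_de=100, n_disease_set=150, planted_overlap=10, seed=2
    )
    return simulate.gen_expression(cfg)
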