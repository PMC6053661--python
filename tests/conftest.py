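import pandas as pd
import pytest

from slamitseq.simulate import SimConfig, simulate_experiment


@pytest.fixture(scope="session")
def sheet_4v3() -> pd.DataFrame:
    rows = [(f"pos_{i}", "cre_pos", i) for i in range(1, 5)] + [
        (f"neg_{i}", "cre_neg", i) for i in range(1, 4)
    ]
    return pd.DataFrame(rows, columns=["sample_id", "group", "replicate"])


@pytest.fixture(scope="session")
def demo_experiment(tmp_path_factory):
    """A small labelled experiment shared across quantification tests."""
    cfg = SimConfig(
        seed=42,
        n_genes=25,
        n_labelled=5,
        snp_fraction=0.2,
        expression=150.0,
        length_min=250,
        length_max=400,
    )
    out = tmp_path_factory.mktemp("demo") / "experiment"
    simulate_experiment(cfg, out)
    return cfg, out
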