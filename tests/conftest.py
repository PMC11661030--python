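import numpy as np
import pandas as pd
import pytest

import genotoxpca as g


@pytest.fixture(scope="session")
def four_panel():
    return g.builtin_panel("FOUR")


@pytest.fixture(scope="session")
def twelve_panel():
    return g.builtin_panel("TWELVE")


def tiny_config(seed=0, noise_sd=0.25, gthc_slope=1.0, n_replicates=3):
    """Two-chemical study (one GTHC, one NGTNHC), four genes, three doses."""
    doses = (g.DoseLevel.LOW, g.DoseLevel.MIDDLE, g.DoseLevel.HIGH)
    return g.SyntheticConfig(
        panel=g.builtin_panel("FOUR"),
        chemicals=(
            ("DEN", g.ChemClass.GTHC, doses),
            ("ASP", g.ChemClass.NGTNHC, doses),
        ),
        n_replicates=n_replicates,
        noise_sd=noise_sd,
        effect={g.ChemClass.GTHC: gthc_slope},
        seed=seed,
    )


@pytest.fixture
def tiny_study():
    return g.generate_study(tiny_config(seed=7))


@pytest.fixture(scope="session")
def study_24h():
    """Default 23-chemical 24 h study under the standard conditions."""
    cfg = g.paper24h_config(seed=0)
    table, truth = g.generate_study(cfg)
    return cfg, table, truth


@pytest.fixture(scope="session")
def ratios_24h(study_24h, four_panel):
    _, table, _ = study_24h
    return g.expression_to_ratios(table, panel=four_panel)


@pytest.fixture(scope="session")
def random_ratio_matrix():
    """Deterministic 20x4 ratio matrix with row/column labels."""
    rng = np.random.default_rng(42)
    data = pd.DataFrame(
        rng.normal(0.3, 1.0, size=(20, 4)),
        columns=["Bax", "Btg2", "Ccng1", "Cdkn1a"],
        index=[f"CHEM{i}24hL" for i in range(20)],
    )
    return g.RatioMatrix(data)
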