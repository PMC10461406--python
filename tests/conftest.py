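import numpy as np
import pandas as pd
import pytest

from crisprcomp.synthetic_data import SimulationConfig, simulate_screen


@pytest.fixture(scope="session")
def null_screen():
    """Small screen with every fitness effect zero (pure null)."""
    cfg = SimulationConfig(n_genes=200, n_nt_guides=200,
                           frac_shared_essential=0.0,
                           frac_species_specific=0.0, frac_suppressor=0.0,
                           frac_mismatch_in_B=0.0, line_activity_sd=0.0,
                           seed=101)
    library, truth, counts, design = simulate_screen(cfg)
    return cfg, library, truth, counts, design


@pytest.fixture(scope="session")
def effect_screen():
    """Screen with shared and species-specific effects at default settings."""
    cfg = SimulationConfig(n_genes=300, n_nt_guides=200, seed=202,
                           frac_mismatch_in_B=0.0)
    library, truth, counts, design = simulate_screen(cfg)
    return cfg, library, truth, counts, design


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def guide_gene_map(library: pd.DataFrame) -> pd.Series:
    return library.loc[~library["is_nt"]].set_index("guide_id")["gene"]
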