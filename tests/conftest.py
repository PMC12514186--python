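import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from axoprop import synthetic

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def default_sim():
    """One default simulated dataset (counts, metadata, orthologs, truth)."""
    cfg = synthetic.SimConfig(n_genes=2000, seed=1)
    ortho = synthetic.simulate_ortholog_table(
        cfg.n_genes, cfg.length_log_sd,
        seed=synthetic.spawn_seeds(cfg.seed, 1)[0])
    counts, meta, truth = synthetic.simulate_counts(cfg, ortho)
    return counts, meta, ortho, truth


@pytest.fixture(scope="session")
def lfc_pairs_default():
    """The default paired-lfc fixture (generator defaults, seed 1)."""
    return synthetic.simulate_lfc_pairs(seed=1)


@pytest.fixture()
def pair_table_from_fixture(lfc_pairs_default):
    """A contrast-pair table where every gene is both-significant, built
    from the paired-lfc fixture (intra columns are placeholders)."""
    df = lfc_pairs_default
    return pd.DataFrame(
        {"lfc_x": df["x"].to_numpy(), "padj_x": 0.01,
         "lfc_y": df["y"].to_numpy(), "padj_y": 0.01,
         "lfc_intra": 0.0, "padj_intra": 1.0},
        index=pd.Index([f"g{i}" for i in range(len(df))], name="gene_id"))


@pytest.fixture(scope="session")
def noiseless_phantom():
    cfg = synthetic.PhantomConfig(species="jerboa", intensity_noise_sd=0.0)
    profile, lengths = synthetic.simulate_tail_phantom(cfg)
    return cfg, profile, lengths


def rectangle_profile(plateau_px: int, lead: int = 5,
                      lo: float = 0.0, hi: float = 1.0) -> np.ndarray:
    values = np.full(lead * 2 + plateau_px, lo)
    values[lead:lead + plateau_px] = hi
    return values
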