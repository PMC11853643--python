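import numpy as np
import pytest

from gitdsp.kg import EntityCatalog, build_kg
from gitdsp.synthetic import SyntheticConfig, generate


@pytest.fixture
def toy_catalog():
    return EntityCatalog(
        ids=["circ:c0", "circ:c1", "circ:c2", "dis:d0", "dis:d1",
             "mi:m0", "mi:m1", "lnc:l0"],
        types=["circRNA", "circRNA", "circRNA", "disease", "disease",
               "miRNA", "miRNA", "lncRNA"])


@pytest.fixture
def toy_tables(toy_catalog):
    import pandas as pd
    return {
        "circ-dis": pd.DataFrame({"head": ["circ:c0", "circ:c1", "circ:c2"],
                                  "tail": ["dis:d0", "dis:d0", "dis:d1"]}),
        "circ-mi": pd.DataFrame({"head": ["circ:c0"], "tail": ["mi:m0"]}),
        "mi-dis": pd.DataFrame({"head": ["mi:m0", "mi:m1"],
                                "tail": ["dis:d1", "dis:d0"]}),
    }


@pytest.fixture
def toy_kg(toy_tables, toy_catalog):
    return build_kg(toy_tables, toy_catalog)


@pytest.fixture(scope="session")
def default_synth():
    """Default-shape planted KG (79/330/404/265 entities, 1327 associations)."""
    return generate(SyntheticConfig(seed=7))


@pytest.fixture
def micro_synth_config():
    """Tiny planted dataset for fast end-to-end structural tests."""
    return SyntheticConfig(n_disease=10, n_circ=24, n_lnc=12, n_mi=12,
                          n_associations=120, latent_rank=4,
                          held_out_fraction=0.2, seed=3)


def micro_model_kwargs(seed=0, **over):
    """Smallest consistent estimator geometry for structural tests."""
    kw = dict(embedding_dim=8, n_heads=2, encoder_layers=1, ffn_hidden=8,
              layer_widths=(4, 2), krl_epochs=2, krl_lr=1e-2,
              krl_batch_size=256, pred_epochs=2, pred_lr=1e-2,
              pred_batch_size=256, neg_ratio=2, similar_exclusion_k=2,
              random_state=seed)
    kw.update(over)
    return kw
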