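import numpy as np
import pandas as pd
import pytest

from aldlipid.chem import build_catalog, default_templates


@pytest.fixture(scope="session")
def templates():
    return default_templates()


@pytest.fixture(scope="session")
def lpc_pc_catalog(templates):
    """Catalog over the LPC and PC class grids only (fast queries)."""
    return build_catalog([templates["LPC"], templates["PC"]])


@pytest.fixture()
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture()
def toy_table(rng):
    """5 lipids x 6 samples of positive abundances."""
    lipids = ["LPC(24:0)", "LPC(26:0)", "PC(44:2)", "TG(62:1)", "SM(34:1)"]
    samples = [f"S{i}" for i in range(6)]
    data = rng.lognormal(3.0, 0.4, size=(5, 6))
    return pd.DataFrame(data, index=lipids, columns=samples)
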