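import numpy as np
import pandas as pd
import pytest

from ribofate.core import CountMatrix
from ribofate.simulate import preset_params, simulate_all


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def minimal_sim_dir(tmp_path_factory):
    """Full synthetic input set at the smallest preset, written once."""
    out = tmp_path_factory.mktemp("sim") / "minimal"
    simulate_all("minimal", seed=7, out_dir=out)
    return out


@pytest.fixture(scope="session")
def minimal_params():
    return preset_params("minimal")


def make_count_matrix(counts: dict, assay="total", condition="control",
                      library_size=None):
    """Small CountMatrix helper: counts maps sample name -> gene vector."""
    df = pd.DataFrame(counts)
    df.index = [f"g{i}" for i in range(len(df))]
    meta = pd.DataFrame(
        {
            "assay": [assay] * df.shape[1],
            "condition": [condition] * df.shape[1],
            "replicate": list(range(1, df.shape[1] + 1)),
        },
        index=df.columns,
    )
    if library_size is not None:
        meta["library_size"] = library_size
    return CountMatrix(counts=df, sample_meta=meta)
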