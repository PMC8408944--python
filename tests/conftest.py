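import numpy as np
import pandas as pd
import pytest

from sibflow import core_expr, motif, syndata


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_cm():
    """5 genes x 6 cells, two states, handcrafted counts."""
    genes = [f"g{i}" for i in range(5)]
    cells = [f"c{i}" for i in range(6)]
    counts = pd.DataFrame(
        np.array(
            [
                [5, 6, 4, 0, 1, 0],
                [0, 1, 0, 7, 8, 6],
                [3, 3, 3, 3, 3, 3],
                [0, 0, 0, 0, 0, 0],
                [2, 1, 2, 1, 2, 1],
            ]
        ),
        index=genes,
        columns=cells,
    )
    meta = pd.DataFrame(
        {
            "stage": ["s1"] * 6,
            "treatment": ["control"] * 6,
            "state": ["X", "X", "X", "Y", "Y", "Y"],
        },
        index=cells,
    )
    gmeta = pd.DataFrame({"is_tf": [True, True, False, False, False]}, index=genes)
    return core_expr.CountMatrix(counts=counts, cells=meta, genes=gmeta)


@pytest.fixture(scope="session")
def ets_pwm():
    return motif.PWM.from_counts("ETSLIKE", syndata.default_pwms()["ETSLIKE"])


@pytest.fixture(scope="session")
def ctrl_pwm():
    return motif.PWM.from_counts("CTRLMOTIF", syndata.default_pwms()["CTRLMOTIF"])


@pytest.fixture(scope="session")
def default_edges_df():
    spec = syndata.default_spec(seed=0)
    return pd.DataFrame(
        list(spec.edges), columns=["parent_state", "child_state", "stage"]
    )


@pytest.fixture(scope="session")
def sim_bundle(tmp_path_factory):
    """A small end-to-end fixture bundle shared across tests."""
    outdir = tmp_path_factory.mktemp("bundle")
    spec = syndata.default_spec(seed=7, cells_per_state=30)
    paths = syndata.write_fixture_bundle(str(outdir), spec)
    return spec, paths, str(outdir)
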