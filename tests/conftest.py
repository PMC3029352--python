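import numpy as np
import pandas as pd
import pytest

import nodclass as nc
from nodclass.data_model_io import NODULE_CONDITIONS


def make_dataset(values: dict[str, list[float]], n_reps: int = 2, panel: str = "nodule"):
    """Build a tiny dataset where each condition's replicates all equal the
    given per-condition value (plus a deterministic jitter so variance > 0)."""
    probes = sorted(values)
    conds = NODULE_CONDITIONS if panel == "nodule" else nc.ROOT_CONDITIONS
    cols = pd.MultiIndex.from_tuples(
        [(c, r + 1) for c in conds for r in range(n_reps)],
        names=["condition", "replicate"],
    )
    rows = []
    for i, p in enumerate(probes):
        row = []
        for j, c in enumerate(conds):
            for r in range(n_reps):
                row.append(values[p][j] + 0.001 * (r - (n_reps - 1) / 2))
        rows.append(row)
    mat = pd.DataFrame(rows, index=pd.Index(probes, name="probe"), columns=cols)
    return nc.ExpressionDataset(values=mat, panel=panel)


@pytest.fixture(scope="session")
def noise_free_run():
    """Noise-free default simulation plus its calls and class assignment."""
    sim = nc.default_nodule_config(n_per_class=10, noise_sd=0.0, seed=7)
    dataset, truth = nc.generate_nodule_dataset(sim)
    calls = nc.call_regulation(dataset)
    assignment = nc.classify_dataset(calls)
    return dataset, truth, calls, assignment


@pytest.fixture()
def rng():
    return np.random.default_rng(20110127)
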