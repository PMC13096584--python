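import numpy as np
import pandas as pd
import pytest

import liverspatial as ls
from liverspatial.synth import GroupSpec


@pytest.fixture(scope="session")
def spatial_data():
    """Default-condition spatial dataset: 2000 spots, 4 samples, beta=1."""
    cfg = ls.SynthConfig(seed=11, n_spots=2000)
    counts, meta, ab, truth = ls.simulate_spatial(cfg)
    return cfg, counts, meta, ab, truth


@pytest.fixture(scope="session")
def spatial_scores(spatial_data):
    """Module scores of the CV / PV marker signatures on the spatial data."""
    _, counts, meta, ab, truth = spatial_data
    norm = ls.normalize_log1p(counts)
    sigs = ls.SignatureSet({"CV": truth.cv_markers, "PV": truth.pv_markers})
    return ls.score_all(norm, sigs, seed=5)


@pytest.fixture(scope="session")
def sc_data():
    """Two-group single-cell dataset with planted type markers."""
    cfg = ls.SynthConfig(
        seed=7, n_genes=300, sc_n_cells_per_group=1200, sc_markers_per_type=5,
        sc_groups={
            "young": GroupSpec({"T": 0.25, "B": 0.25, "NK": 0.25, "Mac": 0.25}),
            "old": GroupSpec({"T": 0.25, "B": 0.25, "NK": 0.25, "Mac": 0.25}),
        },
    )
    counts, meta, truth = ls.simulate_single_cell(cfg)
    return cfg, counts, meta, truth


@pytest.fixture()
def tiny_counts():
    return ls.CountMatrix(
        ["obs1", "obs2", "obs3"], ["geneA", "geneB"],
        np.array([[1, 0], [2, 3], [0, 5]]),
    )


@pytest.fixture()
def tiny_meta():
    return pd.DataFrame({
        "obs_id": ["obs1", "obs2", "obs3"],
        "sample_id": ["s1", "s1", "s2"],
        "group": ["young", "young", "old"],
    })
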