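import numpy as np
import pandas as pd
import pytest

import retarray as ra


@pytest.fixture(scope="session")
def small_study():
    """A modest noisy study with planted effects, shared across tests."""
    design = ra.StudyDesign(n_neg=7, n_pos=10, n_probes=1000, probes_per_gene=2)
    matrix, meta, truth = ra.generate_study(
        design, noise_sd=0.5, distortion_degree=3, seed=11, n_de_genes=50)
    return design, matrix, meta, truth


@pytest.fixture()
def tiny_matrix():
    """4 probes x 4 samples with hand-checkable values."""
    return pd.DataFrame(
        np.array([
            [1.0, 1.0, 0.0, 0.0],
            [5.0, 6.0, 5.0, 6.0],
            [2.0, 4.0, 8.0, 10.0],
            [3.0, 3.0, 3.0, 3.0],
        ]),
        index=pd.Index(["p1", "p2", "p3", "p4"], name="probe_id"),
        columns=["s1", "s2", "s3", "s4"],
    )
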