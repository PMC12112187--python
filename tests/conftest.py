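import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import ita

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def hrg_data():
    """Shared fate-transition-like synthetic dataset with its ground truth."""
    spec = ita.SyntheticSpec(n_genes=6000, cp_count=500, mode="hrg_like", seed=1)
    m, truth = ita.generate(spec)
    return spec, m, truth


@pytest.fixture(scope="session")
def hrg_partition(hrg_data):
    """Detected CP/PES partition of the shared dataset."""
    _, m, _ = hrg_data
    v = ita.compute_rmsf(m)
    g = ita.group_by_variability(v, k=40, min_group=50)
    peaks = ita.detect_cp_peaks(ita.ratio_curves(m, g))
    assert peaks is not None
    part = ita.partition(v, ita.standardize_cp_interval(peaks), peak_interval=peaks)
    return v, part


@pytest.fixture(scope="session")
def hrg_metrics(hrg_data, hrg_partition):
    """Full-protocol bootstrap tables for the shared dataset."""
    _, m, _ = hrg_data
    _, part = hrg_partition
    et, mt = ita.bootstrap_metrics(m, part, ita.BootstrapConfig(seed=3))
    return et, mt


@pytest.fixture()
def tiny_matrix():
    """3 genes x 3 time points with values 1..9."""
    return ita.ExpressionMatrix(
        gene_ids=("g1", "g2", "g3"),
        time_points_min=np.array([0.0, 10.0, 20.0]),
        values=np.arange(1.0, 10.0).reshape(3, 3),
        condition_label="tiny",
    )
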