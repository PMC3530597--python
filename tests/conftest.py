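import numpy as np
import pandas as pd
import pytest

from cnvburden.config import SimulationConfig
from cnvburden.synthetic import gen_marker_map


@pytest.fixture(scope="session")
def small_map() -> pd.DataFrame:
    """8 chromosomes x 1500 markers on 50 Mb (~33 kb spacing)."""
    return gen_marker_map(8, 1500, seed=11)


@pytest.fixture(scope="session")
def dense_map() -> pd.DataFrame:
    """One chromosome, 10 kb marker spacing (for boundary-sensitive tests)."""
    n = 1000
    return pd.DataFrame(
        {
            "marker_id": [f"m{i:04d}" for i in range(n)],
            "chromosome": "1",
            "position_bp": np.arange(1, n + 1) * 10_000,
            "is_cnv_probe": False,
        }
    )


@pytest.fixture
def noise_free_config() -> SimulationConfig:
    """Two callers observing truth perfectly; no QC failures."""
    return SimulationConfig(
        n_samples_per_cohort={"c1": 300, "c2": 300},
        cnv_rate=0.3,
        caller_boundary_jitter_bp=0,
        caller_miss_rate=0.0,
        split_probability=0.0,
        bad_lrr_fraction=0.0,
        noisy_cnv_fraction=0.0,
        n_duplicate_pairs=0,
        seed=5,
    )


def make_call(sample, chrom, start, end, cn, caller="X", n_markers=1):
    return {
        "sample_id": sample,
        "caller_id": caller,
        "chromosome": str(chrom),
        "start_bp": int(start),
        "end_bp": int(end),
        "copy_number": int(cn),
        "n_markers": int(n_markers),
    }
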