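import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite", derandomize=True, max_examples=40, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_probe_table(cn: np.ndarray, chrom: str = "chr1", sample_id: str = "T1",
                     spacing: int = 3000, gc: float | np.ndarray = 0.45) -> pd.DataFrame:
    """Evenly spaced probe table around a given copy-number signal."""
    n = len(cn)
    pos = spacing * np.arange(1, n + 1)
    gc_arr = np.full(n, gc, dtype=float) if np.isscalar(gc) else np.asarray(gc)
    return pd.DataFrame({
        "sample_id": sample_id,
        "probe_id": [f"{chrom}_p{i}" for i in range(n)],
        "chrom": chrom, "pos": pos, "cn": np.asarray(cn, float), "gc": gc_arr,
    })


def make_segments(rows, sample_id="T1") -> pd.DataFrame:
    """Rows of (chrom, start, end, n_markers, cn) -> segment table."""
    return pd.DataFrame(
        [(sample_id, *r) for r in rows],
        columns=["sample_id", "chrom", "start", "end", "n_markers", "cn"])
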