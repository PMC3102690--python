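import numpy as np
import pandas as pd
import pytest

from pbmlin.io import PBMSample


def make_sample(sequences, intensities, n_cols=None, log_base=None,
                name="test") -> PBMSample:
    """Small PBMSample on a row-major grid from parallel lists."""
    n = len(sequences)
    if n_cols is None:
        n_cols = int(np.ceil(np.sqrt(n)))
    rows = np.arange(n) // n_cols + 1
    cols = np.arange(n) % n_cols + 1
    probes = pd.DataFrame({
        "probe_id": [f"p{i}" for i in range(n)],
        "row": rows, "col": cols,
        "sequence": list(sequences),
        "intensity": np.asarray(intensities, dtype=float),
    })
    return PBMSample(probes, grid_shape=(int(rows.max()), n_cols),
                     log_base=log_base, name=name)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_sample(rng):
    """40 random 12-mer probes with positive intensities."""
    bases = np.array(list("ACGT"))
    seqs = ["".join(bases[rng.integers(0, 4, 12)]) for _ in range(40)]
    intens = rng.uniform(50.0, 5000.0, size=40)
    return make_sample(seqs, intens)
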