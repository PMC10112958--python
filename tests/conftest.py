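import logging

import numpy as np
import pytest

from msrdb.asv_io import AsvTable


@pytest.fixture(autouse=True)
def _quiet_logs(caplog):
    # keep expected warnings (zero columns, clipping) out of the report noise
    logging.getLogger("msrdb").setLevel(logging.ERROR)
    yield


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_sequences(rng, n, length=60):
    bases = np.array(list("ACGT"))
    return {
        f"asv{i:03d}": "".join(bases[rng.integers(0, 4, size=length)])
        for i in range(n)
    }


def random_table(rng, n_samples=8, n_asvs=6, depth=500, with_group=True):
    counts = rng.integers(1, depth, size=(n_samples, n_asvs))
    group = None
    if with_group:
        group = np.array(
            ["a"] * (n_samples // 2) + ["b"] * (n_samples - n_samples // 2),
            dtype=object,
        )
    return AsvTable(
        counts=counts,
        sample_ids=[f"S{i}" for i in range(n_samples)],
        asv_ids=[f"asv{j:03d}" for j in range(n_asvs)],
        group=group,
    )
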