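import numpy as np
import pytest

from flexdegree.evidence import NeuronRecord


def make_records(K, S, cell_type="t"):
    """Build NeuronRecords from parallel degree / synapse-count sequences."""
    return [NeuronRecord(f"n{i}", cell_type, int(k), int(s))
            for i, (k, s) in enumerate(zip(K, S))]


@pytest.fixture
def rng():
    return np.random.default_rng(20240817)
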