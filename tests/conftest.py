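import numpy as np
import pytest

import triazopep as tp


@pytest.fixture(scope="session")
def panel_records():
    """The shipped 23-compound characterized panel."""
    return tp.load_reference_panel()


@pytest.fixture(scope="session")
def panel_sequences(panel_records):
    return {r.id: r.parsed() for r in panel_records}


@pytest.fixture(scope="session")
def panel_graphs(panel_sequences):
    return {cid: tp.assemble_graph(seq)
            for cid, seq in panel_sequences.items()}


@pytest.fixture(scope="session")
def panel_descriptors(panel_sequences):
    return tp.build_descriptor_matrix(list(panel_sequences.items()))


@pytest.fixture(scope="session")
def panel_inhibition(panel_records):
    return np.array([r.inh for r in panel_records])
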