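import numpy as np
import pytest

from tetragate import synthetic


@pytest.fixture(scope="session")
def closed_tetramer():
    return synthetic.make_tetramer(synthetic.CLOSED_SPEC, label="4C")


@pytest.fixture(scope="session")
def open_tetramer():
    return synthetic.make_tetramer(synthetic.OPEN_SPEC, label="4O")


@pytest.fixture(scope="session")
def tiny_tetramer():
    """Small channel (80 atoms) for contact/occupancy statistics."""
    spec = synthetic.ChannelSpec(n_residues_per_subunit=5, atom_spacing=2.5,
                                 axial_span=8.0, gate_residue_number=4867)
    return synthetic.make_tetramer(spec, label="tiny")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
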