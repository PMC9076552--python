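import numpy as np
import pytest

from cysexpose import synthetic_data


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def toy_complex():
    return synthetic_data.gen_toy_complex(seed=7)


@pytest.fixture(scope="session")
def toy_structures(tmp_path_factory, toy_complex):
    from cysexpose.cys_survey import Structure

    d = tmp_path_factory.mktemp("pdb")
    (d / "active.pdb").write_text(toy_complex["pdb_active"])
    (d / "deactive.pdb").write_text(toy_complex["pdb_deactive"])
    return (
        Structure.from_pdb(d / "active.pdb"),
        Structure.from_pdb(d / "deactive.pdb"),
    )
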