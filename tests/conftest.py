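import pytest

import protocell as pc


@pytest.fixture(scope="session")
def canonical() -> pc.ParameterSet:
    return pc.canonical_parameters()


@pytest.fixture(scope="session")
def toy_analytic() -> pc.Fixture:
    return pc.generate_fixtures("toy_analytic")


@pytest.fixture(scope="session")
def toy_membrane() -> pc.Fixture:
    return pc.generate_fixtures("toy_membrane")


@pytest.fixture(scope="session")
def toy_dna() -> pc.Fixture:
    return pc.generate_fixtures("toy_dna")


@pytest.fixture()
def minimal_config() -> dict:
    """Smallest valid parameter document: one self-replicator."""
    return {
        "species": {
            "rpc": {
                "role": "self_replicator",
                "n_monomers": 7336.0,
                "monomer_kind": "aa",
                "k_rate": 20.26,
            }
        }
    }
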