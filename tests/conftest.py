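import numpy as np
import pytest

import sedchiro as sc


@pytest.fixture(scope="session")
def ch_primers():
    return sc.CH_PRIMERS


@pytest.fixture(scope="session")
def small_bundle():
    """Noisy synthetic experiment shared by read-processing tests."""
    cfg = sc.SimulationConfig(seed=1, reads_per_sample=300)
    return sc.simulate_all(cfg)


@pytest.fixture(scope="session")
def noiseless_bundle():
    """Error-free experiment: no chimeras, numts, contaminants or errors."""
    cfg = sc.SimulationConfig(
        seed=5,
        reads_per_sample=250,
        chimera_rate=0.0,
        numt_rate=0.0,
        contaminant_rate=0.0,
        dip_fraction=0.0,
        base_quality=80,
    )
    return sc.simulate_all(cfg)


def lineage(**ranks):
    return sc.Lineage.of(**ranks)


@pytest.fixture
def chironomid_lineage():
    def make(genus=None, species=None, family="Chironomidae"):
        return sc.Lineage.of(
            kingdom="Animalia",
            phylum="Arthropoda",
            order="Diptera",
            family=family,
            genus=genus,
            species=species,
            **{"class": "Insecta"},
        )

    return make


@pytest.fixture
def flat_quality():
    def make(seq, q=40, read_id="r", sample=""):
        return sc.QualityRead(read_id, seq, np.full(len(seq), q), sample=sample)

    return make
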