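import pytest

import irinopbpk as ip
from irinopbpk.compound_model import partition_coefficients
from irinopbpk.config import builtin_compound


@pytest.fixture(scope="session")
def reference_individual():
    return ip.build_reference_individual()


@pytest.fixture(scope="session")
def compounds():
    return [builtin_compound(k) for k in ("cpt11", "sn38", "sn38g")]


@pytest.fixture(scope="session")
def kps(reference_individual, compounds):
    compositions = {
        name: {"water_fraction": o.water_fraction,
               "lipid_fraction": o.lipid_fraction}
        for name, o in reference_individual.organs.items()
    }
    return {c.name: partition_coefficients(c, compositions) for c in compounds}


@pytest.fixture(scope="session")
def regimen():
    return ip.DoseRegimen()


@pytest.fixture(scope="session")
def model(reference_individual, compounds, kps):
    return ip.assemble_model(reference_individual, compounds, kps,
                             ip.irinotecan_network())


@pytest.fixture(scope="session")
def observed():
    return ip.reference_observed_dataset()


def make_model_for(individual, compounds, kps, network):
    return ip.assemble_model(individual, compounds, kps, network)
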