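import pytest

from nucleokin import reference_data
from nucleokin.mechanism import CampaignTruth, ExperimentDesign, generate_campaign


@pytest.fixture(scope="session")
def table1():
    return reference_data.load_table1()


@pytest.fixture(scope="session")
def table1_by_label(table1):
    return {r.label: r for r in table1}


@pytest.fixture(scope="session")
def table2():
    return reference_data.load_table2()


@pytest.fixture(scope="session")
def table3():
    return reference_data.load_table3()


@pytest.fixture
def design():
    return ExperimentDesign()


@pytest.fixture(scope="session")
def small_truth():
    return CampaignTruth(
        N_true=9.37,
        sN_true=1.18,
        electrophiles={"A": -8.4, "B": -7.2, "C": -6.7, "D": -5.1},
    )


@pytest.fixture(scope="session")
def noiseless_campaign(small_truth):
    return generate_campaign(small_truth, ExperimentDesign(noise_sd=0.0), seed=7)
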