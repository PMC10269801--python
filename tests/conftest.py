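import pytest

from cfm_diatom.config import cell_parameters, default_config


@pytest.fixture
def config():
    return default_config()


@pytest.fixture
def diatom(config):
    return cell_parameters(config, "diatom")


@pytest.fixture
def other(config):
    return cell_parameters(config, "other")


@pytest.fixture
def diatom_no_si(config):
    return cell_parameters(config, "diatom_no_si")
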