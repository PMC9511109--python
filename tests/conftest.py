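import pytest

from psmcea import CostEffectivenessModel, default_config


@pytest.fixture(scope="session")
def config():
    """The bundled published-model configuration (single source of inputs)."""
    return default_config()


@pytest.fixture(scope="session")
def base_results(config):
    """Deterministic base-case results under default toggles."""
    return CostEffectivenessModel(config).fit()


@pytest.fixture(scope="session")
def chemo_os(config):
    return config.strategies[config.comparator].os.build()


@pytest.fixture(scope="session")
def chemo_pfs(config):
    return config.strategies[config.comparator].pfs.build()


@pytest.fixture(scope="session")
def sug_os(config):
    return config.strategies[config.intervention].os.build()


@pytest.fixture(scope="session")
def sug_pfs(config):
    return config.strategies[config.intervention].pfs.build()
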