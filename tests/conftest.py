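import pytest

from phytomfg_tea import emit_config, run_pipeline


@pytest.fixture(scope="session")
def base_config():
    return emit_config("base")


@pytest.fixture(scope="session")
def base_result(base_config):
    return run_pipeline(base_config)


@pytest.fixture(scope="session")
def spinach_result():
    return run_pipeline(emit_config("spinach"))


@pytest.fixture(scope="session")
def tobacco_result():
    return run_pipeline(emit_config("tobacco"))
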