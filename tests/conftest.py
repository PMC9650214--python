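import pytest

from her2low_cea import load_base_case


@pytest.fixture(scope="session")
def base_config():
    return load_base_case()


@pytest.fixture(scope="session")
def overall(base_config):
    return base_config.cohort("overall")


@pytest.fixture(scope="session")
def hr_neg(base_config):
    return base_config.cohort("hr_neg")
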