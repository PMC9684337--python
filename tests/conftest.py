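import pytest

import bipolarce as b


@pytest.fixture(scope="session")
def params():
    return b.default_parameters()


@pytest.fixture(scope="session")
def lifetable():
    return b.synthesize_lifetable()


@pytest.fixture(scope="session")
def short_params(params):
    """Defaults with a 20-cycle (5-year) horizon for faster runs."""
    from dataclasses import replace

    return replace(params, settings=replace(params.settings, horizon=20))
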