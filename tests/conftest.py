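import pytest

from breakeven import load_rabbit_sinus_lift


@pytest.fixture(scope="session")
def rabbit_table():
    return load_rabbit_sinus_lift()


@pytest.fixture(scope="session")
def rabbit_series(rabbit_table):
    """Bundled series keyed by (study, material)."""
    return {(s.study_label, s.material): s for s in rabbit_table.to_series()}
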