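import pytest

from ohca_survival import DecayParams, Municipality


@pytest.fixture
def default_params() -> DecayParams:
    return DecayParams()  # s0=1, r=0.07, t0=0


@pytest.fixture
def norwegian_cohort() -> list[Municipality]:
    """The four published municipality mean response times."""
    return [
        Municipality("Bergen", "big city", 10.2),
        Municipality("Tokke", "mountain", 16.6),
        Municipality("Lurøy", "island", 32.8),
        Municipality("Sørfold", "rural", 22.6),
    ]
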