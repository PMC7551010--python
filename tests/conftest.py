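import hypothesis.strategies as st
import pytest
from hypothesis import HealthCheck, settings

from ivifmea import AttributeWeights, IVIFNumber, load_case_study

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=100,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@st.composite
def ivif_numbers(draw, min_hesitation: float = 0.0) -> IVIFNumber:
    """Uniformly-ish sampled valid IVIF numbers.

    Draws mu_lo <= mu_hi, then non-membership bounds inside the remaining
    budget so that mu_hi + nu_hi <= 1 - min_hesitation holds by construction.
    """
    a = draw(st.floats(0.0, 1.0 - min_hesitation))
    b = draw(st.floats(a, 1.0 - min_hesitation))
    d = draw(st.floats(0.0, 1.0 - min_hesitation - b))
    c = draw(st.floats(0.0, d))
    return IVIFNumber(a, b, c, d)


@st.composite
def positive_exponents(draw) -> float:
    return draw(st.floats(0.01, 8.0))


@pytest.fixture(scope="session")
def case_study() -> tuple[list, AttributeWeights]:
    return load_case_study()


@pytest.fixture(scope="session")
def case_profiles(case_study):
    return case_study[0]


@pytest.fixture(scope="session")
def case_weights(case_study) -> AttributeWeights:
    return case_study[1]
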