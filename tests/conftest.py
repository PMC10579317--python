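import numpy as np
import pytest

from fundusqc.assessment import ClassicalBackend
from fundusqc.synthetic import DefectSpec, FundusSpec, apply_defects, generate_clean_fundus


@pytest.fixture(scope="session")
def clean_posterior():
    return generate_clean_fundus(FundusSpec(width=96, height=96,
                                            location="posterior", seed=7))


@pytest.fixture(scope="session")
def clean_peripheral():
    return generate_clean_fundus(FundusSpec(width=96, height=96,
                                            location="peripheral", seed=7))


@pytest.fixture(scope="session")
def classical():
    return ClassicalBackend()


@pytest.fixture(scope="session")
def black_peripheral():
    img = generate_clean_fundus(FundusSpec(width=96, height=96,
                                           location="peripheral", seed=7))
    return apply_defects(
        img, DefectSpec(illumination_strength=1.0, illumination_region="whole")
    ).image
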