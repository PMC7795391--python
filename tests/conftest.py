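import pytest

from cantisense import (
    CantileverGeometry,
    ContractileLoad,
    ElasticMaterial,
)


@pytest.fixture
def pdms() -> ElasticMaterial:
    """PDMS substrate at 10:1 base:curing agent."""
    return ElasticMaterial(young_modulus=750.0, poisson_ratio=0.49)


@pytest.fixture
def cm_film() -> ElasticMaterial:
    """Cardiomyocyte monolayer film."""
    return ElasticMaterial(young_modulus=188.0, poisson_ratio=0.49)


@pytest.fixture
def geom_long() -> CantileverGeometry:
    """The 9000 x 3000 um cantilever, 100 um substrate, 10 um film."""
    return CantileverGeometry(9000.0, 3000.0, 100.0, 10.0)


@pytest.fixture
def geom_short() -> CantileverGeometry:
    """The 3000 x 1000 um cantilever used for the perforation studies."""
    return CantileverGeometry(3000.0, 1000.0, 100.0, 10.0)


@pytest.fixture
def load2() -> ContractileLoad:
    """Resting-twitch contractile stress of 2 nN/um^2."""
    return ContractileLoad(film_stress=2.0)
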