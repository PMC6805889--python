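import pytest

from agroshift import land_use_optimizer as luo
from agroshift.synthetic_data import CONVENTIONAL, ORGANIC, EconomySpec, generate_economy


@pytest.fixture(scope="session")
def toy_spec():
    return EconomySpec(n_farm_types=2, n_food_crops=3, n_livestock=2)


@pytest.fixture(scope="session")
def toy_economy(toy_spec):
    return generate_economy(toy_spec, seed=7)


@pytest.fixture(scope="session")
def toy_solutions(toy_economy):
    return {
        system: luo.solve_lp(luo.build_lp(toy_economy, system))
        for system in (CONVENTIONAL, ORGANIC)
    }
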