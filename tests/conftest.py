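import numpy as np
import pytest

from fragsar.core_data import Archipelago, Island, circle_perimeter
from fragsar.sampler import SamplerConfig, build_ensemble
from fragsar.synthetic import SynthConfig, generate_archipelago


def circular_island(iid: str, area: float, dist: float = 0.0, inflate: float = 1.0) -> Island:
    """An island whose perimeter is `inflate` times its equal-area circle's."""
    return Island(id=iid, area=area, perimeter=inflate * circle_perimeter(area),
                  dist_mainland=dist)


@pytest.fixture
def four_islands() -> list[Island]:
    return [circular_island(f"i{k}", float(a), dist=100.0 * k, inflate=1.2)
            for k, a in enumerate([1, 2, 3, 4], start=1)]


@pytest.fixture
def tiny_arch(four_islands) -> Archipelago:
    # occupancies: s1 on all 4, s2 on 2, s3 on 1
    inc = np.array(
        [
            [1, 1, 1, 1],
            [0, 1, 1, 0],
            [0, 0, 0, 1],
        ],
        dtype=bool,
    )
    return Archipelago(islands=four_islands, species_ids=["s1", "s2", "s3"], incidence=inc)


@pytest.fixture(scope="session")
def small_arch() -> Archipelago:
    """A 40-island, 60-species synthetic archipelago for mid-weight tests."""
    return generate_archipelago(
        SynthConfig(n_islands=40, n_species=60, seed=11, b_override=1.0)
    )


@pytest.fixture(scope="session")
def small_ensemble(small_arch):
    cfg = SamplerConfig(pn_min=2, pn_max=8, n_sections=3, n_reps=20, seed=5)
    return build_ensemble(small_arch, cfg), cfg
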