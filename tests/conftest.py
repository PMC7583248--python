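import numpy as np
import pytest

from larfam.alignment import Scoring, default_scoring
from larfam.cli import write_demo_bundle
from larfam.io_formats import AMINO_ACIDS
from larfam.synthetic_data import FamilySimConfig, simulate_family


def random_protein(rng, length):
    letters = np.array(list(AMINO_ACIDS))
    return "".join(letters[rng.integers(0, 20, size=length)])


@pytest.fixture(scope="session")
def scoring() -> Scoring:
    return default_scoring()


@pytest.fixture(scope="session")
def demo_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("demo")
    write_demo_bundle(out, seed=0)
    return out


@pytest.fixture(scope="session")
def default_family():
    """Default synthetic family (5 groups x 10 members, no indels)."""
    return simulate_family(FamilySimConfig(seed=0))


@pytest.fixture(scope="session")
def noise_free_family():
    """Family whose members differ from the reference only at anchors."""
    return simulate_family(
        FamilySimConfig(
            n_groups=5,
            members_per_group=4,
            background_mutation_rate=0.0,
            group_divergence_rate=0.0,
            indel_rate=0.0,
            seed=0,
        )
    )
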