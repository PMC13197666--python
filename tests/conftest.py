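import numpy as np
import pytest

from lbamix import substitution_models as sm
from lbamix import trees_io
from lbamix.simulate import simulate_alignment


@pytest.fixture(scope="session")
def farris_tree():
    return trees_io.load_fixture_tree("farris")


@pytest.fixture(scope="session")
def felsenstein_tree():
    return trees_io.load_fixture_tree("felsenstein")


@pytest.fixture(scope="session")
def quartet():
    return trees_io.fixture_clade_config()["quartet"]


@pytest.fixture(scope="session")
def wag_homogeneous():
    return sm.SubstitutionModel.homogeneous("WAG", alpha=0.6, ncat=4)


@pytest.fixture(scope="session")
def sharp_mixture_model():
    """Calibrated-sharpness synthetic heterogeneous model (Z ~ 7 at 2k sites)."""
    rng = np.random.default_rng(42)
    base = sm.FrequencyProfile(sm.get_default_frequencies("WAG"))
    mix = sm.sample_profile_mixture(100, base, 3.0, 1.0, rng)
    return sm.SubstitutionModel(
        sm.get_exchangeability("WAG"), mix, sm.discrete_gamma_rates(0.6, 4)
    )


@pytest.fixture(scope="session")
def hom_alignment_1k(felsenstein_tree, wag_homogeneous):
    rng = np.random.default_rng(1)
    return simulate_alignment(felsenstein_tree, wag_homogeneous, 1000, rng)


@pytest.fixture(scope="session")
def het_alignment_1k(felsenstein_tree, sharp_mixture_model):
    rng = np.random.default_rng(1)
    return simulate_alignment(felsenstein_tree, sharp_mixture_model, 1000, rng)
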