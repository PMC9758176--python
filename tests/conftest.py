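import numpy as np
import pytest

from founderhap.simulate import founder_demo_config, simulate_genotypes

# Table-1-style diploid genotype patterns at the five panel sites
SITES = (36_214_971, 36_216_426, 36_217_798, 36_220_134, 36_246_117)


def pattern(g1, g2, g3, g4, risk):
    return dict(zip(SITES, (g1, g2, g3, g4, risk)))


ALPHA_HOM = pattern("GG", "GG", "GG", "CC", "AA")
BETA_HOM = pattern("AA", "AA", "AA", "TT", "AA")
ALPHA_CARRIER = pattern("GG", "GG", "GG", "CT", "AT")
BETA_CARRIER = pattern("AG", "AG", "AG", "TT", "AT")
NON_CARRIER = pattern("GG", "GG", "GG", "TT", "TT")


@pytest.fixture(scope="session")
def demo_matrix():
    """Two-founder synthetic panel: P1/P2 alpha-hom, P3/H1 beta-hom, carriers."""
    return simulate_genotypes(founder_demo_config(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(20_260_925)
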