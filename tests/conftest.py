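import numpy as np
import pytest

from kinoreg import PocketAnnotation, SimConfig
from kinoreg.simulate import simulate_compounds, simulate_kinases, simulate_pairs


@pytest.fixture
def tiny_pocket() -> PocketAnnotation:
    return PocketAnnotation(
        kinase_id="K1",
        sequence="ACDEFGHIKL",
        ss8="GHITEBSCGH",
        rsa=np.linspace(0.0, 1.0, 10),
        pocket_volume=450.0,
    )


@pytest.fixture
def small_sim():
    """A small synthetic screen: 6 kinases x 5 compounds, 12 descriptors."""
    cfg = SimConfig(
        n_kinases=6, n_compounds=5, pair_fraction=1.0,
        pocket_length_range=(8, 14), extreme_low_weight=0.3,
        extreme_high_weight=0.3, signal_strength=5.0, noise_sd=2.0,
        latent_dim=2, seed=123,
    )
    kinases = simulate_kinases(cfg)
    compounds = simulate_compounds(cfg, n_descriptors=12)
    pairs, truth = simulate_pairs(cfg, kinases, compounds, return_truth=True)
    return cfg, kinases, compounds, pairs, truth
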