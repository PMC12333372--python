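import numpy as np
import pytest

from rcdmlp.geometry import AtomicConfiguration
from rcdmlp.rc_graph import RadialBasisSpec
from rcdmlp.delta_model import DpHyperParams, MaceHyperParams, init_model


TOY_CODES = [1, 8, 15, 58]


@pytest.fixture(scope="session")
def basis():
    return RadialBasisSpec(r_cut=6.0, n_bessel=8, envelope_order=5)


@pytest.fixture(scope="session")
def small_config():
    """4 QM + 3 MM atoms in a compact cluster."""
    rng = np.random.default_rng(3)
    species = np.array([8, 15, 8, 1, 8, 8, 8])
    region = np.array(["QM"] * 4 + ["MM"] * 3, dtype=object)
    pos = rng.normal(scale=2.0, size=(7, 3))
    return AtomicConfiguration(species, pos, region)


@pytest.fixture(scope="session")
def mace_model(basis):
    hp = MaceHyperParams(
        L=1, T=2, nu=3, N=8, l_max=2, radial_mlp=(8, 8), readout_channels=8,
        basis=basis,
    )
    return init_model("mace_like", hp, TOY_CODES, seed=0)


@pytest.fixture(scope="session")
def dp_model(basis):
    hp = DpHyperParams(
        fitting_layers=(16, 16), embedding_layers=(4, 8, 16), axis_filters=12,
        basis=basis,
    )
    return init_model("dp_like", hp, TOY_CODES, seed=1)


def fd_forces(model_or_pot, config, h=1e-4):
    """Central finite-difference forces for any energy provider."""
    from rcdmlp.delta_model import CorrectionModel, delta_energy_forces

    def energy(cfg):
        if isinstance(model_or_pot, CorrectionModel):
            return delta_energy_forces(model_or_pot, cfg).energy
        e, _ = model_or_pot.energy_forces_batch(cfg.positions)
        return float(e)

    f = np.zeros_like(config.positions)
    for i in range(config.n_atoms):
        for a in range(3):
            for sgn in (1, -1):
                p = config.positions.copy()
                p[i, a] += sgn * h
                f[i, a] -= sgn * energy(config.with_positions(p)) / (2 * h)
    return f
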