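import pytest

from soedkit.photophysics import photofrin_params


@pytest.fixture(scope="session")
def invitro_params():
    """Photofrin in water/Intralipid at 632 nm (phantom conditions)."""
    return photofrin_params("in_vitro_632")


@pytest.fixture(scope="session")
def meoh_params():
    """Photofrin in MeOH at 523 nm (luminescence conditions)."""
    return photofrin_params("in_vitro_523_meoh")


@pytest.fixture(scope="session")
def invivo_params():
    return photofrin_params("in_vivo_632")


@pytest.fixture(scope="session")
def invivo_params_523():
    return photofrin_params("in_vivo_523")


@pytest.fixture(scope="session")
def fig5_kernel():
    """One Monte Carlo pencil kernel at the strongest phantom absorption."""
    from soedkit.fluence import OpticalProperties, mc_pencil_kernel

    return mc_pencil_kernel(
        OpticalProperties(0.58, 0.2), n_photons=1_000_000, seed=2024
    )
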