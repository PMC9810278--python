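import numpy as np
import pytest

from gsmring import gsm, ssn


@pytest.fixture(scope="session")
def tiny_model() -> gsm.GSMModel:
    """3-latent, 6x6-patch GSM instance, small enough for brute-force oracles."""
    return gsm.GSMModel.default(
        n_latents=3,
        patch_side=6,
        sigma_x2=1.0,
        kernel_params=gsm.RingKernel(variance=1.0, width_deg=40.0),
    )


@pytest.fixture(scope="session")
def default_model() -> gsm.GSMModel:
    return gsm.GSMModel.default()


@pytest.fixture(scope="session")
def small_ring() -> ssn.RingNetwork:
    """8-pair ring with mild weights; stable under all tests that use it."""
    return ssn.build_ring(
        params=ssn.RingParams(
            n_pairs=8,
            w_ee=1.0,
            w_ie=1.5,
            w_ei=1.0,
            w_ii=0.5,
            noise_sd=0.5,
            ff_gain=0.3,
            baseline=2.0,
            baseline_i=1.0,
            patch_side=8,
        )
    )


@pytest.fixture(scope="session")
def nt_network() -> ssn.RingNetwork:
    """The package's calibrated NT reference network."""
    return ssn.build_ring(params=ssn.default_nt_params())
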