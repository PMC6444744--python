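import pytest

import radbundle as rb


@pytest.fixture
def device() -> rb.DeviceParams:
    """Default bare device: K_T=25 N/m, F_T=1 kHz, eta_T=1e-5 N s/m."""
    return rb.DeviceParams()


@pytest.fixture
def geom() -> rb.BundleGeometry:
    """Reference bundle: M=1800, E=350 MPa, A=3.2e-18 m^2, l=15 um."""
    return rb.BundleGeometry.reference()


@pytest.fixture
def kin() -> rb.KineticsParams:
    """Reference kinetics: b=1/s, beta=8.1e-7."""
    return rb.KineticsParams(b=1.0, beta=8.1e-7)


@pytest.fixture
def deg() -> rb.DegradationParams:
    """Reference decay value phi=0.7."""
    return rb.DegradationParams(phi=0.7)


@pytest.fixture
def schedule() -> rb.IrradiationSchedule:
    """Reference protocol: four 210 s sessions of 30 Gy, 180 s gaps."""
    return rb.make_schedule(4, 210.0, 180.0, 30.0)


@pytest.fixture
def noiseless() -> rb.NoiseModel:
    return rb.NoiseModel(0.0, 0.0, 0.0)
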