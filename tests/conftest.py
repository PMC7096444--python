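import numpy as np
import pytest

from borondose import (
    EnergyGrid,
    NeutronFieldCalibration,
    RangeEnergyModel,
    TumorSpec,
    build_sobp,
    load_packaged_table,
    neutron_spectrum,
    proton_spectrum_in_tumor,
)


@pytest.fixture(scope="session")
def tissue_model():
    return RangeEnergyModel(density=1.1)


@pytest.fixture(scope="session")
def shallow_tumor():
    return TumorSpec(depth_interval=(1.6, 3.0))


@pytest.fixture(scope="session")
def deep_tumor():
    return TumorSpec(depth_interval=(10.0, 11.3))


@pytest.fixture(scope="session")
def shallow_beam(tissue_model):
    return build_sobp(1.6, 3.0, tissue_model, 12)


@pytest.fixture(scope="session")
def deep_beam(tissue_model):
    return build_sobp(10.0, 11.3, tissue_model, 12)


@pytest.fixture(scope="session")
def shallow_proton_spectrum(shallow_beam, shallow_tumor):
    grid = EnergyGrid.covering(float(np.max(shallow_beam.peak_energies)))
    return proton_spectrum_in_tumor(shallow_beam, shallow_tumor, grid)


@pytest.fixture(scope="session")
def deep_proton_spectrum(deep_beam, deep_tumor):
    grid = EnergyGrid.covering(float(np.max(deep_beam.peak_energies)))
    return proton_spectrum_in_tumor(deep_beam, deep_tumor, grid)


@pytest.fixture(scope="session")
def b11_table():
    return load_packaged_table()


@pytest.fixture(scope="session")
def mcnpx_calibration():
    return NeutronFieldCalibration.mcnpx_like()


@pytest.fixture(scope="session")
def deep_neutron_spectrum(mcnpx_calibration):
    return neutron_spectrum(11.3, mcnpx_calibration)


@pytest.fixture(scope="session")
def shallow_neutron_spectrum(mcnpx_calibration):
    return neutron_spectrum(3.0, mcnpx_calibration)
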