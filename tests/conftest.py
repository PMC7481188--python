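import numpy as np
import pytest

from cdtomo import InstrumentResponse, OpticalSlab, ScanGrid, prototype_grid

#: Prototype polyurethane-foam slab coefficients.
PROTO = dict(mu_a=5.26e-3, mu_s_prime=2.62, n_medium=1.12, z_d=2.54)


@pytest.fixture(scope="session")
def proto_slab() -> OpticalSlab:
    return OpticalSlab(**PROTO)


@pytest.fixture(scope="session")
def proto_grid() -> ScanGrid:
    return prototype_grid()


@pytest.fixture(scope="session")
def small_grid() -> ScanGrid:
    return ScanGrid(nx=8, ny=8, pitch=70 / 31)


@pytest.fixture(scope="session")
def irf() -> InstrumentResponse:
    return InstrumentResponse(irf_fwhm=0.070)


@pytest.fixture(scope="session")
def sharp_irf() -> InstrumentResponse:
    return InstrumentResponse(irf_fwhm=0.0)


@pytest.fixture(scope="session")
def proto_kernels(proto_slab, proto_grid):
    """One-way and two-way kernels on the prototype grid (nt long enough
    that the two-way tail is negligible at the window edge)."""
    from cdtomo import sampled_kernel, two_way_kernel

    one = sampled_kernel(proto_slab, proto_grid.pitch, proto_grid.pitch,
                         0.032, proto_grid.nx, proto_grid.ny, 160)
    return one, two_way_kernel(one)
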