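import numpy as np
import pytest

import gofold as gf


@pytest.fixture(scope="session")
def u_chain():
    return gf.synth.make_u_chain()


@pytest.fixture(scope="session")
def u_topology(u_chain):
    return gf.build_topology(u_chain)


@pytest.fixture(scope="session")
def hairpin30():
    return gf.synth.make_helix_hairpin(30)


@pytest.fixture(scope="session")
def hairpin30_topology(hairpin30):
    return gf.build_topology(hairpin30)


@pytest.fixture(scope="session")
def table2_gdmcl_fl():
    """Published GdmCl fluorescence parameters of the full-length domain."""
    return gf.ChemicalFit(dG0=6.7, m=2.9, s0_n=304.0, s0_u=147.0)


@pytest.fixture(scope="session")
def table2_urea_fl():
    """Published urea fluorescence parameters of the full-length domain."""
    return gf.ChemicalFit(dG0=7.1, m=1.45, s0_n=693.0, s0_u=461.0)


@pytest.fixture(scope="session")
def thermal_full():
    """Published thermal parameters of the full-length domain (CD melt)."""
    return gf.ThermalFit(dH=92.0, tm_K=70.5 + 273.15, dCp=1.9,
                         s0_n=-14.3, s0_u=-0.8)


@pytest.fixture(scope="session")
def thermal_truncated():
    """Published thermal parameters of the tail-truncated variant."""
    return gf.ThermalFit(dH=28.0, tm_K=40.4 + 273.15, dCp=1.0,
                         s0_n=-14.0, s0_u=-4.1)


def brute_force_contacts(coords, rmin=4.0, rmax=6.0, min_sep=4):
    """Independent O(n²) enumeration of the native-contact rule."""
    out = []
    n = len(coords)
    for i in range(n):
        for j in range(i + min_sep, n):
            d = float(np.linalg.norm(coords[i] - coords[j]))
            if rmin <= d <= rmax:
                out.append((i, j, d))
    return out
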