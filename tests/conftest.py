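import numpy as np
import pytest

from septinsim.models import ComplexVariant, build_lattice, default_lattice_spec
from septinsim.phantom import DensityVolume, GridParams


@pytest.fixture(scope="session")
def blob_volume():
    """Small asymmetric two-blob phantom for reconstruction tests."""
    n = 48
    grid = GridParams((n, n, n), 1.0)
    zz, yy, xx = np.mgrid[0:n, 0:n, 0:n].astype(float) - (n - 1) / 2
    vals = np.exp(
        -((zz - 4) ** 2 + (yy + 3) ** 2 + (xx - 6) ** 2) / (2 * 3.0**2)
    ) + 0.7 * np.exp(
        -((zz + 6) ** 2 + yy**2 + (xx + 5) ** 2) / (2 * 4.0**2)
    )
    return DensityVolume(grid, vals)


@pytest.fixture(scope="session")
def sharp_volume():
    """Phantom with signal out to mid frequencies (wedge-power tests)."""
    n = 64
    grid = GridParams((n, n, n), 1.0)
    zz, yy, xx = np.mgrid[0:n, 0:n, 0:n].astype(float) - (n - 1) / 2
    vals = (
        np.exp(-((zz - 4) ** 2 + (yy + 3) ** 2 + (xx - 6) ** 2)
               / (2 * 1.5**2))
        + 0.7 * np.exp(-((zz + 6) ** 2 + yy**2 + (xx + 5) ** 2)
                       / (2 * 2.0**2))
        + 0.5 * np.exp(-(zz**2 + (yy - 8) ** 2 + (xx + 2) ** 2)
                       / (2 * 1.5**2))
    )
    return DensityVolume(grid, vals)


@pytest.fixture(scope="session")
def wt_gic1_lattice():
    spec = default_lattice_spec(
        ComplexVariant.WT_GIC1, n_filaments=2, n_repeats=3
    )
    return build_lattice(spec, ComplexVariant.WT_GIC1, seed=0)


def side_view_of(variant, n_filaments=2, n_repeats=3,
                 grid_shape=(96, 128, 256), voxel=7.3):
    """Noise-free side-view projection of a bridged cable."""
    from septinsim.phantom import render_projection
    from septinsim.pipelines import bridge_sigma_for, subunit_sigma_for

    spec = default_lattice_spec(
        variant, n_filaments=n_filaments, n_repeats=n_repeats
    )
    lat = build_lattice(spec, variant, seed=0)
    grid = GridParams(grid_shape, voxel)
    img = render_projection(
        lat, grid, "side",
        subunit_sigma=subunit_sigma_for(spec),
        bridge_sigma=bridge_sigma_for(spec),
    )
    return img, spec
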