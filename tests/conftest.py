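"""Shared fixtures: small grids and the (expensive) end-to-end phantom runs."""

import numpy as np
import pytest

from dwiqc.grid import GridSpec
from dwiqc.pipelines import run_icewater_qc, run_sphere_study


@pytest.fixture(scope="session")
def small_grid():
    """9x9x3 grid, 2 mm isotropic, isocentre on the central voxel centre."""
    return GridSpec.centered((9, 9, 3), (2.0, 2.0, 2.0))


@pytest.fixture(scope="session")
def icewater_noiseless():
    """Noiseless, unbiased ice-water QC run (2 repeats, coarse supersampling)."""
    return run_icewater_qc(seed=1, noise_sd=0.0, n_repeats=2, supersample=2)


@pytest.fixture(scope="session")
def sphere_noiseless():
    """Noiseless sphere-phantom study with the contaminating low-signal background."""
    return run_sphere_study(seed=0, noise_sd=0.0, n_repeats=1)


@pytest.fixture(scope="session")
def sphere_no_contrast():
    """Control: background rendered with the same S0 and ADC as the spheres."""
    return run_sphere_study(seed=0, noise_sd=0.0, n_repeats=1,
                            background_s0=1000.0, background_adc=2.0e-3)
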