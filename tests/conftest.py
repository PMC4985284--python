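"""Shared fixtures: synthetic runs reused across the decomposition tests.

Simulation sizes are reduced relative to routine experimental acquisition
(coarser radial grid, 10 min scan intervals over 6 h) so the full suite runs
quickly; the physics oracles that depend on absolute accuracy use the
experimental 20 um grid directly.
"""

from __future__ import annotations

import numpy as np
import pytest

from photosv import (
    CellGeometry,
    Photoswitcher,
    SedimentingSpecies,
    SolventModel,
)
from photosv.decomposition import ComponentSpec, build_signal_basis, fit_mcmc
from photosv.synthetic import (
    SyntheticComponent,
    SyntheticRunConfig,
    default_scan_times,
    generate_synthetic,
)

# coarse-but-faithful settings used by the fitting tests
TEST_DR = 0.005          # 50 um radial grid
TEST_DT = 30.0           # internal time step bound (s)
MIX_NOISE = 0.005        # 0.5% of total loading, typical FDS acquisition noise
STABLE_S = 4.25          # BSA-monomer-like stable component (on the s-grid)
SWITCH_S = 2.5           # rsEGFP2-like switching component
S_GRID = np.arange(0.5, 8.01, 0.25)


@pytest.fixture(scope="session")
def geometry() -> CellGeometry:
    return CellGeometry()


@pytest.fixture(scope="session")
def water() -> SolventModel:
    return SolventModel()


@pytest.fixture(scope="session")
def stable_switcher() -> Photoswitcher:
    return Photoswitcher(name="DL488", epsilon0=1.0, alpha=1.0, beta=0.0)


@pytest.fixture(scope="session")
def off_switcher() -> Photoswitcher:
    # free rsEGFP2 under a 13 mW scanning beam
    return Photoswitcher(name="rsEGFP2", epsilon0=1.0, alpha=0.0274, beta=5.5e-4)


@pytest.fixture(scope="session")
def mixture_config(geometry, stable_switcher, off_switcher) -> SyntheticRunConfig:
    """Stable + off-switching mixture, equal signal shares, noise-free."""
    return SyntheticRunConfig(
        components=[
            SyntheticComponent(
                SedimentingSpecies(s=STABLE_S, loading_signal=0.5), stable_switcher
            ),
            SyntheticComponent(
                SedimentingSpecies(s=SWITCH_S, loading_signal=0.5), off_switcher
            ),
        ],
        geometry=geometry,
        scan_times=default_scan_times(600.0, 21600.0),
        dr=TEST_DR,
        noise_sd=0.0,
        dt_max=TEST_DT,
    )


@pytest.fixture(scope="session")
def mixture_clean(mixture_config):
    """Noise-free mixture scan set plus its ground-truth sidecar."""
    return generate_synthetic(mixture_config)


@pytest.fixture(scope="session")
def mixture_noisy(geometry, stable_switcher, off_switcher):
    cfg = SyntheticRunConfig(
        components=[
            SyntheticComponent(
                SedimentingSpecies(s=STABLE_S, loading_signal=0.5), stable_switcher
            ),
            SyntheticComponent(
                SedimentingSpecies(s=SWITCH_S, loading_signal=0.5), off_switcher
            ),
        ],
        geometry=geometry,
        scan_times=default_scan_times(600.0, 21600.0),
        dr=TEST_DR,
        noise_sd=MIX_NOISE,
        seed=7,
        dt_max=TEST_DT,
    )
    return generate_synthetic(cfg)


@pytest.fixture(scope="session")
def mixture_components(stable_switcher, off_switcher):
    return [
        ComponentSpec("DL488", stable_switcher),
        ComponentSpec("rsEGFP2", off_switcher),
    ]


@pytest.fixture(scope="session")
def mixture_basis(mixture_clean, mixture_components, geometry):
    scans, _ = mixture_clean
    return build_signal_basis(
        mixture_components, S_GRID, geometry, scans.times, scans.radii,
        dt_max=TEST_DT,
    )


@pytest.fixture(scope="session")
def mixture_fit(mixture_noisy, mixture_components, geometry, mixture_basis):
    scans, _ = mixture_noisy
    return fit_mcmc(
        scans, mixture_components, S_GRID, geometry=geometry, dt_max=TEST_DT,
        basis=mixture_basis,
    )


@pytest.fixture(scope="session")
def switching_scans(geometry, off_switcher):
    """Single off-switching component with realistic noise (for impostor tests)."""
    cfg = SyntheticRunConfig(
        components=[
            SyntheticComponent(
                SedimentingSpecies(s=SWITCH_S, loading_signal=1.0), off_switcher
            )
        ],
        geometry=geometry,
        scan_times=default_scan_times(600.0, 21600.0),
        dr=TEST_DR,
        noise_sd=MIX_NOISE,
        seed=3,
        dt_max=TEST_DT,
    )
    scans, _ = generate_synthetic(cfg)
    return scans
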