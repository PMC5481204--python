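"""Shared fixtures.

The parameter-recovery and verdict tests all consume the same set of
global fits of simulated two-wavelength experiments (four samples x ten
seeds), so those fits are computed once per session here.
"""

from __future__ import annotations

import dataclasses

import pytest

from baseflip.fitting import FitOptions, GlobalFitResult, fit_global
from baseflip.simulate import AcquisitionSettings, PRESET_NAMES, simulate_experiment

RECOVERY_SEEDS = tuple(range(10))


@pytest.fixture(scope="session")
def acquisition() -> AcquisitionSettings:
    """Study acquisition conditions (80 ps IRF, 4096 ch / 50 ns, 1e7 photons)."""
    return AcquisitionSettings()


@pytest.fixture(scope="session")
def small_acquisition() -> AcquisitionSettings:
    """Reduced problem size for fast solver behaviour tests."""
    return AcquisitionSettings(
        channels=1024, window=30.0, total_signal_photons=2e5, irf_center=1.0
    )


@pytest.fixture(scope="session")
def preset_fits(acquisition) -> dict[str, dict[int, GlobalFitResult]]:
    """Global 4-component fits of each preset over the recovery seeds.

    For every sample the two emission wavelengths are simulated at 1e7
    signal photons and fitted globally with shared lifetimes.
    """
    fits: dict[str, dict[int, GlobalFitResult]] = {}
    options = FitOptions(n_starts=3)
    for name in PRESET_NAMES:
        fits[name] = {}
        for seed in RECOVERY_SEEDS:
            settings = dataclasses.replace(acquisition, seed=seed)
            measurements = simulate_experiment([name], settings)
            fits[name][seed] = fit_global(measurements, settings.irf, 4, options)
    return fits
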