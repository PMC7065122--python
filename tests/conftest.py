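"""Shared fixtures.

Most unit tests run on a reduced 96x96 / 4-coil / 3-slice configuration for
speed; acceptance-level tests that need the full-size default scenario share
the session-scoped fixtures below so the expensive simulations and the
four-arm experiment run only once per session.
"""

from __future__ import annotations

import numpy as np
import pytest

import navmoco as nm
from navmoco.synthetic import _echo_kspaces


@pytest.fixture(scope="session")
def small_schedule() -> nm.AcquisitionSchedule:
    return nm.AcquisitionSchedule(matrix_size=(96, 96), n_slices=3,
                                  n_imaging_echoes=6, navigator_echo_index=7)


@pytest.fixture(scope="session")
def small_phantom() -> nm.PhantomModel:
    return nm.make_phantom((96, 96), rng_seed=0)


@pytest.fixture(scope="session")
def small_coils(small_phantom) -> nm.CoilProfiles:
    return nm.make_coil_profiles(small_phantom, ncoils=4, rng_seed=1)


@pytest.fixture(scope="session")
def small_clean_ds(small_phantom, small_coils, small_schedule):
    """Noise-free, motion-free small dataset."""
    return nm.simulate_mese_kspace(small_phantom, small_coils, small_schedule,
                                   motion=None, noise_sd=0.0, rng_seed=0)


@pytest.fixture(scope="session")
def full_phantom() -> nm.PhantomModel:
    return nm.make_phantom((192, 192), rng_seed=0)


@pytest.fixture(scope="session")
def full_coils(full_phantom) -> nm.CoilProfiles:
    return nm.make_coil_profiles(full_phantom, ncoils=10, rng_seed=1)


@pytest.fixture(scope="session")
def full_schedule() -> nm.AcquisitionSchedule:
    return nm.AcquisitionSchedule()


@pytest.fixture(scope="session")
def full_kspace_echo1(full_phantom, full_coils):
    """Noise-free full-grid echo-1 k-space (ncoils, 192, 192)."""
    ks, kt = _echo_kspaces(full_phantom, full_coils, np.array([9.1]))
    return (ks + kt)[0]


@pytest.fixture(scope="session")
def full_kernels(full_kspace_echo1, full_schedule):
    """1/2-AMCL kernels calibrated on the noisy central region of the
    full-size phantom k-space."""
    from navmoco.grappa import calibrate_kernel, calibration_rows

    rng = np.random.default_rng(42)
    rows = calibration_rows(full_schedule)
    calib = full_kspace_echo1[:, rows, :]
    calib = calib + 0.01 * (rng.standard_normal(calib.shape)
                            + 1j * rng.standard_normal(calib.shape))
    return {kind: [calibrate_kernel(calib, kind=kind)]
            for kind in ("1-AMCL", "2-AMCL")}


@pytest.fixture(scope="session")
def full_combine_weights(full_kspace_echo1):
    from navmoco._fft import ifft2c
    from navmoco.grappa import rss_combine_weights

    return rss_combine_weights(ifft2c(full_kspace_echo1))


@pytest.fixture(scope="session")
def default_experiment():
    """The default four-arm experiment report (run once per session)."""
    cfg = nm.ExperimentConfig()
    report = nm.run_experiment(cfg, seed=1)
    return cfg, report
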