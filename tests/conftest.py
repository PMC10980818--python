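import warnings

import numpy as np
import pandas as pd
import pytest

import propsim as ps


@pytest.fixture
def optics45():
    return ps.OpticsConfig(tilt_phi=45.0, sheet_sigma=0.0, pixel_pitch=1.0, z_max=95.0)


@pytest.fixture
def bead_volume():
    """Small random bead phantom with its ground-truth table."""
    vol, table = ps.make_bead_phantom((96, 64, 64), (1.0, 1.0, 1.0), n=20, seed=42,
                                      amplitude=100.0, sigma=1.5)
    return vol, table


def stratified_bead_volume(shape=(96, 64, 64), spacing_z=2.0, sigma=1.5, seed=0):
    """Beads stratified in z (one per spacing_z) at scattered (x, y)."""
    rng = np.random.default_rng(seed)
    zs = np.arange(6.0, shape[0] - 7.0, spacing_z)
    table = pd.DataFrame(
        {
            "x": rng.uniform(8, shape[2] - 9, len(zs)),
            "y": rng.uniform(8, shape[1] - 9, len(zs)),
            "z": zs,
            "amplitude": 100.0,
            "sigma": sigma,
        }
    )
    return ps.make_bead_phantom(shape, (1.0, 1.0, 1.0), beads=table)


def topdown_acq(volume, optics, width=1e9, c0=0.0, tau=0.0, duration=1.0,
                frame_shape=None, row_origin=None, rate=None):
    """Convenience acquisition: synchronized shutter, optional view rate."""
    sweep = ps.default_sweep(volume, optics, duration=duration)
    shear = ps.ShearWaveform(rate_r=rate if rate is not None else 1.0 / optics.sin_phi)
    shutter = ps.ShutterConfig(width_W=width, center_c0=c0, delay_tau=tau)
    return ps.AcquisitionConfig(optics=optics, sweep=sweep, shear=shear,
                                shutter=shutter, frame_shape=frame_shape,
                                row_origin=row_origin)


def quiet_simulate(volume, acq):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return ps.simulate_projection(volume, acq)
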