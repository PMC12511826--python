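"""Shared fixtures: one standard synthetic phantom reused across modules."""

import numpy as np
import pytest

import qusbead as q


@pytest.fixture(scope="session")
def pulse_spec():
    return q.PulseSpec()  # 6.6 MHz, 70 % fractional bandwidth, fs 40 MHz


@pytest.fixture(scope="session")
def phantom_frame(pulse_spec):
    """One standard phantom frame with bead, tumor and ground truth."""
    spec = q.PhantomSpec(seed=7)
    frame, gt = q.synthesize_rf(spec, pulse_spec)
    return spec, frame, gt


@pytest.fixture(scope="session")
def bmode(phantom_frame):
    _, frame, _ = phantom_frame
    return q.rf_to_bmode(frame)


@pytest.fixture(scope="session")
def bsf_template(bmode, phantom_frame):
    _, _, gt = phantom_frame
    patch = q.extract_patch(bmode, gt.bead_position_mm, q.default_template_shape(bmode))
    return q.build_bsf_template([patch])


@pytest.fixture(scope="session")
def sigma_bead_table(pulse_spec):
    return q.measure_bead_bsc(pulse_spec)


@pytest.fixture(scope="session")
def calibrated_config(pulse_spec):
    return q.BscConfig(band_hz=q.calibration_band(pulse_spec))


@pytest.fixture(scope="session")
def add_decoy():
    """Callable that injects a clean, strong bead-like echo train into a frame.

    The decoy is synthesized speckle-free at ``decoy_pos`` (mm) and scaled to
    ``strength`` x the host frame's RMS, so it out-shines the in-tumor bead.
    """

    def _add(frame, pulse_spec, decoy_pos, strength):
        decoy_spec = q.PhantomSpec(
            scatterer_density=0.0, tissue_attenuation_db_cm_mhz=0.0,
            tumor_center_mm=decoy_pos, tumor_axes_mm=(4.0, 4.0),
            bead=q.BeadSpec(position_mm=decoy_pos, echo_amplitude=1.0), seed=0)
        decoy_frame, _ = q.synthesize_rf(decoy_spec, pulse_spec)
        peak = np.abs(decoy_frame.samples).max()
        rms = float(np.sqrt(np.mean(frame.samples ** 2)))
        scaled = decoy_frame.samples * (strength * rms / peak)
        return q.RFFrame(samples=frame.samples + scaled, fs=frame.fs,
                         fc=frame.fc, pitch_mm=frame.pitch_mm, c=frame.c)

    return _add


@pytest.fixture(scope="session")
def tiny_unet_config():
    """Scaled-down 9-block network for fast unit tests."""
    return q.UNetConfig(block_channels=(2, 4, 8, 16, 32, 16, 8, 4, 2), input_size=32)
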