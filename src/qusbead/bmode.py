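"""RF-to-B-mode conversion.

The first stage of the pipeline: raw per-line echo voltage traces are
envelope-detected (magnitude of the analytic signal), normalized to their
maximum and log-compressed to a fixed dynamic range (60 dB by default).
No scan conversion is performed — frames come from a linear array, so axial
and lateral pixel spacings are carried as metadata instead
(axial dz = c / (2 fs), lateral dx = line pitch).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert
from skimage.transform import resize as _sk_resize

__all__ = [
    "RFFrame",
    "BModeImage",
    "envelope",
    "log_compress",
    "rf_to_bmode",
    "resize_image",
    "resize_mask",
]


@dataclass(frozen=True)
class RFFrame:
    """One frame of raw RF echo data plus acquisition geometry.

    Parameters
    ----------
    samples : ndarray, shape (n_axial, n_lines)
        Echo voltage samples; rows are depth (fast time), columns are lines.
    fs : float
        Sampling frequency in Hz.
    fc : float
        Transmit center frequency in Hz.
    pitch_mm : float
        Lateral spacing between adjacent lines in mm.
    c : float
        Speed of sound in m/s (default 1540).
    """

    samples: np.ndarray
    fs: float
    fc: float
    pitch_mm: float
    c: float = 1540.0

    def __post_init__(self):
        if self.fs <= 0:
            raise ValueError("sampling frequency must be positive")
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 2:
            raise ValueError("RF samples must be a 2-D (axial x lateral) array")
        object.__setattr__(self, "samples", samples)

    @property
    def dz_mm(self) -> float:
        """Axial sample spacing in mm (round-trip corrected): c / (2 fs)."""
        return self.c / (2.0 * self.fs) * 1e3

    @property
    def shape(self) -> tuple[int, int]:
        return self.samples.shape

    def mm_to_px(self, axial_mm: float, lateral_mm: float) -> tuple[int, int]:
        return int(round(axial_mm / self.dz_mm)), int(round(lateral_mm / self.pitch_mm))

    def px_to_mm(self, axial_px: float, lateral_px: float) -> tuple[float, float]:
        return axial_px * self.dz_mm, lateral_px * self.pitch_mm


@dataclass(frozen=True)
class BModeImage:
    """Envelope-detected, log-compressed image.

    ``intensity_db`` is 0 at the frame maximum and floored at
    ``-dynamic_range_db``; geometry mirrors the source :class:`RFFrame`.
    """

    intensity_db: np.ndarray
    dynamic_range_db: float
    fs: float
    fc: float
    pitch_mm: float
    c: float = 1540.0

    @property
    def dz_mm(self) -> float:
        return self.c / (2.0 * self.fs) * 1e3

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensity_db.shape

    def mm_to_px(self, axial_mm: float, lateral_mm: float) -> tuple[int, int]:
        return int(round(axial_mm / self.dz_mm)), int(round(lateral_mm / self.pitch_mm))

    def px_to_mm(self, axial_px: float, lateral_px: float) -> tuple[float, float]:
        return axial_px * self.dz_mm, lateral_px * self.pitch_mm

    def normalized(self) -> np.ndarray:
        """Map [-dynamic_range, 0] dB onto [0, 1] (for display / network input)."""
        return (self.intensity_db + self.dynamic_range_db) / self.dynamic_range_db

    def to_uint8(self) -> np.ndarray:
        return np.round(self.normalized() * 255.0).astype(np.uint8)


def envelope(rf: RFFrame | np.ndarray) -> np.ndarray:
    """Per-line envelope: magnitude of the analytic signal (Hilbert transform).

    Exact on band-limited lines; nonnegative by construction and even in the
    sign of the RF (``envelope(-rf) == envelope(rf)``).
    """
    samples = rf.samples if isinstance(rf, RFFrame) else np.asarray(rf, dtype=np.float64)
    if samples.ndim != 2 or samples.size == 0:
        raise ValueError("expected a non-empty 2-D RF array")
    if samples.shape[0] < 8:
        raise ValueError("need at least 8 axial samples per line")
    return np.abs(hilbert(samples, axis=0))


def log_compress(env: np.ndarray, dynamic_range_db: float = 60.0) -> np.ndarray:
    """Normalize an envelope to its maximum and compress to dB.

    Returns ``20 log10(env / max)`` clamped below at ``-dynamic_range_db``.
    An all-zero envelope has no defined normalization and is rejected.
    """
    env = np.asarray(env, dtype=np.float64)
    if np.any(env < 0):
        raise ValueError("envelope must be nonnegative")
    peak = env.max(initial=0.0)
    if peak <= 0:
        raise ValueError("all-zero envelope: normalization undefined")
    floor = 10.0 ** (-dynamic_range_db / 20.0)
    db = 20.0 * np.log10(np.maximum(env / peak, floor))
    return np.clip(db, -dynamic_range_db, 0.0)


def rf_to_bmode(rf: RFFrame, dynamic_range_db: float = 60.0) -> BModeImage:
    """Envelope-detect and log-compress a frame (the pipeline's step 1)."""
    db = log_compress(envelope(rf), dynamic_range_db)
    return BModeImage(
        intensity_db=db,
        dynamic_range_db=dynamic_range_db,
        fs=rf.fs,
        fc=rf.fc,
        pitch_mm=rf.pitch_mm,
        c=rf.c,
    )


def resize_image(image: np.ndarray, shape: tuple[int, int] = (256, 256)) -> np.ndarray:
    """Bilinear resize with half-pixel-centered coordinates.

    Used to bring B-mode frames to the network's input size. The inverse
    mapping for masks is :func:`resize_mask` back to the native frame shape.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.size == 0:
        raise ValueError("cannot resize an empty image")
    if image.shape == tuple(shape):
        return image.copy()
    return _sk_resize(image, shape, order=1, anti_aliasing=False, preserve_range=True)


def resize_mask(mask: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Nearest-neighbor resize for binary masks; output stays {0, 1} uint8."""
    mask = np.asarray(mask)
    if mask.size == 0:
        raise ValueError("cannot resize an empty mask")
    if mask.shape == tuple(shape):
        return (mask > 0).astype(np.uint8)
    out = _sk_resize(mask.astype(np.float64), shape, order=0, anti_aliasing=False,
                     preserve_range=True)
    return (out > 0.5).astype(np.uint8)
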