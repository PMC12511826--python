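"""Calibration-bead localization by template matching.

The embedded bead leaves a characteristic B-mode signature — a strong main
echo followed by a train of decaying reverberation echoes — called the bead
scattering function (BSF). A BSF template (the pixel-wise mean of a few
normalized labeled bead patches) is slid over each frame's dB-scale B-mode
image with normalized cross-correlation (NCC); the correlation peak gives
the bead position, and the frame with the strongest peak across a sweep is
the reference frame. Constraining the search to the segmented tumor
interior removes bead-like decoys outside the tumor.

NCC runs on float dB images (60 dB range). The reported position is the
template center; windows with zero intensity variance get coefficient 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.feature import match_template

from .bmode import BModeImage

__all__ = [
    "BSFTemplate", "BeadDetection", "build_bsf_template", "extract_patch",
    "default_template_shape", "ncc_map", "locate_bead", "select_bead_frame",
    "save_template", "load_template",
]

LOW_CONFIDENCE_NCC = 0.5


@dataclass(frozen=True)
class BSFTemplate:
    """Averaged, normalized bead-signature patch used as the NCC template."""

    patch: np.ndarray
    source_count: int

    @property
    def shape(self) -> tuple[int, int]:
        return self.patch.shape


@dataclass(frozen=True)
class BeadDetection:
    """NCC peak for one frame: position (template center, 0-based) and score."""

    frame_index: int
    axial_px: int
    lateral_px: int
    axial_mm: float
    lateral_mm: float
    ncc_peak: float
    constrained: bool
    low_confidence: bool


def build_bsf_template(patches: list[np.ndarray]) -> BSFTemplate:
    """Pixel-wise mean of per-patch zero-mean / unit-variance normalized patches."""
    if len(patches) == 0:
        raise ValueError("need at least one patch")
    shape = np.asarray(patches[0]).shape
    norm = []
    for p in patches:
        p = np.asarray(p, dtype=np.float64)
        if p.shape != shape:
            raise ValueError("all patches must share one size")
        std = p.std()
        if std == 0:
            raise ValueError("constant patch carries no bead signature")
        norm.append((p - p.mean()) / std)
    return BSFTemplate(patch=np.mean(norm, axis=0), source_count=len(patches))


def default_template_shape(bmode: BModeImage, bead_diameter_mm: float = 2.0,
                           axial_factor: float = 2.0,
                           lateral_factor: float = 1.5) -> tuple[int, int]:
    """Template extent in pixels: ``axial_factor`` x bead diameter axially (to
    cover the reverberation train), ``lateral_factor`` x laterally."""
    n_ax = max(3, int(round(axial_factor * bead_diameter_mm / bmode.dz_mm)))
    n_lat = max(3, int(round(lateral_factor * bead_diameter_mm / bmode.pitch_mm)))
    return n_ax, n_lat


def extract_patch(bmode: BModeImage, center_mm: tuple[float, float],
                  shape: tuple[int, int]) -> np.ndarray:
    """Cut a patch of given pixel shape centered at a mm position (clipped to
    the frame)."""
    r, c = bmode.mm_to_px(*center_mm)
    h, w = shape
    img = bmode.intensity_db
    r0 = int(np.clip(r - h // 2, 0, img.shape[0] - h))
    c0 = int(np.clip(c - w // 2, 0, img.shape[1] - w))
    return img[r0:r0 + h, c0:c0 + w].copy()


def _window_variance(image: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Variance of each valid sliding window (same layout as valid-mode NCC)."""
    h, w = shape
    area = h * w
    ones = np.ones(shape)
    s1 = ndimage.correlate(image, ones, mode="constant")
    s2 = ndimage.correlate(image * image, ones, mode="constant")
    r0, c0 = h // 2, w // 2
    hh, ww = image.shape[0] - h + 1, image.shape[1] - w + 1
    s1 = s1[r0:r0 + hh, c0:c0 + ww]
    s2 = s2[r0:r0 + hh, c0:c0 + ww]
    return np.maximum(s2 / area - (s1 / area) ** 2, 0.0)


def ncc_map(bmode: BModeImage | np.ndarray, template: BSFTemplate) -> np.ndarray:
    """Normalized cross-correlation coefficient at every offset.

    Returns a map with the frame's shape; entry (r, c) is the Pearson
    correlation between the template and the window whose *center* sits at
    (r, c). Border offsets where the template does not fit, and windows with
    zero variance, are 0 by convention. Values are clipped to [-1, 1].
    """
    image = bmode.intensity_db if isinstance(bmode, BModeImage) else np.asarray(bmode,
                                                                                dtype=np.float64)
    tpl = template.patch
    if tpl.shape[0] > image.shape[0] or tpl.shape[1] > image.shape[1]:
        raise ValueError("template larger than the frame")
    full = np.zeros(image.shape, dtype=np.float64)
    if tpl.std() == 0:
        return full
    valid = match_template(image, tpl, pad_input=False)
    var = _window_variance(image, tpl.shape)
    scale = max(image.std() ** 2, 1e-30)
    valid = np.where(var <= 1e-12 * scale, 0.0, valid)
    r0, c0 = tpl.shape[0] // 2, tpl.shape[1] // 2
    full[r0:r0 + valid.shape[0], c0:c0 + valid.shape[1]] = np.clip(valid, -1.0, 1.0)
    return full


def locate_bead(bmode: BModeImage, template: BSFTemplate,
                mask: np.ndarray | None = None, frame_index: int = 0,
                low_confidence_ncc: float = LOW_CONFIDENCE_NCC) -> BeadDetection:
    """Find the NCC peak, optionally restricted to template centers inside a
    tumor mask. Ties break toward the smallest axial, then lateral index."""
    cc = ncc_map(bmode, template)
    h, w = template.shape
    r0, c0 = h // 2, w // 2
    valid = np.zeros(cc.shape, dtype=bool)
    valid[r0:bmode.shape[0] - (h - 1 - r0), c0:bmode.shape[1] - (w - 1 - c0)] = True
    constrained = mask is not None
    if constrained:
        mask = np.asarray(mask)
        if mask.shape != cc.shape:
            raise ValueError("mask geometry must match the frame")
        if not mask.any():
            raise ValueError("mask is empty: nothing to search")
        valid &= mask > 0
        if not valid.any():
            raise ValueError("mask excludes every searchable offset")
    score = np.where(valid, cc, -np.inf)
    idx = int(np.argmax(score))  # C-order argmax == smallest axial, then lateral
    r, c = np.unravel_index(idx, score.shape)
    az_mm, lat_mm = bmode.px_to_mm(float(r), float(c))
    peak = float(cc[r, c])
    return BeadDetection(frame_index=frame_index, axial_px=int(r), lateral_px=int(c),
                         axial_mm=az_mm, lateral_mm=lat_mm, ncc_peak=peak,
                         constrained=constrained,
                         low_confidence=peak < low_confidence_ncc)


def save_template(template: BSFTemplate, path) -> None:
    """Persist a template as a 16-bit PNG plus a JSON sidecar carrying the
    value range and source count (NCC is scale-invariant, but the exact
    values are restored anyway)."""
    import json
    from pathlib import Path

    import imageio.v3 as iio

    path = Path(path)
    lo = float(template.patch.min())
    hi = float(template.patch.max())
    span = hi - lo if hi > lo else 1.0
    scaled = np.round((template.patch - lo) / span * 65535.0).astype(np.uint16)
    iio.imwrite(path, scaled)
    path.with_suffix(".json").write_text(json.dumps(
        {"min": lo, "max": hi, "source_count": template.source_count,
         "shape": list(template.shape)}))


def load_template(path) -> BSFTemplate:
    import json
    from pathlib import Path

    import imageio.v3 as iio

    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    scaled = np.asarray(iio.imread(path), dtype=np.float64) / 65535.0
    patch = scaled * (meta["max"] - meta["min"]) + meta["min"]
    return BSFTemplate(patch=patch, source_count=int(meta["source_count"]))


def select_bead_frame(detections: list[BeadDetection]) -> int:
    """Index (into the list) of the detection with maximal NCC peak; ties go
    to the lowest index. This frame provides the bead reference spectrum."""
    if len(detections) == 0:
        raise ValueError("no detections to select from")
    peaks = np.array([d.ncc_peak for d in detections])
    return int(np.argmax(peaks))
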