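"""Bead-referenced backscatter-coefficient (BSC) estimation and Gaussian-model
parameter extraction.

The segmented tumor is tiled into 3 mm x 3 mm data blocks (about ten pulse
lengths per side) with 75 % overlap. Each block's backscattered power
spectrum W(f) is a Hann-windowed, zero-padded, line-averaged periodogram of
the gated RF. The tissue BSC follows from the in situ calibration bead:

    sigma(f) = W(f) / W_bead(f) * sigma_bead(f)

where W_bead is the spectrum averaged across the bead surface and
sigma_bead the bead's known BSC curve. Because bead and tissue share the
transmission path, any system gain and any attenuation common to both
cancel exactly in the ratio — the property that makes the in situ reference
attractive.

Each block's BSC curve is then fitted with the spherical Gaussian model

    sigma(f) = EAC * (pi/2) d^6 k^4 exp(-2 k^2 d^2),      k = 2 pi f / c

by linear regression of ln sigma - 4 ln k on k^2: the slope gives the
characteristic dimension d (effective scatterer diameter ESD = 3.11 d) and
the intercept the effective acoustic concentration EAC = n_bar * gamma_0^2.
Fits with nonnegative slope or out-of-bounds d are marked invalid (stored at
the configured lower bound) and excluded from map summaries, mirroring the
sentinel convention for blocks that do not fit the Gaussian model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal.windows import hann

from .bmode import RFFrame
from .bead import BeadDetection

ESD_TO_D = 3.11

__all__ = [
    "ESD_TO_D", "Block", "BlockGrid", "tile_blocks", "bead_exclusion_zone",
    "BlockSpectrum", "block_power_spectrum", "bead_power_spectrum",
    "BeadReference", "make_bead_reference", "BSCCurve", "estimate_bsc",
    "GaussianFit", "SphericalGaussianModel", "fit_gaussian_model",
    "ParamMap", "build_param_map", "relative_error", "analysis_nfft",
]


# ---------------------------------------------------------------------------
# tiling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Block:
    """Half-open pixel ranges [r0, r1) x [c0, c1) plus grid position."""

    block_id: int
    row: int
    col: int
    r0: int
    r1: int
    c0: int
    c1: int

    def intersects(self, zone: tuple[int, int, int, int]) -> bool:
        zr0, zr1, zc0, zc1 = zone
        return self.r0 < zr1 and zr0 < self.r1 and self.c0 < zc1 and zc0 < self.c1


@dataclass
class BlockGrid:
    block_size_mm: float
    overlap_fraction: float
    n_rows: int
    n_cols: int
    blocks: list[Block]
    excluded: list[tuple[Block, str]] = field(default_factory=list)

    @property
    def excluded_reasons(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for _, reason in self.excluded:
            out[reason] = out.get(reason, 0) + 1
        return out


def bead_exclusion_zone(detection: BeadDetection, geometry,
                        gate_mm: float, bead_diameter_mm: float = 2.0,
                        lateral_factor: float = 1.5) -> tuple[int, int, int, int]:
    """Rectangle around the bead no data block may touch: axial extent equals
    the bead gate (main echo plus reverberation train), lateral extent
    ``lateral_factor`` x the bead diameter, centered on the detection."""
    half_ax = int(round(gate_mm / 2.0 / geometry.dz_mm))
    half_lat = int(round(lateral_factor * bead_diameter_mm / 2.0 / geometry.pitch_mm))
    return (detection.axial_px - half_ax, detection.axial_px + half_ax + 1,
            detection.lateral_px - half_lat, detection.lateral_px + half_lat + 1)


def tile_blocks(mask: np.ndarray, geometry, bead_zone: tuple[int, int, int, int] | None = None,
                block_size_mm: float = 3.0, overlap_fraction: float = 0.75,
                coverage_threshold: float = 0.75) -> BlockGrid:
    """Tile the mask's bounding box into overlapping data blocks.

    Stride is ``block_size * (1 - overlap)``. A block is retained iff at
    least ``coverage_threshold`` of its pixels lie in-mask, its center pixel
    is in-mask, and it does not intersect the bead exclusion zone; rejected
    blocks are recorded with their reason ('coverage' or 'bead').
    """
    mask = np.asarray(mask) > 0
    if not mask.any():
        raise ValueError("mask is empty: nothing to tile")
    if not (0.0 <= overlap_fraction < 1.0):
        raise ValueError("overlap fraction must be in [0, 1)")
    rows = np.nonzero(mask.any(axis=1))[0]
    cols = np.nonzero(mask.any(axis=0))[0]
    r_lo, r_hi = int(rows[0]), int(rows[-1]) + 1
    c_lo, c_hi = int(cols[0]), int(cols[-1]) + 1
    dz, dx = geometry.dz_mm, geometry.pitch_mm
    ext_ax_mm = (r_hi - r_lo) * dz
    ext_lat_mm = (c_hi - c_lo) * dx
    blk_ax = int(round(block_size_mm / dz))
    blk_lat = int(round(block_size_mm / dx))
    stride_mm = block_size_mm * (1.0 - overlap_fraction)
    eps = 1e-9

    def offsets(extent_mm: float) -> list[float]:
        out, i = [], 0
        while i * stride_mm + block_size_mm <= extent_mm + eps:
            out.append(i * stride_mm)
            i += 1
        return out

    off_ax = offsets(ext_ax_mm)
    off_lat = offsets(ext_lat_mm)
    if not off_ax or not off_lat:
        warnings.warn("mask bounding box smaller than one data block; no blocks")
        return BlockGrid(block_size_mm, overlap_fraction, 0, 0, [], [])

    blocks, excluded = [], []
    bid = 0
    for i, oz in enumerate(off_ax):
        r0 = r_lo + int(round(oz / dz))
        r1 = min(r0 + blk_ax, mask.shape[0])
        for j, ox in enumerate(off_lat):
            c0 = c_lo + int(round(ox / dx))
            c1 = min(c0 + blk_lat, mask.shape[1])
            blk = Block(bid, i, j, r0, r1, c0, c1)
            bid += 1
            sub = mask[r0:r1, c0:c1]
            center_in = mask[(r0 + r1) // 2, (c0 + c1) // 2]
            if sub.mean() < coverage_threshold or not center_in:
                excluded.append((blk, "coverage"))
            elif bead_zone is not None and blk.intersects(bead_zone):
                excluded.append((blk, "bead"))
            else:
                blocks.append(blk)
    return BlockGrid(block_size_mm, overlap_fraction, len(off_ax), len(off_lat),
                     blocks, excluded)


# ---------------------------------------------------------------------------
# spectra
# ---------------------------------------------------------------------------

def analysis_nfft(gate_samples: int, pad_factor: int = 4) -> int:
    """FFT length: gate zero-padded by ``pad_factor``, rounded up to a power
    of two. Shared between block and bead spectra so the frequency grids
    coincide by construction."""
    return int(2 ** np.ceil(np.log2(max(8, pad_factor * gate_samples))))


@dataclass(frozen=True)
class BlockSpectrum:
    """Line-averaged backscattered power spectrum of one data block."""

    frequencies: np.ndarray
    power: np.ndarray
    block_id: int
    n_lines_averaged: int


def _gated_periodogram(rf_samples: np.ndarray, nfft: int) -> np.ndarray:
    """Hann-windowed, zero-padded, per-line periodogram averaged over lines."""
    gate = rf_samples.shape[0]
    win = hann(gate, sym=False)
    windowed = rf_samples * win[:, None]
    spec = np.fft.rfft(windowed, nfft, axis=0)
    return np.mean(np.abs(spec) ** 2, axis=1)


def block_power_spectrum(rf: RFFrame, block: Block, nfft: int | None = None) -> BlockSpectrum:
    """W(f) for one data block: per-line Hann-windowed, zero-padded FFT
    magnitude squared of the gated RF, averaged over the block's lines."""
    if block.r1 - block.r0 < 4:
        raise ValueError("gate shorter than 4 samples")
    if (block.r0 < 0 or block.r1 > rf.shape[0]
            or block.c0 < 0 or block.c1 > rf.shape[1] or block.c1 <= block.c0):
        raise ValueError("block lies outside the frame")
    gate = rf.samples[block.r0:block.r1, block.c0:block.c1]
    if nfft is None:
        nfft = analysis_nfft(gate.shape[0])
    power = _gated_periodogram(gate, nfft)
    freqs = np.fft.rfftfreq(nfft, 1.0 / rf.fs)
    return BlockSpectrum(frequencies=freqs, power=power, block_id=block.block_id,
                         n_lines_averaged=gate.shape[1])


def bead_power_spectrum(rf: RFFrame, detection: BeadDetection, gate_mm: float,
                        lateral_extent_mm: float = 2.0, nfft: int | None = None,
                        pre_fraction: float = 0.25) -> BlockSpectrum:
    """W_bead(f): average of per-line power spectra over the lines spanning
    the bead's lateral extent, gated axially around the bead echo.

    The gate starts ``pre_fraction`` of its length above the main echo so it
    covers the main echo and the reverberation train below it.
    """
    gate_px = int(round(gate_mm / rf.dz_mm))
    r0 = detection.axial_px - int(round(pre_fraction * gate_px))
    r1 = r0 + gate_px
    half_lat = max(1, int(round(lateral_extent_mm / 2.0 / rf.pitch_mm)))
    c0 = detection.lateral_px - half_lat
    c1 = detection.lateral_px + half_lat + 1
    if not (0 <= detection.axial_px < rf.shape[0]
            and 0 <= detection.lateral_px < rf.shape[1]):
        raise ValueError("bead detection lies outside the frame")
    r0 = max(r0, 0)
    r1 = min(r1, rf.shape[0])
    c0 = max(c0, 0)
    c1 = min(c1, rf.shape[1])
    if r1 - r0 < 4:
        raise ValueError("bead gate shorter than 4 samples")
    gate = rf.samples[r0:r1, c0:c1]
    if nfft is None:
        nfft = analysis_nfft(gate.shape[0])
    power = _gated_periodogram(gate, nfft)
    freqs = np.fft.rfftfreq(nfft, 1.0 / rf.fs)
    return BlockSpectrum(frequencies=freqs, power=power, block_id=-1,
                         n_lines_averaged=gate.shape[1])


# ---------------------------------------------------------------------------
# bead reference and BSC
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BeadReference:
    """Bead spectrum, tabulated bead BSC and the usable frequency band."""

    frequencies: np.ndarray
    w_bead: np.ndarray
    sigma_bead: np.ndarray
    band: np.ndarray  # boolean mask over the frequency grid


def make_bead_reference(w_bead: BlockSpectrum,
                        sigma_bead_table: tuple[np.ndarray, np.ndarray] | float,
                        band_db: float = -10.0,
                        band_hz: tuple[float, float] | None = None) -> BeadReference:
    """Assemble the calibration reference.

    ``sigma_bead_table`` is either (frequencies_hz, sigma) — interpolated
    onto the analysis grid — or a scalar for a frequency-flat bead BSC.
    ``band_hz`` fixes the usable band explicitly (the band is a property of
    the transducer/calibration, so fixing it keeps the analysis identical
    across acquisitions with different overlying loss); when omitted the
    band is data-driven: where the system response W_bead / sigma_bead is
    within ``band_db`` of its peak (default -10 dB).
    """
    freqs = w_bead.frequencies
    if np.isscalar(sigma_bead_table):
        sigma = np.full_like(freqs, float(sigma_bead_table))
    else:
        tab_f, tab_s = sigma_bead_table
        sigma = np.interp(freqs, np.asarray(tab_f, dtype=float),
                          np.asarray(tab_s, dtype=float))
    if w_bead.power.max() <= 0:
        raise ValueError("bead spectrum is identically zero")
    if band_hz is not None:
        band = (freqs >= band_hz[0]) & (freqs <= band_hz[1])
    else:
        # band selection runs on the system response W_bead / sigma_bead:
        # the bead's own spectral structure (reverberation comb) divides
        # out, leaving the smooth pulse-band envelope whose -10 dB support
        # is the usable band
        with np.errstate(divide="ignore", invalid="ignore"):
            response = np.where(sigma > 0,
                                w_bead.power / np.where(sigma > 0, sigma, 1.0), 0.0)
        peak = response.max()
        band = response >= peak * 10.0 ** (band_db / 10.0)
        # keep only the contiguous run containing the peak
        ipk = int(np.argmax(response))
        lo = ipk
        while lo > 0 and band[lo - 1]:
            lo -= 1
        hi = ipk
        while hi < len(band) - 1 and band[hi + 1]:
            hi += 1
        band = np.zeros_like(band)
        band[lo:hi + 1] = True
    band &= freqs > 0
    if band.sum() < 5:
        raise ValueError("usable band contains fewer than 5 frequency points")
    if np.any(sigma[band] <= 0):
        raise ValueError("bead BSC table must be positive on the usable band")
    return BeadReference(frequencies=freqs, w_bead=w_bead.power, sigma_bead=sigma,
                         band=band)


@dataclass(frozen=True)
class BSCCurve:
    frequencies: np.ndarray
    sigma: np.ndarray


def estimate_bsc(w: BlockSpectrum, ref: BeadReference) -> BSCCurve:
    """sigma(f) = W(f) / W_bead(f) * sigma_bead(f), restricted to the band.

    System gain and any loss factor common to sample and bead cancel exactly.
    """
    if w.frequencies.shape != ref.frequencies.shape or \
            not np.allclose(w.frequencies, ref.frequencies):
        raise ValueError("sample and reference must share one frequency grid")
    band = ref.band
    wb = ref.w_bead[band]
    if np.any(wb <= 0):
        raise ValueError("bead reference power must be positive on the band")
    sigma = w.power[band] / wb * ref.sigma_bead[band]
    return BSCCurve(frequencies=ref.frequencies[band], sigma=sigma)


# ---------------------------------------------------------------------------
# spherical Gaussian model fit
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GaussianFit:
    """Result of fitting the spherical Gaussian model to one BSC curve."""

    d_um: float
    esd_um: float
    eac: float
    valid: bool
    residual: float

    def __post_init__(self):
        # the ESD / characteristic-dimension relation holds by construction
        assert abs(self.esd_um - ESD_TO_D * self.d_um) <= 1e-9 * max(self.esd_um, 1.0)


class SphericalGaussianModel:
    """Linearized fit of sigma(f) = EAC (pi/2) d^6 k^4 exp(-2 k^2 d^2).

    With y = ln sigma - 4 ln k and x = k^2, the model is the line
    y = b - 2 d^2 x; ordinary least squares gives d = sqrt(-slope / 2) and
    EAC = exp(b) / ((pi/2) d^6). The fit is an exact inverse of the forward
    model on noiseless curves.
    """

    def __init__(self, curve: BSCCurve, sound_speed: float = 1540.0,
                 d_bounds_um: tuple[float, float] = (1.0, 500.0)):
        sigma = np.asarray(curve.sigma, dtype=np.float64)
        freqs = np.asarray(curve.frequencies, dtype=np.float64)
        if len(sigma) < 5:
            raise ValueError("need at least 5 frequency points in the band")
        if np.any(sigma <= 0):
            raise ValueError("BSC curve must be positive on the band")
        self.curve = curve
        self.c = sound_speed
        self.d_bounds_um = d_bounds_um
        self._k = 2.0 * np.pi * freqs / sound_speed
        self._y = np.log(sigma) - 4.0 * np.log(self._k)

    def fit(self) -> GaussianFit:
        x = self._k ** 2
        slope, intercept = np.polyfit(x, self._y, 1)
        resid = float(np.mean((self._y - (slope * x + intercept)) ** 2))
        d_lo, d_hi = self.d_bounds_um
        if slope >= 0:
            return self._invalid(d_lo, resid)
        d_m = float(np.sqrt(-slope / 2.0))
        d_um = d_m * 1e6
        # inclusive bounds with float tolerance so a fit exactly at a bound
        # (e.g. d equal to the sentinel value) still counts as valid
        if not (d_lo * (1.0 - 1e-9) <= d_um <= d_hi * (1.0 + 1e-9)):
            return self._invalid(d_lo, resid)
        eac = float(np.exp(intercept) / ((np.pi / 2.0) * d_m ** 6))
        return GaussianFit(d_um=d_um, esd_um=ESD_TO_D * d_um, eac=eac,
                           valid=True, residual=resid)

    @staticmethod
    def _invalid(d_lo: float, resid: float) -> GaussianFit:
        # sentinel: stored at the lower bound, flagged, excluded from averages
        return GaussianFit(d_um=d_lo, esd_um=ESD_TO_D * d_lo, eac=float("nan"),
                           valid=False, residual=resid)


def fit_gaussian_model(curve: BSCCurve, sound_speed: float = 1540.0,
                       d_bounds_um: tuple[float, float] = (1.0, 500.0)) -> GaussianFit:
    return SphericalGaussianModel(curve, sound_speed, d_bounds_um).fit()


# ---------------------------------------------------------------------------
# parametric maps
# ---------------------------------------------------------------------------

@dataclass
class ParamMap:
    """Per-block ESD / EAC rasters plus summaries over valid blocks only."""

    esd_um: np.ndarray   # (n_rows, n_cols), NaN where no valid fit
    eac: np.ndarray
    valid: np.ndarray    # boolean raster
    esd_mean: float
    esd_std: float
    eac_mean: float
    eac_std: float
    n_valid: int
    summary_defined: bool


def build_param_map(grid: BlockGrid, fits: list[GaussianFit]) -> ParamMap:
    """Rasterize per-block fits onto the block grid and summarize valid fits.

    Invalid (sentinel) fits and excluded blocks stay NaN in the rasters and
    never enter the mean/std.
    """
    if len(fits) != len(grid.blocks):
        raise ValueError("need exactly one fit per retained block")
    esd = np.full((grid.n_rows, grid.n_cols), np.nan)
    eac = np.full((grid.n_rows, grid.n_cols), np.nan)
    valid = np.zeros((grid.n_rows, grid.n_cols), dtype=bool)
    esd_vals, eac_vals = [], []
    for blk, fit in zip(grid.blocks, fits):
        if fit.valid:
            esd[blk.row, blk.col] = fit.esd_um
            eac[blk.row, blk.col] = fit.eac
            valid[blk.row, blk.col] = True
            esd_vals.append(fit.esd_um)
            eac_vals.append(fit.eac)
    n_valid = len(esd_vals)
    if n_valid == 0:
        warnings.warn("no valid Gaussian fits: map summary undefined")
        return ParamMap(esd, eac, valid, float("nan"), float("nan"),
                        float("nan"), float("nan"), 0, False)
    return ParamMap(esd, eac, valid,
                    float(np.mean(esd_vals)), float(np.std(esd_vals)),
                    float(np.mean(eac_vals)), float(np.std(eac_vals)),
                    n_valid, True)


def relative_error(value_a: float, value_b: float) -> float:
    """|a - b| / |b| (reference in the denominator)."""
    if value_b == 0:
        raise ValueError("reference value must be nonzero")
    return abs(value_a - value_b) / abs(value_b)
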