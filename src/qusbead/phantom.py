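"""Synthetic RF phantom simulator with known backscatter ground truth.

Emulates the acquisition this pipeline targets: a linear-array scan of a
tissue volume containing an elliptical tumor, diffuse sub-resolution
scatterers, an embedded calibration bead with a reverberant echo train, and
(optionally) an attenuating overlay layer on top of everything.

The statistical design ties the simulated speckle directly to the spherical
Gaussian backscatter model: each diffuse scatterer contributes the transmit
pulse filtered in the amplitude domain by ``k^2 exp(-k^2 d^2)`` (Rayleigh
factor times Gaussian form-factor amplitude), so the ensemble-average power
spectrum of a data block is proportional to ``|P(f)|^2 k^4 exp(-2 k^2 d^2)``
— exactly the shape of the BSC model used for fitting. The simulator is the
oracle for end-to-end effective-scatterer-diameter (ESD) recovery.

Frames are synthesized line-by-line in the frequency domain, which gives
exact fractional delays and per-scatterer, depth-cumulative,
frequency-dependent attenuation (in dB/cm/MHz) at negligible cost.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import gausspulse

from .bmode import RFFrame, rf_to_bmode, resize_image, resize_mask
from .bsc import ESD_TO_D

__all__ = [
    "ESD_TO_D",
    "PulseSpec",
    "Pulse",
    "BeadSpec",
    "OverlaySpec",
    "PhantomSpec",
    "GroundTruth",
    "make_pulse",
    "measure_fractional_bandwidth",
    "gaussian_model_bsc",
    "synthesize_rf",
    "synthesize_sweep",
    "make_dataset",
    "ellipse_mask",
    "measure_bead_bsc",
    "calibration_band",
    "save_phantom_h5",
    "load_phantom_h5",
]


# ---------------------------------------------------------------------------
# pulse
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PulseSpec:
    """Transmit pulse description.

    center_frequency : Hz
    fractional_bandwidth : -6 dB fractional bandwidth (e.g. 0.70)
    sampling_frequency : Hz
    sound_speed : m/s
    """

    center_frequency: float = 6.6e6
    fractional_bandwidth: float = 0.70
    sampling_frequency: float = 40e6
    sound_speed: float = 1540.0

    def __post_init__(self):
        if not (0.0 < self.fractional_bandwidth < 2.0):
            raise ValueError("fractional bandwidth must be in (0, 2)")
        if self.sampling_frequency <= 4.0 * self.center_frequency:
            raise ValueError("sampling frequency must exceed 4x center frequency")

    @property
    def band(self) -> tuple[float, float]:
        """Nominal -6 dB band edges in Hz."""
        half = 0.5 * self.fractional_bandwidth * self.center_frequency
        return self.center_frequency - half, self.center_frequency + half


@dataclass(frozen=True)
class Pulse:
    """Sampled Gaussian-modulated transmit pulse; ``center_index`` marks t = 0."""

    samples: np.ndarray
    center_index: int
    fs: float
    spec: PulseSpec

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def length_mm(self) -> float:
        """Pulse spatial length (envelope support) in mm of depth."""
        return len(self.samples) / self.fs * self.spec.sound_speed / 2.0 * 1e3


def make_pulse(spec: PulseSpec) -> Pulse:
    """Gaussian-modulated sinusoid whose -6 dB power bandwidth matches the spec.

    Rejects configurations whose upper band edge reaches Nyquist (aliasing).
    """
    fc, bw, fs = spec.center_frequency, spec.fractional_bandwidth, spec.sampling_frequency
    if fc * (1.0 + bw / 2.0) >= fs / 2.0:
        raise ValueError("pulse band extends to or beyond Nyquist; increase fs")
    tc = gausspulse("cutoff", fc=fc, bw=bw, bwr=-6, tpr=-80)
    n_half = int(np.ceil(tc * fs))
    t = np.arange(-n_half, n_half + 1) / fs
    p = gausspulse(t, fc=fc, bw=bw, bwr=-6)
    return Pulse(samples=p.astype(np.float64), center_index=n_half, fs=fs, spec=spec)


def measure_fractional_bandwidth(pulse: Pulse, level_db: float = -6.0) -> tuple[float, float]:
    """Measure (peak frequency, fractional bandwidth) at ``level_db`` re peak power."""
    nfft = max(4096, 8 * len(pulse))
    freqs = np.fft.rfftfreq(nfft, 1.0 / pulse.fs)
    power = np.abs(np.fft.rfft(pulse.samples, nfft)) ** 2
    ipk = int(np.argmax(power))
    thr = power[ipk] * 10.0 ** (level_db / 10.0)
    above = power >= thr
    lo = ipk
    while lo > 0 and above[lo - 1]:
        lo -= 1
    hi = ipk
    while hi < len(power) - 1 and above[hi + 1]:
        hi += 1
    f_peak = freqs[ipk]
    return f_peak, (freqs[hi] - freqs[lo]) / f_peak


# ---------------------------------------------------------------------------
# phantom description
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BeadSpec:
    """Calibration bead: a strong main echo plus a decaying reverberation train."""

    position_mm: tuple[float, float] = (15.0, 15.0)  # (axial, lateral)
    diameter_mm: float = 2.0
    # a titanium bead is a strong specular reflector: its echo is far larger
    # than the surrounding speckle (the central assumption of the in situ
    # reference method); 100x the diffuse RMS puts it ~40 dB above speckle
    echo_amplitude: float = 100.0
    reverb_count: int = 3
    reverb_decay: float = 0.5
    reverb_spacing_mm: float = 2.0     # round-trip axial spacing between echoes

    def train_extent_mm(self) -> float:
        """Axial extent from the main echo to the last reverberation echo."""
        return self.reverb_count * self.reverb_spacing_mm / 2.0


@dataclass(frozen=True)
class OverlaySpec:
    """Attenuating layer occupying the top ``thickness_mm`` of the field."""

    attenuation_db_cm_mhz: float = 0.5
    thickness_mm: float = 15.0

    def __post_init__(self):
        if self.attenuation_db_cm_mhz < 0:
            raise ValueError("attenuation coefficient must be nonnegative")


@dataclass(frozen=True)
class PhantomSpec:
    """Scene description for one synthetic frame.

    The elliptical tumor is echo-contrasted against the background through
    ``tumor_contrast`` (ratio of tumor to background scatterer amplitude
    variance); scatterer size ``char_dimension_um`` is the Gaussian
    correlation length d, so the true ESD is 3.11 d and the true effective
    acoustic concentration (EAC) is density x tumor impedance-contrast
    variance.
    """

    depth_mm: float = 30.0
    width_mm: float = 30.0
    pitch_mm: float = 0.3
    scatterer_density: float = 4.0            # scatterers per mm^2
    char_dimension_um: float = 25.0           # Gaussian correlation length d
    impedance_contrast_var: float = 1.0       # background gamma_0^2 analogue
    tumor_center_mm: tuple[float, float] = (15.0, 15.0)
    tumor_axes_mm: tuple[float, float] = (8.0, 6.0)  # semi-axes (axial, lateral)
    tumor_contrast: float = 0.35              # tumor/background variance ratio
    tissue_attenuation_db_cm_mhz: float = 0.5
    bead: BeadSpec | None = field(default_factory=BeadSpec)
    overlay: OverlaySpec | None = None
    noise_std: float = 0.0                    # additive white noise, x diffuse RMS
    seed: int = 0

    def __post_init__(self):
        cz, cx = self.tumor_center_mm
        az, ax = self.tumor_axes_mm
        if not (0 < cz - az and cz + az < self.depth_mm
                and 0 < cx - ax and cx + ax < self.width_mm):
            raise ValueError("tumor ellipse must lie strictly inside the field")
        if self.bead is not None:
            bz, bx = self.bead.position_mm
            if ((bz - cz) / az) ** 2 + ((bx - cx) / ax) ** 2 > 1.0:
                raise ValueError("bead must lie inside the tumor ellipse")
        if self.tissue_attenuation_db_cm_mhz < 0:
            raise ValueError("attenuation coefficient must be nonnegative")

    @property
    def tumor_eac(self) -> float:
        return self.scatterer_density * self.impedance_contrast_var * self.tumor_contrast

    @property
    def esd_um(self) -> float:
        return ESD_TO_D * self.char_dimension_um


@dataclass(frozen=True)
class GroundTruth:
    """Known answers for one synthetic phantom."""

    esd_um: float
    eac: float
    char_dimension_um: float
    bsc_freqs_hz: np.ndarray
    bsc_sigma: np.ndarray
    mask: np.ndarray                     # uint8, native RF grid
    bead_position_mm: tuple[float, float] | None
    seed: int

    def to_json(self) -> str:
        return json.dumps({
            "esd_um": self.esd_um,
            "eac": self.eac,
            "char_dimension_um": self.char_dimension_um,
            "bsc_freqs_hz": np.asarray(self.bsc_freqs_hz).tolist(),
            "bsc_sigma": np.asarray(self.bsc_sigma).tolist(),
            "bead_position_mm": (list(self.bead_position_mm)
                                 if self.bead_position_mm is not None else None),
            "seed": self.seed,
        })

    @classmethod
    def from_json(cls, text: str, mask: np.ndarray) -> "GroundTruth":
        d = json.loads(text)
        bead = d["bead_position_mm"]
        return cls(
            esd_um=d["esd_um"], eac=d["eac"],
            char_dimension_um=d["char_dimension_um"],
            bsc_freqs_hz=np.asarray(d["bsc_freqs_hz"]),
            bsc_sigma=np.asarray(d["bsc_sigma"]),
            mask=mask,
            bead_position_mm=tuple(bead) if bead is not None else None,
            seed=d["seed"],
        )


def gaussian_model_bsc(freqs_hz: np.ndarray, d_um: float, eac: float,
                       c: float = 1540.0) -> np.ndarray:
    """Spherical Gaussian backscatter model.

    sigma(f) = EAC * (pi/2) * d^6 * k^4 * exp(-2 k^2 d^2), with k = 2 pi f / c.
    The (pi/2) d^6 constant folds in the average particle volume
    V_s = (2 pi d^2)^{3/2} and the 1/(16 pi^2) prefactor. d is in meters
    internally (argument in micrometers); units of sigma are nominal.
    """
    k = 2.0 * np.pi * np.asarray(freqs_hz, dtype=np.float64) / c
    d = d_um * 1e-6
    return eac * (np.pi / 2.0) * d ** 6 * k ** 4 * np.exp(-2.0 * k ** 2 * d ** 2)


def ellipse_mask(shape: tuple[int, int], dz_mm: float, pitch_mm: float,
                 center_mm: tuple[float, float], axes_mm: tuple[float, float]) -> np.ndarray:
    """Rasterize an ellipse (mm coordinates) onto the native RF pixel grid."""
    n_ax, n_lat = shape
    z = (np.arange(n_ax) + 0.5) * dz_mm
    x = (np.arange(n_lat) + 0.5) * pitch_mm
    cz, cx = center_mm
    az, ax_ = axes_mm
    zz = ((z - cz) / az) ** 2
    xx = ((x - cx) / ax_) ** 2
    return (zz[:, None] + xx[None, :] <= 1.0).astype(np.uint8)


# ---------------------------------------------------------------------------
# RF synthesis
# ---------------------------------------------------------------------------

def _attenuation_db_per_mhz(z_mm: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    """Round-trip attenuation in dB per MHz for scatterers at depths z (mm)."""
    a_t = spec.tissue_attenuation_db_cm_mhz
    z_cm = z_mm / 10.0
    if spec.overlay is None:
        return 2.0 * a_t * z_cm
    t_cm = spec.overlay.thickness_mm / 10.0
    a_o = spec.overlay.attenuation_db_cm_mhz
    in_layer = np.minimum(z_cm, t_cm)
    below = np.maximum(z_cm - t_cm, 0.0)
    return 2.0 * (a_o * in_layer + a_t * below)


def _size_filter(freqs_hz: np.ndarray, d_um: float, c: float) -> np.ndarray:
    """Amplitude-domain scatterer response: sqrt(pi/2) d^3 k^2 exp(-k^2 d^2)."""
    k = 2.0 * np.pi * freqs_hz / c
    d = d_um * 1e-6
    return np.sqrt(np.pi / 2.0) * d ** 3 * k ** 2 * np.exp(-(k * d) ** 2)


def _line_geometry(spec: PhantomSpec, pulse: PulseSpec) -> tuple[int, int, float]:
    dz_mm = pulse.sound_speed / (2.0 * pulse.sampling_frequency) * 1e3
    n_samples = int(round(spec.depth_mm / dz_mm))
    n_lines = int(round(spec.width_mm / spec.pitch_mm))
    return n_samples, n_lines, dz_mm


def synthesize_rf(spec: PhantomSpec, pulse_spec: PulseSpec,
                  rng: np.random.Generator | None = None,
                  bead_gain: float = 1.0) -> tuple[RFFrame, GroundTruth]:
    """Synthesize one RF frame and its ground truth.

    ``rng`` overrides the spec seed (used for multi-frame sweeps);
    ``bead_gain`` scales the bead echo amplitude (elevational profile).
    """
    pulse = make_pulse(pulse_spec)
    n_samples, n_lines, dz_mm = _line_geometry(spec, pulse_spec)
    c = pulse_spec.sound_speed
    fs = pulse_spec.sampling_frequency
    if rng is None:
        rng = np.random.default_rng(spec.seed)

    nfft = int(2 ** np.ceil(np.log2(n_samples + len(pulse) + 1)))
    freqs = np.fft.rfftfreq(nfft, 1.0 / fs)
    # pulse spectrum with peak shifted to t = 0
    pf = np.fft.rfft(pulse.samples, nfft) * np.exp(
        2j * np.pi * freqs * pulse.center_index / fs)
    size_f = _size_filter(freqs, spec.char_dimension_um, c)
    f_mhz = freqs / 1e6

    rf = np.zeros((n_samples, n_lines), dtype=np.float64)

    area = spec.depth_mm * spec.width_mm
    n_scat = int(rng.poisson(spec.scatterer_density * area)) if spec.scatterer_density > 0 else 0
    if n_scat > 0:
        z = rng.uniform(0.0, spec.depth_mm, n_scat)
        x = rng.uniform(0.0, spec.width_mm, n_scat)
        cz, cx = spec.tumor_center_mm
        az, ax_ = spec.tumor_axes_mm
        in_tumor = ((z - cz) / az) ** 2 + ((x - cx) / ax_) ** 2 <= 1.0
        var = np.where(in_tumor, spec.impedance_contrast_var * spec.tumor_contrast,
                       spec.impedance_contrast_var)
        amps = rng.standard_normal(n_scat) * np.sqrt(var)
        att_db = _attenuation_db_per_mhz(z, spec)          # dB per MHz, per scatterer
        tau = 2.0 * (z * 1e-3) / c                          # round-trip delay, s
        line_idx = np.clip(np.round(x / spec.pitch_mm - 0.5).astype(int), 0, n_lines - 1)

        order = np.argsort(line_idx, kind="stable")
        line_sorted = line_idx[order]
        bounds = np.searchsorted(line_sorted, np.arange(n_lines + 1))
        base = pf * size_f
        for li in range(n_lines):
            sel = order[bounds[li]:bounds[li + 1]]
            if sel.size == 0:
                continue
            att = 10.0 ** (-np.outer(att_db[sel], f_mhz) / 20.0)
            phase = np.exp(-2j * np.pi * np.outer(tau[sel], freqs))
            spec_line = (amps[sel][:, None] * att * phase).sum(axis=0) * base
            rf[:, li] += np.fft.irfft(spec_line, nfft)[:n_samples]

    diffuse_rms = float(np.sqrt(np.mean(rf ** 2))) if n_scat > 0 else 0.0

    bead_pos = None
    if spec.bead is not None:
        bead = spec.bead
        bz, bx = bead.position_mm
        bead_pos = (bz, bx)
        ref_amp = diffuse_rms if diffuse_rms > 0 else 1.0
        amp0 = bead.echo_amplitude * ref_amp * bead_gain
        att_bead = 10.0 ** (-_attenuation_db_per_mhz(np.array([bz]), spec)[0]
                            * f_mhz / 20.0)
        x_lines = (np.arange(n_lines) + 0.5) * spec.pitch_mm
        half = bead.diameter_mm / 2.0
        lat = np.abs(x_lines - bx)
        affected = np.nonzero(lat <= half)[0]
        for li in affected:
            w = 0.5 * (1.0 + np.cos(np.pi * lat[li] / half)) if half > 0 else 1.0
            spec_line = np.zeros_like(freqs, dtype=complex)
            for m in range(bead.reverb_count + 1):
                z_m = bz + m * bead.reverb_spacing_mm / 2.0
                tau_m = 2.0 * (z_m * 1e-3) / c
                spec_line += (amp0 * w * bead.reverb_decay ** m
                              * np.exp(-2j * np.pi * freqs * tau_m))
            rf[:, li] += np.fft.irfft(spec_line * pf * att_bead, nfft)[:n_samples]

    if spec.noise_std > 0:
        scale = spec.noise_std * (diffuse_rms if diffuse_rms > 0 else 1.0)
        rf += rng.standard_normal(rf.shape) * scale

    frame = RFFrame(samples=rf, fs=fs, fc=pulse_spec.center_frequency,
                    pitch_mm=spec.pitch_mm, c=c)

    f_lo, f_hi = pulse_spec.band
    gt_freqs = np.linspace(f_lo, f_hi, 101)
    gt = GroundTruth(
        esd_um=spec.esd_um,
        eac=spec.tumor_eac,
        char_dimension_um=spec.char_dimension_um,
        bsc_freqs_hz=gt_freqs,
        bsc_sigma=gaussian_model_bsc(gt_freqs, spec.char_dimension_um, spec.tumor_eac, c),
        mask=ellipse_mask((n_samples, n_lines), dz_mm, spec.pitch_mm,
                          spec.tumor_center_mm, spec.tumor_axes_mm),
        bead_position_mm=bead_pos,
        seed=spec.seed,
    )
    return frame, gt


def synthesize_sweep(spec: PhantomSpec, pulse_spec: PulseSpec, n_frames: int = 11,
                     elev_sigma_frames: float = 2.0) -> tuple[list[RFFrame], GroundTruth]:
    """Elevational sweep across the bead: independent speckle per frame, bead
    echo amplitude following a Gaussian elevational profile peaking at the
    center frame."""
    if n_frames < 1:
        raise ValueError("need at least one frame")
    seeds = np.random.SeedSequence(spec.seed).spawn(n_frames)
    center = (n_frames - 1) / 2.0
    frames: list[RFFrame] = []
    gt = None
    for i in range(n_frames):
        gain = float(np.exp(-0.5 * ((i - center) / elev_sigma_frames) ** 2))
        frame, gt_i = synthesize_rf(spec, pulse_spec,
                                    rng=np.random.default_rng(seeds[i]),
                                    bead_gain=gain)
        frames.append(frame)
        if i == int(round(center)):
            gt = gt_i
    return frames, gt


def calibration_band(pulse_spec: PulseSpec, level_db: float = -10.0) -> tuple[float, float]:
    """Usable analysis band measured at calibration: the transmit pulse's
    band at ``level_db`` re peak power. Fixing the band here (rather than
    per acquisition) keeps the analysis identical when overlying loss tilts
    the received spectra."""
    pulse = make_pulse(pulse_spec)
    nfft = max(4096, 8 * len(pulse))
    freqs = np.fft.rfftfreq(nfft, 1.0 / pulse.fs)
    power = np.abs(np.fft.rfft(pulse.samples, nfft)) ** 2
    ipk = int(np.argmax(power))
    thr = power[ipk] * 10.0 ** (level_db / 10.0)
    lo = ipk
    while lo > 0 and power[lo - 1] >= thr:
        lo -= 1
    hi = ipk
    while hi < len(power) - 1 and power[hi + 1] >= thr:
        hi += 1
    return float(freqs[lo]), float(freqs[hi])


def measure_bead_bsc(pulse_spec: PulseSpec, bead: BeadSpec | None = None,
                     gate_mm: float = 6.0, lateral_extent_mm: float = 1.0,
                     nfft: int | None = None, pre_fraction: float = 0.25,
                     depth_mm: float = 30.0) -> tuple[np.ndarray, np.ndarray]:
    """Calibrate the bead BSC curve sigma_bead(f) on a clean phantom.

    Emulates the one-off calibration measurement of the bead's backscatter:
    the bead alone (no diffuse scatterers, no attenuation) is imaged and its
    echo spectrum — gated and line-averaged exactly as the in situ reference
    will be — is normalized by the transmit pulse power spectrum. The
    resulting table carries the bead's full scattering function including
    the reverberation comb, so dividing the in situ bead spectrum by it
    cancels gating and reverberation effects identically.

    Returns ``(frequencies_hz, sigma_bead)`` on the analysis grid
    (arbitrary but fixed units).
    """
    from .bead import BeadDetection
    from .bsc import bead_power_spectrum, analysis_nfft

    if bead is None:
        bead = BeadSpec()
    bz, bx = depth_mm / 2.0, depth_mm / 2.0
    bead = replace(bead, position_mm=(bz, bx))
    spec = PhantomSpec(depth_mm=depth_mm, width_mm=depth_mm,
                       scatterer_density=0.0, tissue_attenuation_db_cm_mhz=0.0,
                       tumor_center_mm=(bz, bx),
                       tumor_axes_mm=(depth_mm / 3, depth_mm / 3),
                       bead=bead, overlay=None, seed=0)
    frame, _ = synthesize_rf(spec, pulse_spec)
    r, c_ = frame.mm_to_px(bz, bx)
    det = BeadDetection(frame_index=0, axial_px=r, lateral_px=c_,
                        axial_mm=bz, lateral_mm=bx, ncc_peak=1.0,
                        constrained=False, low_confidence=False)
    if nfft is None:
        nfft = analysis_nfft(int(round(gate_mm / frame.dz_mm)))
    w = bead_power_spectrum(frame, det, gate_mm=gate_mm,
                            lateral_extent_mm=lateral_extent_mm, nfft=nfft,
                            pre_fraction=pre_fraction)
    pulse = make_pulse(pulse_spec)
    pf = np.abs(np.fft.rfft(pulse.samples, nfft)) ** 2
    floor = pf.max() * 1e-6
    sigma = w.power / np.maximum(pf, floor)
    return w.frequencies, np.maximum(sigma, sigma.max() * 1e-12)


# ---------------------------------------------------------------------------
# segmentation dataset
# ---------------------------------------------------------------------------

@dataclass
class SegDataset:
    """Paired B-mode images (float in [0, 1]) and binary masks."""

    images: np.ndarray   # (n, H, W) float32
    masks: np.ndarray    # (n, H, W) uint8
    area_ratios: np.ndarray
    phantom_ids: np.ndarray  # grouping key for leakage-free k-fold splits
    seed: int

    def __len__(self) -> int:
        return len(self.images)


def make_dataset(n_frames: int, seed: int = 0, image_size: tuple[int, int] = (256, 256),
                 ratio_range: tuple[float, float] = (0.05, 0.175),
                 pulse_spec: PulseSpec | None = None,
                 base_spec: PhantomSpec | None = None,
                 frames_per_phantom: int = 1) -> SegDataset:
    """Generate a labeled segmentation dataset from randomized phantoms.

    Tumor-to-image area ratios are drawn uniformly from ``ratio_range``;
    ellipse aspect and position, tumor contrast, and bead presence vary per
    phantom. ``frames_per_phantom`` frames share one phantom identity (for
    grouped cross-validation splits).
    """
    if n_frames < 1:
        raise ValueError("need at least one frame")
    if pulse_spec is None:
        pulse_spec = PulseSpec()
    if base_spec is None:
        base_spec = PhantomSpec(bead=None)
    rng = np.random.default_rng(seed)
    images, masks, ratios, pids = [], [], [], []
    field_area = base_spec.depth_mm * base_spec.width_mm
    i = 0
    while i < n_frames:
        pid = i // frames_per_phantom
        ratio = rng.uniform(*ratio_range)
        aspect = rng.uniform(0.6, 1.4)
        area = ratio * field_area
        ax_ = float(np.sqrt(area * aspect / np.pi))
        az = float(np.sqrt(area / (aspect * np.pi)))
        margin = 1.0
        cz = rng.uniform(az + margin, base_spec.depth_mm - az - margin)
        cx = rng.uniform(ax_ + margin, base_spec.width_mm - ax_ - margin)
        # markedly hypoechoic lesions (about -11 to -5 dB relative backscatter),
        # matching the conspicuous appearance of mammary tumors in B-mode
        contrast = rng.uniform(0.08, 0.3)
        with_bead = rng.random() < 0.5
        bead = None
        if with_bead:
            bead = BeadSpec(position_mm=(cz, cx))
        spec = replace(base_spec,
                       tumor_center_mm=(cz, cx), tumor_axes_mm=(az, ax_),
                       tumor_contrast=contrast, bead=bead,
                       seed=int(rng.integers(0, 2 ** 31 - 1)))
        frame, gt = synthesize_rf(spec, pulse_spec)
        bmode = rf_to_bmode(frame)
        img = resize_image(bmode.normalized(), image_size).astype(np.float32)
        msk = resize_mask(gt.mask, image_size)
        images.append(img)
        masks.append(msk)
        ratios.append(float(gt.mask.mean()))
        pids.append(pid)
        i += 1
    return SegDataset(images=np.stack(images), masks=np.stack(masks),
                      area_ratios=np.asarray(ratios), phantom_ids=np.asarray(pids),
                      seed=seed)


# ---------------------------------------------------------------------------
# HDF5 container
# ---------------------------------------------------------------------------

def save_phantom_h5(path, frames: list[RFFrame], gt: GroundTruth) -> None:
    """Write frames + ground truth to the standard container layout:
    dataset ``rf`` (samples x lines x frames), ``mask`` (uint8),
    ``ground_truth`` JSON; attributes fs_hz, fc_hz, pitch_mm, c_mps, seed."""
    import h5py

    first = frames[0]
    stack = np.stack([f.samples for f in frames], axis=2)
    with h5py.File(path, "w") as h5:
        ds = h5.create_dataset("rf", data=stack.astype(np.float32))
        ds.attrs["fs_hz"] = first.fs
        ds.attrs["fc_hz"] = first.fc
        ds.attrs["pitch_mm"] = first.pitch_mm
        ds.attrs["c_mps"] = first.c
        ds.attrs["seed"] = gt.seed
        h5.create_dataset("mask", data=gt.mask.astype(np.uint8))
        h5.create_dataset("ground_truth", data=gt.to_json())


def load_phantom_h5(path) -> tuple[list[RFFrame], GroundTruth]:
    import h5py

    with h5py.File(path, "r") as h5:
        ds = h5["rf"]
        stack = np.asarray(ds, dtype=np.float64)
        fs = float(ds.attrs["fs_hz"])
        fc = float(ds.attrs["fc_hz"])
        pitch = float(ds.attrs["pitch_mm"])
        c = float(ds.attrs["c_mps"])
        mask = np.asarray(h5["mask"], dtype=np.uint8)
        gt_json = h5["ground_truth"][()]
        if isinstance(gt_json, bytes):
            gt_json = gt_json.decode()
    frames = [RFFrame(samples=stack[:, :, i], fs=fs, fc=fc, pitch_mm=pitch, c=c)
              for i in range(stack.shape[2])]
    return frames, GroundTruth.from_json(gt_json, mask)
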