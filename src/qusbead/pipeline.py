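"""End-to-end automatic BSC estimation.

Orchestrates the three-step protocol over a multi-frame tumor scan:

1. convert every RF frame to a B-mode image;
2. segment the tumor (U-Net, or supplied reference masks) and localize the
   calibration bead by mask-constrained NCC, selecting the frame with the
   strongest correlation peak as the reference frame;
3. tile each frame's tumor mask into overlapping data blocks, estimate each
   block's BSC against the reference frame's bead spectrum, fit the
   spherical Gaussian model, and assemble ESD / EAC parametric maps.

The bead spectrum of the single reference frame calibrates every frame of
the volume; per-frame bead detections are still computed so bead-bearing
blocks can be excluded frame by frame. All stages are deterministic — a
fixed configuration reproduces the report bit for bit (modulo wall times).
"""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from .bmode import RFFrame, BModeImage, rf_to_bmode
from .bead import BSFTemplate, BeadDetection, locate_bead, select_bead_frame
from .unet import UNet, predict_mask, confusion, metrics
from .bsc import (tile_blocks, bead_exclusion_zone, block_power_spectrum,
                  bead_power_spectrum, make_bead_reference, estimate_bsc,
                  fit_gaussian_model, build_param_map, relative_error,
                  analysis_nfft, ParamMap, BlockGrid)

__all__ = ["BscConfig", "FrameResult", "RunReport", "run_pipeline",
           "compare_auto_vs_reference"]


@dataclass(frozen=True)
class BscConfig:
    """Tunable analysis parameters with the pipeline defaults."""

    dynamic_range_db: float = 60.0
    block_size_mm: float = 3.0
    overlap_fraction: float = 0.75
    coverage_threshold: float = 0.75
    bead_gate_mm: float = 6.0          # main echo + reverberation train
    bead_lateral_extent_mm: float = 1.0  # central bead lines only (strong echo)
    bead_diameter_mm: float = 2.0
    band_db: float = -10.0
    band_hz: tuple[float, float] | None = None  # fixed analysis band (calibration)
    d_bounds_um: tuple[float, float] = (1.0, 500.0)
    sound_speed: float = 1540.0


@dataclass
class FrameResult:
    frame_index: int
    mask_source: str               # 'unet' | 'reference'
    detection: BeadDetection | None
    n_retained: int
    excluded_reasons: dict[str, int]
    param_map: ParamMap | None
    grid: "BlockGrid | None" = None
    fits: "list | None" = None     # one GaussianFit per retained block
    skipped: bool = False
    skip_reason: str = ""


@dataclass
class RunReport:
    reference_frame: int
    frames: list[FrameResult]
    esd_mean_um: float
    esd_std_um: float
    eac_mean: float
    eac_std: float
    n_valid_blocks: int
    stage_seconds: dict[str, float] = field(default_factory=dict)
    config: BscConfig = field(default_factory=BscConfig)

    def to_json(self) -> str:
        def enc(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            if hasattr(o, "__dict__") or hasattr(o, "__dataclass_fields__"):
                return asdict(o) if hasattr(o, "__dataclass_fields__") else vars(o)
            raise TypeError(type(o))
        payload = {
            "reference_frame": self.reference_frame,
            "esd_mean_um": self.esd_mean_um,
            "esd_std_um": self.esd_std_um,
            "eac_mean": self.eac_mean,
            "eac_std": self.eac_std,
            "n_valid_blocks": self.n_valid_blocks,
            "stage_seconds": self.stage_seconds,
            "config": asdict(self.config),
            "frames": [
                {
                    "frame_index": fr.frame_index,
                    "mask_source": fr.mask_source,
                    "n_retained": fr.n_retained,
                    "excluded_reasons": fr.excluded_reasons,
                    "esd_mean_um": fr.param_map.esd_mean if fr.param_map else None,
                    "eac_mean": fr.param_map.eac_mean if fr.param_map else None,
                    "skipped": fr.skipped,
                    "skip_reason": fr.skip_reason,
                    "ncc_peak": fr.detection.ncc_peak if fr.detection else None,
                }
                for fr in self.frames
            ],
        }
        return json.dumps(payload, indent=2, default=enc)


def _segment_frames(bmodes: list[BModeImage], model: UNet | None,
                    masks: list[np.ndarray] | None) -> tuple[list[np.ndarray], str]:
    if masks is not None:
        if len(masks) != len(bmodes):
            raise ValueError("one mask per frame required")
        return [(np.asarray(m) > 0).astype(np.uint8) for m in masks], "reference"
    if model is None:
        raise ValueError("either a trained model or reference masks are required")
    return [predict_mask(model, bm) for bm in bmodes], "unet"


def run_pipeline(frames: list[RFFrame], template: BSFTemplate,
                 model: UNet | None = None,
                 masks: list[np.ndarray] | None = None,
                 sigma_bead: tuple[np.ndarray, np.ndarray] | float = 1.0,
                 config: BscConfig | None = None,
                 segment_only: bool = False) -> RunReport:
    """Run the full automatic protocol on a frame stack.

    ``masks`` (reference masks, e.g. hand labels or simulator ground truth)
    bypasses the network; otherwise ``model`` segments every frame. Returns
    a :class:`RunReport`; with ``segment_only`` the BSC stages are skipped
    and only segmentation/bead results are reported.
    """
    if len(frames) == 0:
        raise ValueError("no frames")
    config = config or BscConfig()
    stage_t: dict[str, float] = {}

    t0 = time.perf_counter()
    bmodes = [rf_to_bmode(f, config.dynamic_range_db) for f in frames]
    stage_t["bmode"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    frame_masks, mask_source = _segment_frames(bmodes, model, masks)
    stage_t["segment"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    detections: list[BeadDetection | None] = []
    for i, (bm, mk) in enumerate(zip(bmodes, frame_masks)):
        if not mk.any():
            warnings.warn(f"frame {i}: empty segmentation, skipped")
            detections.append(None)
            continue
        detections.append(locate_bead(bm, template, mask=mk, frame_index=i))
    stage_t["bead"] = time.perf_counter() - t0

    usable = [d for d in detections if d is not None]
    results = [FrameResult(frame_index=i, mask_source=mask_source,
                           detection=detections[i], n_retained=0,
                           excluded_reasons={}, param_map=None,
                           skipped=detections[i] is None,
                           skip_reason="" if detections[i] is not None
                           else "empty segmentation")
               for i in range(len(frames))]

    if segment_only:
        return RunReport(reference_frame=-1, frames=results,
                         esd_mean_um=float("nan"), esd_std_um=float("nan"),
                         eac_mean=float("nan"), eac_std=float("nan"),
                         n_valid_blocks=0, stage_seconds=stage_t, config=config)

    if not usable:
        raise RuntimeError("no bead found in any frame; cannot calibrate BSC")
    ref_local = select_bead_frame(usable)
    ref_index = usable[ref_local].frame_index

    t0 = time.perf_counter()
    ref_frame = frames[ref_index]
    block_gate_px = int(round(config.block_size_mm / ref_frame.dz_mm))
    bead_gate_px = int(round(config.bead_gate_mm / ref_frame.dz_mm))
    nfft = analysis_nfft(max(block_gate_px, bead_gate_px))
    w_bead = bead_power_spectrum(ref_frame, usable[ref_local],
                                 gate_mm=config.bead_gate_mm,
                                 lateral_extent_mm=config.bead_lateral_extent_mm,
                                 nfft=nfft)
    reference = make_bead_reference(w_bead, sigma_bead, band_db=config.band_db,
                                    band_hz=config.band_hz)
    stage_t["bead_reference"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    esd_all, eac_all, n_valid = [], [], 0
    for i, (frame, mk) in enumerate(zip(frames, frame_masks)):
        if results[i].skipped:
            continue
        det = detections[i]
        zone = bead_exclusion_zone(det, frame, gate_mm=config.bead_gate_mm,
                                   bead_diameter_mm=config.bead_diameter_mm)
        try:
            grid = tile_blocks(mk, frame, bead_zone=zone,
                               block_size_mm=config.block_size_mm,
                               overlap_fraction=config.overlap_fraction,
                               coverage_threshold=config.coverage_threshold)
        except ValueError:
            results[i].skipped = True
            results[i].skip_reason = "untileable mask"
            continue
        fits = []
        for blk in grid.blocks:
            w = block_power_spectrum(frame, blk, nfft=nfft)
            curve = estimate_bsc(w, reference)
            fits.append(fit_gaussian_model(curve, config.sound_speed,
                                           config.d_bounds_um))
        pmap = build_param_map(grid, fits) if grid.blocks else None
        results[i].n_retained = len(grid.blocks)
        results[i].excluded_reasons = grid.excluded_reasons
        results[i].param_map = pmap
        results[i].grid = grid
        results[i].fits = fits
        if pmap is not None and pmap.summary_defined:
            esd_all.append(pmap.esd_mean)
            eac_all.append(pmap.eac_mean)
            n_valid += pmap.n_valid
    stage_t["bsc"] = time.perf_counter() - t0

    if esd_all:
        esd_mean, esd_std = float(np.mean(esd_all)), float(np.std(esd_all))
        eac_mean, eac_std = float(np.mean(eac_all)), float(np.std(eac_all))
    else:
        esd_mean = esd_std = eac_mean = eac_std = float("nan")
    return RunReport(reference_frame=ref_index, frames=results,
                     esd_mean_um=esd_mean, esd_std_um=esd_std,
                     eac_mean=eac_mean, eac_std=eac_std,
                     n_valid_blocks=n_valid, stage_seconds=stage_t, config=config)


def compare_auto_vs_reference(frames: list[RFFrame], template: BSFTemplate,
                              auto_masks: list[np.ndarray],
                              reference_masks: list[np.ndarray],
                              sigma_bead=1.0,
                              config: BscConfig | None = None) -> dict:
    """Relative errors of mean ESD / EAC between two mask sources, plus the
    per-frame Dice between the masks themselves."""
    if len(auto_masks) != len(reference_masks) or len(auto_masks) != len(frames):
        raise ValueError("frame sets must match between mask sources")
    if len(frames) == 0:
        raise ValueError("empty frame set")
    rep_a = run_pipeline(frames, template, masks=auto_masks,
                         sigma_bead=sigma_bead, config=config)
    rep_r = run_pipeline(frames, template, masks=reference_masks,
                         sigma_bead=sigma_bead, config=config)
    dices = []
    for ma, mr in zip(auto_masks, reference_masks):
        c = confusion((np.asarray(ma) > 0).astype(np.uint8),
                      (np.asarray(mr) > 0).astype(np.uint8))
        dices.append(metrics(c).dice)
    return {
        "esd_relative_error": relative_error(rep_a.esd_mean_um, rep_r.esd_mean_um),
        "eac_relative_error": relative_error(rep_a.eac_mean, rep_r.eac_mean),
        "dice_per_frame": dices,
        "auto_report": rep_a,
        "reference_report": rep_r,
    }
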