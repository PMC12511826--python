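# qusbead

Automatic, bead-referenced backscatter-coefficient (BSC) estimation for
tumor ultrasound.

Spectral quantitative ultrasound characterizes tissue microstructure by
estimating the backscatter coefficient σ(f) of a region and reducing it to
physical parameters — the effective scatterer diameter (ESD) and effective
acoustic concentration (EAC). Doing this in vivo requires (1) a reference
spectrum that cancels system and attenuation effects and (2) a segmented
tumor region; both are usually produced manually. `qusbead` automates the
whole chain for scans that contain a small embedded calibration bead:

1. RF frames → B-mode images (envelope detection, 60 dB log compression);
2. U-Net tumor segmentation (single-channel 256×256 input, nine resolution
   blocks 64…1024…64, BCE-with-logits + Adam — implemented from scratch on
   numpy with hand-written backpropagation, so it runs anywhere);
3. calibration-bead localization by normalized cross-correlation with a
   bead-scattering-function (BSF) template, constrained to the segmented
   tumor; the frame with the strongest peak becomes the reference frame;
4. per-block BSC via the in situ reference,
   σ̂(f) = W(f)/W_bead(f) · σ_bead(f), on 3 mm × 3 mm blocks with 75 %
   overlap (bead-bearing blocks excluded), and a linearized fit of the
   spherical Gaussian model
   σ(f) = EAC·(π/2)d⁶k⁴e^{−2k²d²} giving per-block ESD = 3.11·d and EAC.

Because no in vivo data ships with the package, a synthetic RF phantom
simulator with exactly known ground truth (scatterer size d, EAC, tumor
mask, bead position, optional attenuating overlay) generates every input
the pipeline needs; the simulator's ensemble statistics match the Gaussian
scattering model by construction, so end-to-end parameter recovery is
testable quantitatively. See `docs/methods.md` for the models and their
assumptions.

## Worked example

```python
import numpy as np
import qusbead as q

pulse = q.PulseSpec()                       # 6.6 MHz, 70 % bandwidth, fs 40 MHz
spec  = q.PhantomSpec(seed=1, char_dimension_um=25.0)   # true ESD = 77.8 um
frame, gt = q.synthesize_rf(spec, pulse)

bm  = q.rf_to_bmode(frame)                  # 60 dB B-mode
tpl = q.build_bsf_template([q.extract_patch(bm, gt.bead_position_mm,
                                            q.default_template_shape(bm))])

report = q.run_pipeline(
    [frame], tpl,
    masks=[gt.mask],                        # ground-truth mask (or model=...)
    sigma_bead=q.measure_bead_bsc(pulse),   # one-off bead calibration table
    config=q.BscConfig(band_hz=q.calibration_band(pulse)))

pm = report.frames[0].param_map
print(f"reference frame {report.reference_frame}")
print(f"ESD {pm.esd_mean:.1f} +/- {pm.esd_std:.1f} um over {pm.n_valid} blocks "
      f"(truth {gt.esd_um:.1f} um)")
print(f"blocks retained {report.frames[0].n_retained}, "
      f"excluded {report.frames[0].excluded_reasons}")
```

Output:

```
reference frame 0
ESD 78.8 +/- 17.4 um over 108 blocks (truth 77.8 um)
blocks retained 108, excluded {'coverage': 30, 'bead': 96}
```

The per-block ESD map averages to 78.8 µm against a ground truth of
77.8 µm (+1.3 %); 96 overlapping blocks were discarded because they touch
the bead's echo train, 30 because they extend past the tumor boundary. Adding a
1.5 cm attenuating overlay above the tumor leaves the estimate unchanged —
the losses cancel in the bead-referenced ratio.

The same stages are available from the shell:

```bash
qusbead simulate --out phantom.h5 --frames 11 --seed 1
qusbead train --out runs/unet --n-train 200 --image-size 128
qusbead run --rf phantom.h5 --checkpoint runs/unet/unet.npz --out runs/bsc
```

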