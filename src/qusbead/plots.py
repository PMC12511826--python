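"""Parametric-map visualization: ESD / EAC rasters over the B-mode image."""

from __future__ import annotations

import numpy as np
import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .bmode import BModeImage
from .bsc import BlockGrid, ParamMap

__all__ = ["plot_param_map_overlay"]


def plot_param_map_overlay(bmode: BModeImage, grid: BlockGrid, pmap: ParamMap,
                           out_path, param: str = "esd",
                           title: str | None = None) -> None:
    """Render a per-block parameter raster over the B-mode frame.

    ``param`` selects the raster ('esd' in um or 'eac', nominal units);
    excluded and invalid blocks stay transparent.
    """
    raster = pmap.esd_um if param == "esd" else pmap.eac
    label = "ESD (um)" if param == "esd" else "EAC (nominal units)"
    h_mm = bmode.shape[0] * bmode.dz_mm
    w_mm = bmode.shape[1] * bmode.pitch_mm

    fig, ax = plt.subplots(figsize=(6, 6 * h_mm / max(w_mm, 1e-9)))
    ax.imshow(bmode.intensity_db, cmap="gray", vmin=-bmode.dynamic_range_db,
              vmax=0.0, extent=(0, w_mm, h_mm, 0), aspect="equal")
    if grid.blocks:
        # extent spans the block centers of the tiling grid
        r_cents = [(b.r0 + b.r1) / 2.0 for b in grid.blocks]
        c_cents = [(b.c0 + b.c1) / 2.0 for b in grid.blocks]
        half_r = grid.block_size_mm / 2.0
        extent = (min(c_cents) * bmode.pitch_mm - half_r,
                  max(c_cents) * bmode.pitch_mm + half_r,
                  max(r_cents) * bmode.dz_mm + half_r,
                  min(r_cents) * bmode.dz_mm - half_r)
        masked = np.ma.masked_invalid(raster)
        im = ax.imshow(masked, cmap="viridis", alpha=0.75, extent=extent,
                       aspect="equal", interpolation="nearest")
        fig.colorbar(im, ax=ax, label=label, shrink=0.8)
    ax.set_xlabel("lateral (mm)")
    ax.set_ylabel("depth (mm)")
    if title:
        ax.set_title(title)
    fig.savefig(out_path, dpi=120, bbox_inches="tight")
    plt.close(fig)
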