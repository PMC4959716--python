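"""MAI-on-T2W overlay rendering."""

from __future__ import annotations

from pathlib import Path

import matplotlib
import numpy as np

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .volume import VolumeImage

__all__ = ["export_overlay"]


def export_overlay(
    t2w: VolumeImage,
    mai: VolumeImage,
    slice_index: int,
    path: str | Path,
    display_threshold: float = 0.2,
    dpi: int = 150,
) -> Path:
    """Write a PNG of one axial slice: grayscale T2W under a blue-to-red
    MAI colour wash that is fully transparent below ``display_threshold``.
    """
    if not t2w.same_geometry(mai, tol=1e-6):
        raise ValueError("T2W and MAI volumes must share geometry")
    if not 0 <= slice_index < t2w.shape[2]:
        raise IndexError(f"slice {slice_index} out of range 0..{t2w.shape[2] - 1}")
    t2_slice = t2w.data[:, :, slice_index].T
    mai_slice = np.clip(mai.data[:, :, slice_index].T, 0.0, 1.0)

    rgba = matplotlib.colormaps["jet"](mai_slice)
    rgba[..., 3] = np.where(mai_slice >= display_threshold, 0.6, 0.0)

    fig, axm = plt.subplots(figsize=(4, 4))
    axm.imshow(t2_slice, cmap="gray", origin="lower",
               aspect=t2w.spacing[1] / t2w.spacing[0])
    axm.imshow(rgba, origin="lower", aspect=t2w.spacing[1] / t2w.spacing[0])
    axm.set_axis_off()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=dpi, bbox_inches="tight")
    plt.close(fig)
    return path
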