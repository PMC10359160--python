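"""Couch handling and intensity normalization ahead of training/inference.

Couch removal is realized as: threshold the volume (default -300 HU), keep
the largest 3D connected component (the patient body; the couch band is a
separate component), morphologically close it (radius-2 ball) and fill holes
slice-by-slice along z (lungs are interior holes at this threshold). Voxels
outside the body mask are then set to air (-1000 HU). The couch can be
digitally re-added afterwards from a geometric model, e.g. for downstream
dose calculation.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .errors import DegenerateInputError, GridMismatchError
from .phantom import HU_AIR, CouchModel
from .volumes import BinaryMask, ScalarVolume

__all__ = [
    "segment_body",
    "remove_couch",
    "add_couch",
    "normalize_intensity",
    "denormalize_intensity",
    "DEFAULT_BODY_THRESHOLD_HU",
    "DEFAULT_WINDOW_HU",
]

DEFAULT_BODY_THRESHOLD_HU = -300.0
DEFAULT_WINDOW_HU = (-1000.0, 1000.0)


def _ball(radius: int) -> np.ndarray:
    r = int(radius)
    x, y, z = np.mgrid[-r:r + 1, -r:r + 1, -r:r + 1]
    return x**2 + y**2 + z**2 <= r**2


def segment_body(volume: ScalarVolume,
                 threshold_hu: float = DEFAULT_BODY_THRESHOLD_HU) -> BinaryMask:
    """Largest above-threshold component, closed and hole-filled per z-slice."""
    fg = volume.values > threshold_hu
    if not fg.any():
        raise DegenerateInputError(
            f"no voxels above {threshold_hu} HU: cannot segment a body"
        )
    labels, n = ndimage.label(fg)
    if n > 1:
        sizes = ndimage.sum_labels(fg, labels, index=np.arange(1, n + 1))
        fg = labels == (1 + int(np.argmax(sizes)))
    # closing with outside-as-foreground erosion so structures that reach the
    # volume border (a body spanning all z-slices) are not shaved there
    ball = _ball(2)
    fg = ndimage.binary_erosion(ndimage.binary_dilation(fg, ball), ball,
                                border_value=1)
    for k in range(fg.shape[2]):
        fg[:, :, k] = ndimage.binary_fill_holes(fg[:, :, k])
    return BinaryMask(volume.grid, fg)


def remove_couch(volume: ScalarVolume, body: BinaryMask) -> ScalarVolume:
    """Set every voxel outside the body mask to air (-1000 HU)."""
    if not body.grid.matches(volume.grid):
        raise GridMismatchError("body mask grid does not match the volume grid")
    out = np.where(body.values, volume.values, HU_AIR)
    return ScalarVolume(volume.grid, out)


def add_couch(volume: ScalarVolume, couch_model: CouchModel,
              overlap_threshold_hu: float = DEFAULT_BODY_THRESHOLD_HU
              ) -> ScalarVolume:
    """Paint the couch model's HU into the volume.

    The couch region must not overlap tissue: any couch voxel already above
    ``overlap_threshold_hu`` raises an error.
    """
    couch = couch_model.mask(volume.grid)
    if not couch.values.any():
        return volume.copy()
    if (volume.values[couch.values] > overlap_threshold_hu).any():
        raise ValueError("couch geometry overlaps non-air voxels")
    out = volume.values.copy()
    out[couch.values] = couch_model.hu
    return ScalarVolume(volume.grid, out)


def normalize_intensity(volume: ScalarVolume,
                        window: tuple[float, float] = DEFAULT_WINDOW_HU
                        ) -> ScalarVolume:
    """Affine map of [window_min, window_max] -> [-1, 1], clipped outside."""
    lo, hi = window
    if not lo < hi:
        raise ValueError(f"degenerate window {window}")
    x = np.clip(volume.values, lo, hi)
    return ScalarVolume(volume.grid, 2.0 * (x - lo) / (hi - lo) - 1.0)


def denormalize_intensity(volume: ScalarVolume,
                          window: tuple[float, float] = DEFAULT_WINDOW_HU
                          ) -> ScalarVolume:
    """Inverse of :func:`normalize_intensity` on the clipped range."""
    lo, hi = window
    if not lo < hi:
        raise ValueError(f"degenerate window {window}")
    return ScalarVolume(volume.grid,
                        (volume.values + 1.0) / 2.0 * (hi - lo) + lo)
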