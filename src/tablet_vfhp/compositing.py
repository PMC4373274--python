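"""Augmented-reality frame compositing.

The composited display frame S is built from the camera frame C, the
stimulus/response frame T and the binary skin mask M by

    S = (C x M) + (T x ~M)

applied element-by-element and channel-wise.  Because M is binary this is a
pure per-pixel *selection* — camera where M = 1, stimulus where M = 0 — and
is implemented as such, which is arithmetically identical but cannot
overflow 8-bit intensities.  No blending occurs: every output pixel is
bit-identical to the corresponding pixel of exactly one input stream.

Camera and stimulus rasters generally differ (e.g. a 640x480 camera against
a 1024x768 projector); reconciliation is an explicit nearest-neighbor
:func:`resample_to` step, and :func:`compose` itself refuses mismatched
shapes rather than resampling implicitly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DimensionMismatchError, ValidationError
from .segmentation import validate_frame

__all__ = ["CompositeFrame", "compose", "resample_to", "validate_mask"]

CAMERA, STIMULUS = 1, 0  # provenance codes; provenance equals the mask


@dataclass(frozen=True)
class CompositeFrame:
    """Superimposed frame plus per-pixel provenance.

    ``provenance`` is an H x W array: 1 where the pixel came from the camera
    stream, 0 where it came from the stimulus stream.
    """

    pixels: np.ndarray
    provenance: np.ndarray

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.pixels, dtype=dtype)


def validate_mask(mask: np.ndarray, name: str = "mask") -> np.ndarray:
    """Validate an H x W binary mask and return it as ``uint8`` of {0, 1}."""
    arr = np.asarray(mask)
    if arr.ndim != 2:
        raise ValidationError(f"{name} must be 2-D, got shape {arr.shape}")
    if not np.issubdtype(arr.dtype, np.integer) and arr.dtype != bool:
        raise ValidationError(f"{name} must be integer/bool, got {arr.dtype}")
    arr = arr.astype(np.uint8, copy=False)
    if arr.size and not np.isin(arr, (0, 1)).all():
        raise ValidationError(f"{name} values must be strictly binary {{0, 1}}")
    return arr


def compose(camera: np.ndarray, stimulus: np.ndarray, mask: np.ndarray) -> CompositeFrame:
    """Superimpose camera over stimulus under a binary mask.

    Raises
    ------
    DimensionMismatchError
        If the three inputs do not share H x W dimensions.  No implicit
        resampling happens here; use :func:`resample_to` first.
    """
    cam = validate_frame(camera, "camera")
    stim = validate_frame(stimulus, "stimulus")
    m = validate_mask(mask)
    if cam.shape != stim.shape or cam.shape[:2] != m.shape:
        raise DimensionMismatchError(
            f"camera {cam.shape}, stimulus {stim.shape} and mask {m.shape} "
            "must share dimensions"
        )
    pixels = np.where(m[..., None].astype(bool), cam, stim)
    return CompositeFrame(pixels=pixels, provenance=m.copy())


def resample_to(frame: np.ndarray, height: int, width: int) -> np.ndarray:
    """Nearest-neighbor rescale of a frame to ``height`` x ``width``.

    Index mapping is ``src = (dst * n_src) // n_dst`` per axis, so an
    integer upscale replicates each pixel in a block and the identity target
    returns a bit-identical copy.
    """
    arr = validate_frame(frame)
    if height < 1 or width < 1:
        raise ValidationError("target dimensions must be >= 1")
    rows = (np.arange(height) * arr.shape[0]) // height
    cols = (np.arange(width) * arr.shape[1]) // width
    return arr[rows][:, cols].copy()
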