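"""Per-pixel skin/stylus color segmentation.

The hand and the (red-sleeved) stylus are isolated from each camera frame by
a fixed rule in RGB space, derived from the classical uniform-daylight skin
locus: a pixel is skin iff

    R > 55  and  G > 20  and  B > 20
    and max(R, G, B) - min(R, G, B) > 15
    and |R - G| > 15  and  R > G  and  R > B

All comparisons are strict, so threshold-valued pixels are non-skin.  The
thresholds are exposed in :class:`SkinRule` because in practice the R and G
cut-offs need slight adjustment to the illumination of a given rig; the
defaults reproduce the daylight rule exactly.

Frames are 8-bit, three-channel arrays (H x W x 3, ``uint8`` semantics).
Floating-point frames are rejected rather than silently rounded.  Masks are
H x W arrays of {0, 1} (``uint8``).
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

from .errors import ValidationError

__all__ = ["SkinRule", "classify_skin_pixel", "segment_frame", "validate_frame"]


@dataclass(frozen=True)
class SkinRule:
    """Thresholds of the RGB skin-color rule.

    Parameters
    ----------
    r_min, g_min, b_min:
        Per-channel lower bounds (strict).
    chroma_min:
        Lower bound (strict) on max(R,G,B) - min(R,G,B); rejects gray pixels.
    rg_gap_min:
        Lower bound (strict) on \\|R - G\\|.
    """

    r_min: int = 55
    g_min: int = 20
    b_min: int = 20
    chroma_min: int = 15
    rg_gap_min: int = 15

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not isinstance(v, (int, np.integer)) or isinstance(v, bool):
                raise ValidationError(f"SkinRule.{f.name} must be an integer, got {v!r}")
            if not 0 <= v <= 255:
                raise ValidationError(f"SkinRule.{f.name}={v} outside [0, 255]")


def _check_channel(name: str, value: object) -> int:
    if not isinstance(value, (int, np.integer)) or isinstance(value, bool):
        raise ValidationError(f"channel {name} must be an integer, got {value!r}")
    if not 0 <= int(value) <= 255:
        raise ValidationError(f"channel {name}={value} outside [0, 255]")
    return int(value)


def classify_skin_pixel(pixel: tuple[int, int, int], rule: SkinRule = SkinRule()) -> bool:
    """Classify a single (R, G, B) pixel as skin/stylus.

    Pure-Python reference path; :func:`segment_frame` is the bulk equivalent.
    """
    r = _check_channel("R", pixel[0])
    g = _check_channel("G", pixel[1])
    b = _check_channel("B", pixel[2])
    return (
        r > rule.r_min
        and g > rule.g_min
        and b > rule.b_min
        and max(r, g, b) - min(r, g, b) > rule.chroma_min
        and abs(r - g) > rule.rg_gap_min
        and r > g
        and r > b
    )


def validate_frame(frame: np.ndarray, name: str = "frame") -> np.ndarray:
    """Validate an H x W x 3 8-bit frame and return it as ``uint8``."""
    arr = np.asarray(frame)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValidationError(f"{name} must be H x W x 3, got shape {arr.shape}")
    if arr.shape[0] < 1 or arr.shape[1] < 1:
        raise ValidationError(f"{name} must have at least one pixel")
    if not np.issubdtype(arr.dtype, np.integer):
        raise ValidationError(
            f"{name} must have integer dtype (8-bit video); got {arr.dtype} — "
            "floating-point frames are rejected, not rounded"
        )
    if arr.size and (arr.min() < 0 or arr.max() > 255):
        raise ValidationError(f"{name} has channel values outside [0, 255]")
    return arr.astype(np.uint8, copy=False)


def segment_frame(frame: np.ndarray, rule: SkinRule = SkinRule()) -> np.ndarray:
    """Apply the skin rule to every pixel of a frame.

    Parameters
    ----------
    frame:
        H x W x 3 integer array with values in [0, 255].
    rule:
        Thresholds; defaults are the daylight skin rule.

    Returns
    -------
    numpy.ndarray
        H x W ``uint8`` mask, 1 where the pixel is skin/stylus, else 0.
    """
    arr = validate_frame(frame).astype(np.int16)
    r, g, b = arr[..., 0], arr[..., 1], arr[..., 2]
    mx = arr.max(axis=2)
    mn = arr.min(axis=2)
    skin = (
        (r > rule.r_min)
        & (g > rule.g_min)
        & (b > rule.b_min)
        & (mx - mn > rule.chroma_min)
        & (np.abs(r - g) > rule.rg_gap_min)
        & (r > g)
        & (r > b)
    )
    return skin.astype(np.uint8)
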