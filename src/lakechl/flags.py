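"""Quality-flag bitmask vocabulary and the valid-pixel predicate.

Eleven named bits are carried per pixel. Two are *required* flags that must
be raised for a pixel to be usable (water classification and the
shoreline/shallow-water buffer); the remaining nine are *exclusion* flags
(clouds, cloud buffer/shadow, cirrus, and the processor's out-of-scope /
out-of-range diagnostics), any one of which invalidates the pixel.

Bit order is fixed so that files written by :mod:`lakechl.io` are portable.
"""
from __future__ import annotations

import enum

import numpy as np
from scipy import ndimage

__all__ = [
    "Flag",
    "FLAG_ORDER",
    "REQUIRED_FLAGS",
    "EXCLUSION_FLAGS",
    "valid_pixel_mask",
    "apply_cloud_buffer",
    "set_flag",
]


class Flag(enum.IntFlag):
    """Named quality-flag bits, in their canonical (file) order."""

    IDEPIX_WATER = 1 << 0
    IDEPIX_CLOUD = 1 << 1
    IDEPIX_CLOUD_BUFFER = 1 << 2
    IDEPIX_CLOUD_SHADDOW = 1 << 3
    IDEPIX_CIRRUS_SURE = 1 << 4
    RTOSA_OOS = 1 << 5
    RTOSA_OOR = 1 << 6
    RHOW_OOR = 1 << 7
    RHOW_OOS = 1 << 8
    IOP_OOR = 1 << 9
    SHORE_SHALLOW_BUFFER = 1 << 10


#: Canonical bit order (index == bit position).
FLAG_ORDER: tuple[Flag, ...] = tuple(Flag)

#: Flags that must be raised for a pixel to be valid.
REQUIRED_FLAGS: tuple[Flag, ...] = (Flag.IDEPIX_WATER, Flag.SHORE_SHALLOW_BUFFER)

#: Flags that must NOT be raised for a pixel to be valid.
EXCLUSION_FLAGS: tuple[Flag, ...] = tuple(
    f for f in Flag if f not in REQUIRED_FLAGS
)

_REQUIRED_BITS = int(np.bitwise_or.reduce([int(f) for f in REQUIRED_FLAGS]))
_EXCLUSION_BITS = int(np.bitwise_or.reduce([int(f) for f in EXCLUSION_FLAGS]))


def valid_pixel_mask(bitmask: np.ndarray) -> np.ndarray:
    """Boolean raster of pixels passing the quality-flag rule.

    A pixel is valid iff both required flags are raised and none of the
    nine exclusion flags is raised.

    Parameters
    ----------
    bitmask
        Integer array of per-pixel flag words.
    """
    bm = np.asarray(bitmask)
    if not np.issubdtype(bm.dtype, np.integer):
        raise TypeError(f"flag bitmask must be integer, got dtype {bm.dtype}")
    required_ok = (bm & _REQUIRED_BITS) == _REQUIRED_BITS
    excluded = (bm & _EXCLUSION_BITS) != 0
    return required_ok & ~excluded


def apply_cloud_buffer(cloud_mask: np.ndarray, width: int = 2) -> np.ndarray:
    """Dilate a cloud mask by ``width`` pixels (square / Chebyshev metric).

    Used to derive the cloud-buffer flag from the cloud flag in synthetic
    scenes. ``width=0`` returns a copy of the input.
    """
    if width < 0:
        raise ValueError(f"buffer width must be >= 0, got {width}")
    mask = np.asarray(cloud_mask, dtype=bool)
    if width == 0:
        return mask.copy()
    size = 2 * width + 1
    return ndimage.binary_dilation(mask, structure=np.ones((size, size), bool))


def set_flag(bitmask: np.ndarray, flag: Flag, where: np.ndarray) -> np.ndarray:
    """Return ``bitmask`` with ``flag`` raised where ``where`` is True."""
    bm = np.asarray(bitmask).copy()
    bm[np.asarray(where, dtype=bool)] |= int(flag)
    return bm
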