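"""Single-channel micrograph container and TIFF I/O.

A :class:`Micrograph` is a 2-D grid of nonnegative intensities together with
the acquisition metadata that the quantification pipeline needs to enforce its
comparability contract: bit depth, channel label, exposure time and whether
shading correction has already been applied.  Pixel values are held as float64
internally; quantized images (fresh off the camera, or after the 8-bit
transform) must stay within ``[0, 2**bit_depth - 1]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import tifffile

__all__ = ["Micrograph", "read_tiff", "write_tiff"]


@dataclass
class Micrograph:
    """A single-channel fluorescence or phase-contrast image.

    Parameters
    ----------
    pixels
        2-D array of nonnegative intensities.  Stored as float64.
    bit_depth
        8 or 16.  For quantized images every value must lie in
        ``[0, 2**bit_depth - 1]``; corrected images keep continuous values
        (still bounded by the quantized range they came from).
    exposure
        Exposure time in seconds.  Fields being compared must share it.
    channel
        Free-form channel label (e.g. ``"GFP"`` or ``"phase"``).
    corrected
        True once shading correction has been applied.
    meta
        Auxiliary provenance (8-bit mapping parameters, shading provenance,
        simulation seed, ...).
    """

    pixels: np.ndarray
    bit_depth: int = 16
    exposure: float = 1.0
    channel: str = "GFP"
    corrected: bool = False
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2:
            raise ValueError(f"expected a 2-D image, got shape {px.shape}")
        if px.shape[0] <= 0 or px.shape[1] <= 0:
            raise ValueError("image dimensions must be positive")
        if not np.all(np.isfinite(px)):
            raise ValueError("pixel values must be finite")
        if px.min() < 0:
            raise ValueError("pixel values must be nonnegative")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        if px.max() > 2**self.bit_depth - 1:
            raise ValueError(
                f"pixel values exceed the {self.bit_depth}-bit range"
            )
        px.setflags(write=False)  # shape and content fixed after construction
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def with_pixels(self, pixels: np.ndarray, **overrides: Any) -> "Micrograph":
        """Return a copy carrying new pixel data and updated metadata."""
        kw: dict[str, Any] = dict(
            bit_depth=self.bit_depth,
            exposure=self.exposure,
            channel=self.channel,
            corrected=self.corrected,
            meta=dict(self.meta),
        )
        kw.update(overrides)
        return Micrograph(pixels, **kw)


def write_tiff(image: Micrograph, path: str | Path) -> None:
    """Write a micrograph as a grayscale TIFF.

    Quantized images are written at their native integer depth; corrected
    (continuous) images as 32-bit float so no information is lost.
    """
    px = image.pixels
    if image.corrected or not float(px.max(initial=0.0)).is_integer():
        data = px.astype(np.float32)
    else:
        dtype = np.uint8 if image.bit_depth == 8 else np.uint16
        data = px.astype(dtype)
    tifffile.imwrite(str(path), data)


def read_tiff(
    path: str | Path,
    *,
    exposure: float = 1.0,
    channel: str = "GFP",
    corrected: bool = False,
) -> Micrograph:
    """Read a grayscale TIFF into a :class:`Micrograph`.

    Bit depth is inferred from the on-disk dtype (uint8 -> 8, otherwise 16;
    float data is treated as corrected 16-bit-range intensities).
    """
    data = tifffile.imread(str(path))
    if data.ndim != 2:
        raise ValueError(f"{path}: expected a single-channel 2-D TIFF")
    bit_depth = 8 if data.dtype == np.uint8 else 16
    if np.issubdtype(data.dtype, np.floating):
        corrected = True
    return Micrograph(
        np.asarray(data, dtype=np.float64),
        bit_depth=bit_depth,
        exposure=exposure,
        channel=channel,
        corrected=corrected,
        meta={"source": str(path)},
    )
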