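"""Retrospective flat-field / dark-field estimation and correction.

The imaging model is ``I_i(x) = flatfield(x) * S_i(x) + darkfield(x)`` with
``S_i`` the true specimen signal of image ``i``.  Given a stack of fields
acquired under identical optics, the two instrument surfaces are estimated
from the images themselves by alternating (a) a robust per-pixel split of
the stack into background (specimen-free) and foreground (cell-covered)
observations with (b) smoothness-penalized low-order polynomial surface
fits — the same low-rank-plus-smoothness idea behind retrospective shading
tools, in a dependency-free closed form.  Alternatively a predefined profile
pair can be loaded from disk.

Correction is ``corrected(x) = max(0, (I(x) - darkfield(x)) / flatfield(x))``
and keeps continuous intensity units (no re-quantization).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from skimage.filters import threshold_otsu

from .micrograph import Micrograph

__all__ = [
    "ShadingModel",
    "ImageStack",
    "estimate_shading",
    "correct_image",
    "load_shading_profile",
    "save_shading_profile",
    "identity_model",
]


@dataclass
class ShadingModel:
    """Paired flat-field (multiplicative, mean 1) and dark-field (additive)."""

    flatfield: np.ndarray
    darkfield: np.ndarray
    provenance: str = "estimated"  # "estimated" | "predefined" | "identity"
    converged: bool = True
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ff = np.asarray(self.flatfield, dtype=np.float64)
        df = np.asarray(self.darkfield, dtype=np.float64)
        if ff.shape != df.shape:
            raise ValueError("flatfield and darkfield shapes differ")
        if ff.ndim != 2:
            raise ValueError("shading surfaces must be 2-D")
        if not np.all(ff > 0):
            raise ValueError("flatfield must be strictly positive everywhere")
        if abs(ff.mean() - 1.0) > 1e-6:
            raise ValueError("flatfield mean must be 1 (normalization convention)")
        if df.min() < 0:
            raise ValueError("darkfield must be nonnegative")
        self.flatfield = ff
        self.darkfield = df

    @property
    def shape(self) -> tuple[int, int]:
        return self.flatfield.shape  # type: ignore[return-value]


def identity_model(shape: tuple[int, int]) -> ShadingModel:
    """No-op model (flat-field 1, dark-field 0) for pre-corrected data."""
    return ShadingModel(np.ones(shape), np.zeros(shape), provenance="identity")


@dataclass
class ImageStack:
    """Same-shape micrographs acquired under one optical configuration."""

    images: list[Micrograph]
    channel: str = "GFP"
    exposure: float = 1.0

    def __post_init__(self) -> None:
        if not self.images:
            raise ValueError("empty stack")
        shape = self.images[0].shape
        depth = self.images[0].bit_depth
        for im in self.images:
            if im.shape != shape:
                raise ValueError("stack images must share one shape")
            if im.bit_depth != depth:
                raise ValueError("stack images must share one bit depth")
            if im.exposure != self.exposure:
                raise ValueError(
                    "all images being compared must share the exposure time"
                )

    @property
    def shape(self) -> tuple[int, int]:
        return self.images[0].shape

    def as_array(self) -> np.ndarray:
        return np.stack([im.pixels for im in self.images])


# ---------------------------------------------------------------------------
# polynomial surface machinery


def _poly_basis(shape: tuple[int, int], degree: int) -> np.ndarray:
    """2-D polynomial basis (terms x**i * y**j, i + j <= degree), flattened."""
    h, w = shape
    y = np.linspace(-1.0, 1.0, h)[:, None] * np.ones((1, w))
    x = np.ones((h, 1)) * np.linspace(-1.0, 1.0, w)[None, :]
    cols = []
    for total in range(degree + 1):
        for i in range(total + 1):
            j = total - i
            cols.append((x**i * y**j).ravel())
    return np.stack(cols, axis=1)


def _fit_surface(
    values: np.ndarray,
    weights: np.ndarray,
    degree: int,
    ridge: float,
) -> np.ndarray:
    """Weighted ridge least-squares polynomial surface through `values`.

    The ridge penalty acts on every non-constant coefficient; it is the
    smoothness knob of the estimator.  Pixels with zero weight are ignored
    (the surface extrapolates over them).
    """
    shape = values.shape
    B = _poly_basis(shape, degree)
    w = weights.ravel()
    v = values.ravel()
    ok = w > 0
    if not np.any(ok):
        return np.zeros(shape)
    Bw = B[ok] * w[ok, None]
    A = B[ok].T @ Bw
    rhs = Bw.T @ v[ok]
    pen = np.ones(B.shape[1]) * ridge * w[ok].sum()
    pen[0] = 0.0  # never penalize the constant term
    A[np.diag_indices_from(A)] += pen
    coef = np.linalg.solve(A, rhs)
    return (B @ coef).reshape(shape)


def _downsample(a: np.ndarray, f: int) -> np.ndarray:
    """Block-mean downsample by factor f (truncating ragged edges)."""
    if f <= 1:
        return a
    h, w = a.shape
    h2, w2 = h // f, w // f
    return a[: h2 * f, : w2 * f].reshape(h2, f, w2, f).mean(axis=(1, 3))


# ---------------------------------------------------------------------------
# estimation


def estimate_shading(
    stack: ImageStack,
    *,
    smoothness: float = 1e-3,
    max_iter: int = 12,
    tol: float = 1e-4,
    min_images: int = 8,
    flat_degree: int = 4,
    dark_degree: int = 2,
    assume_zero_darkfield: bool = False,
) -> ShadingModel:
    """Estimate a :class:`ShadingModel` from an image stack.

    Alternates two steps until the surfaces stabilize (relative change below
    ``tol``) or ``max_iter`` is reached:

    1. *robust stack summary* — with the current dark-field subtracted, an
       Otsu split of the residuals classifies each (image, pixel) observation
       as background or specimen; per pixel, a trimmed mean (lower 75%,
       rejecting bright puncta) of the specimen observations summarizes the
       local gain, and the mean of background observations the local offset;
    2. *smoothness-penalized surfaces* — low-order polynomial surfaces are
       fitted through the two per-pixel summaries, weighted by observation
       counts; the flat-field is rescaled to mean 1.

    Estimation is deterministic for a fixed stack and settings and invariant
    to the order of images in the stack.  Non-convergence is reported via a
    warning and the ``converged`` flag, not an exception.

    Parameters
    ----------
    smoothness
        Ridge weight on non-constant polynomial coefficients.
    min_images
        Refuse stacks smaller than this (estimation is ill-posed).
    assume_zero_darkfield
        Pin the dark-field at 0 (for cameras with negligible offset).
    """
    if len(stack.images) < min_images:
        raise ValueError(
            f"shading estimation needs >= {min_images} images, "
            f"got {len(stack.images)}"
        )
    imgs = stack.as_array()
    shape = stack.shape
    # work on a coarse grid for speed; surfaces are smooth by assumption
    ds = max(1, min(shape) // 128)
    imgs_c = np.stack([_downsample(im, ds) for im in imgs])
    # the estimator uses only per-pixel cross-stack statistics; sorting the
    # stack axis canonicalizes float summation order, making the result
    # bit-identical under permutation of the input images
    imgs_c = np.sort(imgs_c, axis=0)
    cshape = imgs_c.shape[1:]

    dark_c = (
        np.zeros(cshape)
        if assume_zero_darkfield
        else np.full(cshape, float(np.percentile(imgs_c, 5.0)))
    )
    flat_c = np.ones(cshape)
    converged = False
    n_iter = 0

    for n_iter in range(1, max_iter + 1):
        resid = imgs_c - dark_c[None]
        spread = float(resid.max() - resid.min())
        if spread < 1e-9:
            # no spatial or temporal structure at all: identity flat-field
            new_flat = np.ones(cshape)
            new_dark = dark_c if assume_zero_darkfield else np.maximum(
                _fit_surface(
                    imgs_c.mean(axis=0), np.ones(cshape), dark_degree, smoothness
                ),
                0.0,
            )
            flat_c, dark_c = new_flat, new_dark
            converged = True
            break
        thr = float(threshold_otsu(resid.ravel()))
        fg = resid > thr

        fg_vals = np.where(fg, resid, np.nan)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            q75 = np.nanquantile(fg_vals, 0.75, axis=0)
            trim = np.where(fg_vals <= q75[None], fg_vals, np.nan)
            fg_mean = np.nanmean(trim, axis=0)
            fg_n = np.sum(np.isfinite(trim), axis=0).astype(float)
            bg_mean = np.nanmean(np.where(~fg, imgs_c, np.nan), axis=0)
            bg_n = np.sum(~fg, axis=0).astype(float)
        fg_mean = np.nan_to_num(fg_mean)
        bg_mean = np.nan_to_num(bg_mean)

        if fg_n.sum() == 0:
            new_flat = np.ones(cshape)
        else:
            surf = _fit_surface(fg_mean, fg_n, flat_degree, smoothness)
            surf = np.maximum(surf, 1e-3 * max(float(surf.max()), 1e-12))
            new_flat = surf / surf.mean()
        if assume_zero_darkfield:
            new_dark = np.zeros(cshape)
        else:
            new_dark = np.maximum(
                _fit_surface(bg_mean, bg_n, dark_degree, smoothness), 0.0
            )

        d_flat = float(np.max(np.abs(new_flat - flat_c)))
        d_dark = float(np.max(np.abs(new_dark - dark_c))) / max(
            float(np.abs(new_dark).max()), 1.0
        )
        flat_c, dark_c = new_flat, new_dark
        if max(d_flat, d_dark) < tol:
            converged = True
            break

    if not converged:
        warnings.warn(
            f"shading estimation did not converge in {max_iter} iterations; "
            "returning the last iterate",
            RuntimeWarning,
            stacklevel=2,
        )

    # evaluate the fitted surfaces back at full resolution
    if ds > 1:
        flat_full = _refit_full(flat_c, shape, flat_degree, smoothness)
        flat_full = np.maximum(flat_full, 1e-3)
        flat_full /= flat_full.mean()
        dark_full = np.maximum(
            _refit_full(dark_c, shape, dark_degree, smoothness), 0.0
        )
    else:
        flat_full = flat_c / flat_c.mean()
        dark_full = dark_c

    return ShadingModel(
        flat_full,
        dark_full,
        provenance="estimated",
        converged=converged,
        meta={
            "n_images": len(stack.images),
            "smoothness": smoothness,
            "iterations": n_iter,
            "downsample": ds,
        },
    )


def _refit_full(
    coarse: np.ndarray, shape: tuple[int, int], degree: int, ridge: float
) -> np.ndarray:
    """Lift a coarse-grid surface to full resolution via the same basis."""
    surf = _fit_surface(coarse, np.ones_like(coarse), degree, ridge)
    B_c = _poly_basis(coarse.shape, degree)
    # recover coefficients on the coarse grid, evaluate on the fine one
    coef, *_ = np.linalg.lstsq(B_c, surf.ravel(), rcond=None)
    return (_poly_basis(shape, degree) @ coef).reshape(shape)


# ---------------------------------------------------------------------------
# correction and profile I/O


def correct_image(image: Micrograph, model: ShadingModel) -> Micrograph:
    """Apply ``max(0, (I - darkfield) / flatfield)`` pixelwise."""
    if image.shape != model.shape:
        raise ValueError(
            f"image shape {image.shape} does not match model shape {model.shape}"
        )
    out = np.maximum(0.0, (image.pixels - model.darkfield) / model.flatfield)
    return image.with_pixels(
        out,
        corrected=True,
        meta={**image.meta, "shading_provenance": model.provenance},
    )


def load_shading_profile(
    flatfield: np.ndarray | str | Path,
    darkfield: np.ndarray | str | Path,
) -> ShadingModel:
    """Build a model from predefined profiles (arrays or 32-bit float TIFFs).

    The flat-field is rescaled to mean 1 (the profile is renormalized, the
    data never are); a non-positive flat-field pixel is an error.
    """
    ff = _load_grid(flatfield)
    df = _load_grid(darkfield)
    if ff.shape != df.shape:
        raise ValueError("flat-field and dark-field profiles differ in shape")
    if ff.min() <= 0:
        raise ValueError("flat-field profile contains non-positive pixels")
    ff = ff / ff.mean()
    return ShadingModel(ff, np.maximum(df, 0.0), provenance="predefined")


def _load_grid(src: np.ndarray | str | Path) -> np.ndarray:
    if isinstance(src, (str, Path)):
        return np.asarray(tifffile.imread(str(src)), dtype=np.float64)
    return np.asarray(src, dtype=np.float64)


def save_shading_profile(model: ShadingModel, directory: str | Path) -> None:
    """Write flat-field/dark-field as float32 TIFFs plus a JSON sidecar."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(str(d / "flatfield.tif"), model.flatfield.astype(np.float32))
    tifffile.imwrite(str(d / "darkfield.tif"), model.darkfield.astype(np.float32))
    sidecar = {
        "shape": list(model.shape),
        "flatfield_mean": 1.0,
        "provenance": model.provenance,
        "converged": model.converged,
    }
    (d / "shading.json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))
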