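"""Top-percentile puncta segmentation and per-field intensity metrics.

The measurement chain per corrected field is:

1. ``to_8bit`` — linear min/max rescale to 8 bit (per image by default; a
   fixed range can be supplied to preserve absolute comparability across
   images);
2. ``segment_puncta`` — select the top-fraction (default 0.05%) brightest
   pixels: with ``k = floor(f * N)`` the threshold is the ``(N - k)``-th
   order statistic and the mask keeps pixels *strictly greater* than it
   (ties excluded, so at most ``k`` pixels are ever selected);
3. ``analyze_particles`` — 8-connected components of the mask become puncta
   with per-punctum area, maximal intensity and integrated density;
4. per-field aggregation — summed punctum integrated density divided by the
   cell count gives the integrated density per cell, the quantity entering
   the relative response ratio.

Cell counts come either from a paired phase-contrast image (``count_cells``:
Otsu threshold, hole filling, distance-transform watershed) or are supplied
per field.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.morphology import remove_small_objects
from skimage.segmentation import watershed

from .micrograph import Micrograph

__all__ = [
    "Punctum",
    "PunctaSet",
    "FieldMeasurement",
    "SegmentationResult",
    "to_8bit",
    "segment_puncta",
    "analyze_particles",
    "count_cells",
    "measure_field",
]

DEFAULT_TOP_FRACTION = 0.0005  # top 0.05% of pixels


@dataclass(frozen=True)
class Punctum:
    """One segmented condensate (8-connected component of selected pixels)."""

    label: int
    pixel_coords: frozenset[tuple[int, int]]
    area_px: int
    max_intensity: float
    integrated_density: float


@dataclass
class PunctaSet:
    """All puncta of one field plus the segmentation audit trail."""

    puncta: list[Punctum]
    threshold_used: float
    top_fraction: float
    source: str = ""
    measured_on: str = "8bit"  # "8bit" | "corrected"

    def __len__(self) -> int:
        return len(self.puncta)

    @property
    def total_integrated_density(self) -> float:
        return float(sum(p.integrated_density for p in self.puncta))

    @property
    def max_intensities(self) -> list[float]:
        return [p.max_intensity for p in self.puncta]

    @property
    def total_area_px(self) -> int:
        return int(sum(p.area_px for p in self.puncta))


@dataclass
class FieldMeasurement:
    """Per-field summary keyed by condition and replicate experiment."""

    condition: str
    experiment_id: str
    field_id: str
    cell_count: int
    integrated_density_per_cell: float
    max_intensities: list[float]
    n_puncta: int = 0
    threshold_used: float = 0.0
    measured_on: str = "8bit"

    def __post_init__(self) -> None:
        if self.cell_count < 0:
            raise ValueError("cell_count must be nonnegative")
        if self.integrated_density_per_cell < 0:
            raise ValueError("integrated_density_per_cell must be nonnegative")
        self.n_puncta = len(self.max_intensities)


@dataclass
class SegmentationResult:
    mask: np.ndarray
    threshold: float
    budget_k: int
    n_selected: int


# ---------------------------------------------------------------------------


def to_8bit(
    image: Micrograph,
    vmin: float | None = None,
    vmax: float | None = None,
) -> Micrograph:
    """Linear 8-bit transform ``v -> round(255 * (v - vmin) / (vmax - vmin))``.

    By default ``vmin``/``vmax`` are the image's own extrema (per-image
    scaling); passing an explicit display range shared across a set of
    images preserves absolute comparability between them.  A constant image
    maps to all zeros by convention.  The mapping parameters are recorded in
    the output metadata for audit.
    """
    px = image.pixels
    lo = float(px.min()) if vmin is None else float(vmin)
    hi = float(px.max()) if vmax is None else float(vmax)
    if hi <= lo:
        out = np.zeros_like(px)
    else:
        out = np.clip(np.round(255.0 * (px - lo) / (hi - lo)), 0.0, 255.0)
    return image.with_pixels(
        out,
        bit_depth=8,
        meta={**image.meta, "eight_bit_vmin": lo, "eight_bit_vmax": hi},
    )


def segment_puncta(
    image: Micrograph, top_fraction: float = DEFAULT_TOP_FRACTION
) -> SegmentationResult:
    """Select the top-fraction brightest pixels of an image.

    ``k = floor(top_fraction * N)``; the threshold is the ``(N - k)``-th
    smallest pixel value and the mask keeps values strictly above it, so at
    most ``k`` pixels are selected (ties at the threshold are excluded —
    a constant image yields an empty mask).
    """
    if not 0.0 < top_fraction < 1.0:
        raise ValueError("top_fraction must lie strictly between 0 and 1")
    px = image.pixels
    n = px.size
    k = int(np.floor(top_fraction * n))
    if k == 0:
        warnings.warn(
            f"top_fraction {top_fraction} selects 0 of {n} pixels",
            RuntimeWarning,
            stacklevel=2,
        )
        return SegmentationResult(
            np.zeros(px.shape, dtype=bool), float(px.max()), 0, 0
        )
    flat = px.ravel()
    threshold = float(np.partition(flat, n - k - 1)[n - k - 1])
    mask = px > threshold
    return SegmentationResult(mask, threshold, k, int(mask.sum()))


def analyze_particles(
    mask: np.ndarray,
    intensity_image: Micrograph,
    *,
    threshold_used: float = 0.0,
    top_fraction: float = DEFAULT_TOP_FRACTION,
    source: str = "",
    measured_on: str = "8bit",
) -> PunctaSet:
    """Connected-component particle analysis of a binary mask.

    Components are 8-connected; no minimum-size or shape filter is applied
    (single-pixel puncta are legitimate).  Intensities are read from
    ``intensity_image``.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != intensity_image.shape:
        raise ValueError("mask and intensity image shapes differ")
    labels = cc_label(mask, connectivity=2)
    px = intensity_image.pixels
    puncta: list[Punctum] = []
    for lab in range(1, labels.max() + 1):
        rr, cc = np.nonzero(labels == lab)
        vals = px[rr, cc]
        puncta.append(
            Punctum(
                label=lab,
                pixel_coords=frozenset(zip(rr.tolist(), cc.tolist())),
                area_px=len(rr),
                max_intensity=float(vals.max()),
                integrated_density=float(vals.sum()),
            )
        )
    return PunctaSet(
        puncta=puncta,
        threshold_used=threshold_used,
        top_fraction=top_fraction,
        source=source,
        measured_on=measured_on,
    )


def count_cells(
    phase_image: Micrograph,
    *,
    min_area_px: int = 120,
    min_separation_px: int = 12,
) -> int:
    """Count cells in a phase-contrast image.

    Cells appear as dark regions on a light background: Otsu threshold,
    fill holes, split touching cells by a distance-transform watershed,
    count components above ``min_area_px``.  A field without genuine
    foreground/background contrast (the Otsu classes separated by less than
    four within-class standard deviations) counts as empty.
    """
    px = phase_image.pixels
    if px.size == 0 or px.max() == px.min():
        return 0
    thr = threshold_otsu(px)
    below, above = px[px < thr], px[px >= thr]
    if below.size == 0 or above.size == 0:
        return 0
    within_sd = max(float(below.std()), float(above.std()), 1e-12)
    if (float(above.mean()) - float(below.mean())) < 4.0 * within_sd:
        return 0  # no bimodal contrast: background-only field
    cells = px < thr
    cells = ndi.binary_fill_holes(cells)
    cells = remove_small_objects(cells, max_size=min_area_px - 1)
    if not cells.any():
        return 0
    distance = ndi.distance_transform_edt(cells)
    peaks = peak_local_max(
        distance, min_distance=min_separation_px, labels=cells,
        exclude_border=False,
    )
    if len(peaks) == 0:
        return 0
    markers = np.zeros(px.shape, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    labels = watershed(-distance, markers, mask=cells)
    counts = np.bincount(labels.ravel())[1:]
    return int(np.sum(counts >= min_area_px))


def measure_field(
    corrected: Micrograph,
    phase_or_count: Micrograph | int,
    *,
    top_fraction: float = DEFAULT_TOP_FRACTION,
    condition: str = "",
    experiment_id: str = "",
    field_id: str = "",
    measure_on: str = "8bit",
    eight_bit_range: tuple[float, float] | None = None,
    allow_uncorrected: bool = False,
) -> tuple[FieldMeasurement, PunctaSet]:
    """Run the full per-field measurement chain.

    Segmentation always happens on the 8-bit transform of the corrected
    image; punctum intensities are read from that same 8-bit image
    (``measure_on="8bit"``, the default) or from the corrected full-depth
    image (``measure_on="corrected"``, which preserves absolute intensity
    scale across fields).

    Parameters
    ----------
    phase_or_count
        A paired phase-contrast micrograph (cells are counted automatically)
        or a precomputed integer cell count.
    eight_bit_range
        Optional fixed (vmin, vmax) shared across compared images.
    allow_uncorrected
        Permit measuring an image that has not been shading-corrected.
    """
    if measure_on not in ("8bit", "corrected"):
        raise ValueError("measure_on must be '8bit' or 'corrected'")
    if not corrected.corrected and not allow_uncorrected:
        raise ValueError(
            "image is not shading-corrected; pass allow_uncorrected=True "
            "to measure it anyway"
        )
    if isinstance(phase_or_count, Micrograph):
        n_cells = count_cells(phase_or_count)
    else:
        n_cells = int(phase_or_count)
        if n_cells < 0:
            raise ValueError("cell count must be nonnegative")

    if eight_bit_range is None:
        img8 = to_8bit(corrected)
    else:
        img8 = to_8bit(corrected, *eight_bit_range)
    seg = segment_puncta(img8, top_fraction)
    intensity_src = img8 if measure_on == "8bit" else corrected
    puncta = analyze_particles(
        seg.mask,
        intensity_src,
        threshold_used=seg.threshold,
        top_fraction=top_fraction,
        source=field_id,
        measured_on=measure_on,
    )

    total = puncta.total_integrated_density
    if n_cells == 0:
        if len(puncta) > 0:
            raise ValueError(
                "cell count is 0 but puncta were detected: integrated "
                "density per cell is undefined"
            )
        id_per_cell = 0.0
    else:
        id_per_cell = total / n_cells

    fm = FieldMeasurement(
        condition=condition,
        experiment_id=experiment_id,
        field_id=field_id,
        cell_count=n_cells,
        integrated_density_per_cell=id_per_cell,
        max_intensities=puncta.max_intensities,
        threshold_used=seg.threshold,
        measured_on=measure_on,
    )
    return fm, puncta
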