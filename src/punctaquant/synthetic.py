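"""Synthetic yeast-field generator with full ground truth.

Emulates wide-field fluorescence micrographs of budding-yeast cells carrying
a GFP-tagged P-body marker: a dispersed cytoplasmic baseline plus discrete
bright puncta (diffraction-limited Gaussian spots), modulated by a smooth
multiplicative flat-field, offset by an additive dark-field, and degraded by
Poisson shot noise and Gaussian read noise.  A paired synthetic
phase-contrast image (dark cell interiors on a light background) supports
automated cell counting.  Every sampled quantity is recorded in a
:class:`FieldGroundTruth` so downstream stages (shading correction,
segmentation, statistics) can be tested against known truth.

Condition presets parameterize the biological states of interest — log-phase
growth, diauxic shift, glucose deprivation, vector control vs. scaffold
overexpression, cycloheximide persistence, and hexanediol dispersal (which
conserves total cell fluorescence while redistributing punctum intensity
into the cytoplasm, consistent with unchanged protein levels).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from skimage.draw import ellipse as draw_ellipse

from .micrograph import Micrograph

__all__ = [
    "ConditionPreset",
    "FieldGroundTruth",
    "ExperimentDesign",
    "FieldRecord",
    "SimulatedExperiment",
    "PRESETS",
    "dispersed_variant",
    "generate_field",
    "generate_experiment",
    "punctum_volume",
]

MAX_16BIT = 65535.0
TRUNCATION_SIGMAS = 4.0  # spots rendered out to 4 sigma
#: fraction of a 2-D Gaussian's volume inside the 4-sigma truncation disc
TRUNCATION_MASS = 1.0 - math.exp(-TRUNCATION_SIGMAS**2 / 2.0)


@dataclass(frozen=True)
class ConditionPreset:
    """Pre-shading, pre-noise intensity statistics of one biological state.

    All intensities are in raw camera counts before the flat-field, dark-field
    and noise are applied.

    Parameters
    ----------
    name
        Preset label.
    puncta_per_cell_mean
        Mean of the per-cell punctum count distribution.
    puncta_dispersion
        Negative-binomial shape (``var = mu + mu**2 / k``); ``None`` means
        Poisson counts.
    punctum_amplitude_mean, punctum_amplitude_cv
        Mean peak amplitude (counts above the cytoplasmic baseline) and its
        coefficient of variation; amplitudes are log-normal.
    punctum_sigma_px
        Isotropic Gaussian spot width in pixels.
    cytoplasm_baseline
        Mean dispersed cytoplasmic intensity inside cells, in counts.
    condensed
        Whether the state carries discrete condensates.
    """

    name: str
    puncta_per_cell_mean: float
    punctum_amplitude_mean: float
    punctum_amplitude_cv: float
    punctum_sigma_px: float
    cytoplasm_baseline: float
    condensed: bool
    puncta_dispersion: float | None = None

    def __post_init__(self) -> None:
        if self.puncta_per_cell_mean < 0:
            raise ValueError("puncta_per_cell_mean must be nonnegative")
        if self.punctum_sigma_px <= 0:
            raise ValueError("punctum_sigma_px must be positive")
        if self.cytoplasm_baseline < 0:
            raise ValueError("cytoplasm_baseline must be nonnegative")
        if self.condensed:
            if self.punctum_amplitude_mean <= 0:
                raise ValueError("condensed preset requires a positive amplitude mean")
        elif self.puncta_per_cell_mean > 0 and self.punctum_amplitude_mean <= 0:
            raise ValueError("puncta with nonpositive amplitude are not meaningful")


@dataclass
class FieldGroundTruth:
    """Everything sampled while rendering one field."""

    seed: int
    cell_records: list[tuple[float, float, float, float, float]]
    """Per cell: (row, col, semi-axis a, semi-axis b, orientation rad)."""
    puncta_records: list[tuple[float, float, float, float, int]]
    """Per punctum: (row, col, amplitude, sigma, parent cell index)."""
    flatfield_true: np.ndarray
    darkfield_true: np.ndarray
    noise_params: tuple[float, float]
    """(photon gain, read-noise SD)."""
    ambient_background: float
    """Shading-affected ambient (autofluorescence/stray-light) level."""
    cell_coverage_px: int
    """Number of pixels covered by the union of cell interiors."""
    preset: ConditionPreset | None = None

    @property
    def cell_count(self) -> int:
        return len(self.cell_records)


def punctum_volume(amplitude: float, sigma: float) -> float:
    """Integrated intensity of a truncated Gaussian spot (counts x px^2)."""
    return amplitude * 2.0 * math.pi * sigma**2 * TRUNCATION_MASS


# ---------------------------------------------------------------------------
# presets

_BASELINE = 120.0
_SIGMA_PX = 1.0
_CV = 0.2
_MEAN_CELL_AREA_PX = math.pi * 20.0 * 18.0  # nominal ellipse, radii 15-25 px


def dispersed_variant(
    preset: ConditionPreset,
    name: str,
    mean_cell_area_px: float = _MEAN_CELL_AREA_PX,
) -> ConditionPreset:
    """Dispersal counterpart of a condensed preset, conserving fluorescence.

    The punctum intensity budget (mean count x mean spot volume) is folded
    into the cytoplasmic baseline, spread over the mean cell area — the
    situation after 1,6-hexanediol treatment or glucose replenishment, where
    condensates dissolve but the tagged protein's cellular level is unchanged.
    """
    redistributed = (
        preset.puncta_per_cell_mean
        * punctum_volume(preset.punctum_amplitude_mean, preset.punctum_sigma_px)
        / mean_cell_area_px
    )
    return replace(
        preset,
        name=name,
        puncta_per_cell_mean=0.0,
        punctum_amplitude_mean=0.0,
        punctum_amplitude_cv=0.0,
        cytoplasm_baseline=preset.cytoplasm_baseline + redistributed,
        condensed=False,
    )


_DIAUXIC = ConditionPreset(
    "diauxic", puncta_per_cell_mean=1.0, punctum_amplitude_mean=800.0,
    punctum_amplitude_cv=_CV, punctum_sigma_px=_SIGMA_PX,
    cytoplasm_baseline=_BASELINE, condensed=True,
)
_VECTOR = ConditionPreset(
    "vector", puncta_per_cell_mean=0.8, punctum_amplitude_mean=300.0,
    punctum_amplitude_cv=_CV, punctum_sigma_px=_SIGMA_PX,
    cytoplasm_baseline=_BASELINE, condensed=True,
)

PRESETS: dict[str, ConditionPreset] = {
    "log_phase": ConditionPreset(
        "log_phase", puncta_per_cell_mean=0.6, punctum_amplitude_mean=250.0,
        punctum_amplitude_cv=_CV, punctum_sigma_px=_SIGMA_PX,
        cytoplasm_baseline=_BASELINE, condensed=True,
    ),
    "diauxic": _DIAUXIC,
    "glucose_deprivation": ConditionPreset(
        "glucose_deprivation", puncta_per_cell_mean=1.2,
        punctum_amplitude_mean=900.0, punctum_amplitude_cv=_CV,
        punctum_sigma_px=_SIGMA_PX, cytoplasm_baseline=_BASELINE,
        condensed=True,
    ),
    "vector": _VECTOR,
    # scaffold overexpression: 4x the vector-control punctum amplitude
    "overexpression": replace(
        _VECTOR, name="overexpression", punctum_amplitude_mean=1200.0
    ),
    "chx_persistent": replace(
        _VECTOR, name="chx_persistent", punctum_amplitude_mean=1200.0
    ),
    "hexanediol": dispersed_variant(_DIAUXIC, "hexanediol"),
    "glucose_replenishment": dispersed_variant(_DIAUXIC, "glucose_replenishment"),
}


# ---------------------------------------------------------------------------
# field rendering


def _sample_cells(
    rng: np.random.Generator,
    n_cells: int,
    shape: tuple[int, int],
    radius_range: tuple[float, float],
) -> list[tuple[float, float, float, float, float]]:
    """Place near-non-overlapping ellipses fully inside the image."""
    cells: list[tuple[float, float, float, float, float]] = []
    h, w = shape
    max_tries = 400 * max(n_cells, 1)
    tries = 0
    while len(cells) < n_cells and tries < max_tries:
        tries += 1
        a = rng.uniform(*radius_range)
        b = a * rng.uniform(0.75, 1.0)
        margin = a + 2.0
        if 2 * margin >= min(h, w):
            raise ValueError("image too small for the configured cell radii")
        r = rng.uniform(margin, h - margin)
        c = rng.uniform(margin, w - margin)
        mean_r = (a + b) / 2.0
        ok = all(
            math.hypot(r - rr, c - cc) > 0.85 * (mean_r + (aa + bb) / 2.0)
            for rr, cc, aa, bb, _ in cells
        )
        if ok:
            cells.append((r, c, a, b, rng.uniform(0.0, math.pi)))
    if len(cells) < n_cells:
        raise ValueError(
            f"could only place {len(cells)}/{n_cells} cells; "
            "reduce cell count or radii for this image size"
        )
    return cells


def _render_spot(
    signal: np.ndarray, r0: float, c0: float, amplitude: float, sigma: float
) -> None:
    """Add a truncated isotropic Gaussian in place."""
    h, w = signal.shape
    rad = TRUNCATION_SIGMAS * sigma
    r_lo = max(int(math.floor(r0 - rad)), 0)
    r_hi = min(int(math.ceil(r0 + rad)) + 1, h)
    c_lo = max(int(math.floor(c0 - rad)), 0)
    c_hi = min(int(math.ceil(c0 + rad)) + 1, w)
    rr, cc = np.mgrid[r_lo:r_hi, c_lo:c_hi]
    d2 = (rr - r0) ** 2 + (cc - c0) ** 2
    g = np.where(d2 <= rad**2, np.exp(-d2 / (2.0 * sigma**2)), 0.0)
    signal[r_lo:r_hi, c_lo:c_hi] += amplitude * g


def _default_flatfield(
    rng: np.random.Generator, shape: tuple[int, int]
) -> np.ndarray:
    """Radial polynomial gain surface scaled into [0.7, 1.3], mean 1."""
    h, w = shape
    rr, cc = np.mgrid[0:h, 0:w]
    rho2 = ((rr - (h - 1) / 2) / (h / 2)) ** 2 + ((cc - (w - 1) / 2) / (w / 2)) ** 2
    rho2 /= rho2.max()
    a2 = rng.uniform(-0.25, -0.10)  # vignetting: dimmer at the corners
    a4 = rng.uniform(-0.05, 0.05)
    f = 1.0 + a2 * rho2 + a4 * rho2**2
    lo, hi = f.min(), f.max()
    if hi - lo > 1e-12:  # rescale span into [0.7, 1.3] territory
        span = min(0.3, (hi - lo) / 2.0)
        f = 1.0 - span + 2.0 * span * (f - lo) / (hi - lo)
    return f / f.mean()


def _default_darkfield(
    rng: np.random.Generator, shape: tuple[int, int]
) -> np.ndarray:
    """Constant camera offset plus a mild planar gradient."""
    h, w = shape
    rr, cc = np.mgrid[0:h, 0:w]
    base = rng.uniform(35.0, 45.0)
    gr = rng.uniform(-8.0, 8.0)
    gc = rng.uniform(-8.0, 8.0)
    d = base + gr * (rr / max(h - 1, 1) - 0.5) + gc * (cc / max(w - 1, 1) - 0.5)
    return np.maximum(d, 0.0)


def generate_field(
    preset: ConditionPreset,
    n_cells: int,
    *,
    shading: bool = True,
    seed: int = 0,
    shape: tuple[int, int] = (512, 512),
    gain: float = 1.0,
    read_noise_sd: float = 2.0,
    flatfield: np.ndarray | None = None,
    darkfield: np.ndarray | None = None,
    cell_radius_range: tuple[float, float] = (15.0, 25.0),
    ambient_background: float = 20.0,
) -> tuple[Micrograph, Micrograph, FieldGroundTruth]:
    """Render one fluorescence/phase image pair with ground truth.

    The fluorescence image is built as
    ``flatfield * (ambient + baseline * cells + sum of Gaussian puncta)
    + darkfield`` — ``ambient_background`` models medium autofluorescence
    and stray light, present everywhere and shaded like any real photon
    flux —,
    then passed through Poisson shot noise (scaled by ``gain``; ``gain = 0``
    disables it) and additive Gaussian read noise, rounded to integer counts
    and clipped to the 16-bit range.  Identical arguments give bit-identical
    output.

    Parameters
    ----------
    preset
        Intensity statistics of the biological condition.
    n_cells
        Number of cells to place (near-non-overlapping filled ellipses).
    shading
        Apply the flat-field/dark-field model; when off, the true model in
        the returned ground truth is identity (flat 1, dark 0).
    seed
        RNG seed; the single source of randomness.
    flatfield, darkfield
        Optional explicit shading surfaces (used by recovery tests); ignored
        when ``shading`` is off.
    """
    h, w = shape
    if h <= 0 or w <= 0:
        raise ValueError("image dimensions must be positive")
    if preset.punctum_sigma_px >= min(h, w):
        raise ValueError("punctum sigma must be smaller than the image")
    if n_cells < 0:
        raise ValueError("n_cells must be nonnegative")

    rng = np.random.default_rng(seed)

    cells = _sample_cells(rng, n_cells, shape, cell_radius_range)
    cell_mask = np.zeros(shape, dtype=bool)
    for r, c, a, b, th in cells:
        rr, cc = draw_ellipse(r, c, a, b, shape=shape, rotation=th)
        cell_mask[rr, cc] = True

    if ambient_background < 0:
        raise ValueError("ambient_background must be nonnegative")
    signal = ambient_background + np.where(
        cell_mask, preset.cytoplasm_baseline, 0.0
    )

    # punctum counts, positions (interior 70% of each cell), amplitudes
    puncta: list[tuple[float, float, float, float, int]] = []
    mu = preset.puncta_per_cell_mean
    sig_ln = math.sqrt(math.log(1.0 + preset.punctum_amplitude_cv**2))
    for ci, (r, c, a, b, th) in enumerate(cells):
        if mu <= 0:
            n_p = 0
        elif preset.puncta_dispersion is None:
            n_p = int(rng.poisson(mu))
        else:
            k = preset.puncta_dispersion
            n_p = int(rng.negative_binomial(k, k / (k + mu)))
        for _ in range(n_p):
            # uniform in the interior ellipse (70% of the radii)
            u = math.sqrt(rng.uniform())
            phi = rng.uniform(0.0, 2.0 * math.pi)
            dr_ = 0.7 * a * u * math.cos(phi)
            dc_ = 0.7 * b * u * math.sin(phi)
            pr = r + dr_ * math.cos(th) - dc_ * math.sin(th)
            pc = c + dr_ * math.sin(th) + dc_ * math.cos(th)
            amp = preset.punctum_amplitude_mean * rng.lognormal(
                -(sig_ln**2) / 2.0, sig_ln
            )
            _render_spot(signal, pr, pc, amp, preset.punctum_sigma_px)
            puncta.append((pr, pc, amp, preset.punctum_sigma_px, ci))

    if shading:
        ff = flatfield if flatfield is not None else _default_flatfield(rng, shape)
        df = darkfield if darkfield is not None else _default_darkfield(rng, shape)
        ff = np.asarray(ff, dtype=np.float64)
        df = np.asarray(df, dtype=np.float64)
        if ff.shape != shape or df.shape != shape:
            raise ValueError("shading surfaces must match the image shape")
        ff = ff / ff.mean()  # normalization convention: mean 1
    else:
        ff = np.ones(shape)
        df = np.zeros(shape)

    img = ff * signal + df
    if gain > 0:
        img = rng.poisson(np.maximum(img, 0.0) / gain) * gain
    if read_noise_sd > 0:
        img = img + rng.normal(0.0, read_noise_sd, size=shape)
    img = np.clip(np.round(img), 0.0, MAX_16BIT)

    fluor = Micrograph(
        img, bit_depth=16, channel=preset.name, corrected=not shading,
        meta={"seed": seed, "preset": preset.name, "shading": shading},
    )

    # synthetic phase contrast: dark cell interiors on a light background
    phase_px = np.where(cell_mask, 80.0, 200.0)
    phase_px = phase_px + rng.normal(0.0, 2.0, size=shape)
    phase_px = np.clip(np.round(phase_px), 0.0, MAX_16BIT)
    phase = Micrograph(
        phase_px, bit_depth=16, channel="phase",
        meta={"seed": seed, "preset": preset.name},
    )

    gt = FieldGroundTruth(
        seed=seed,
        cell_records=cells,
        puncta_records=puncta,
        flatfield_true=ff,
        darkfield_true=df,
        noise_params=(gain, read_noise_sd),
        ambient_background=ambient_background,
        cell_coverage_px=int(cell_mask.sum()),
        preset=preset,
    )
    return fluor, phase, gt


# ---------------------------------------------------------------------------
# experiment-level simulation


@dataclass(frozen=True)
class ExperimentDesign:
    """Replicated multi-group imaging design.

    Mirrors the replication structure of the biological experiments: each
    group (strain x construct x preset) is imaged in ``n_experiments``
    independent experiments of ``n_fields_per_experiment`` fields each.
    """

    groups: tuple[tuple[str, str, ConditionPreset], ...]
    """(strain label, construct label, preset) per group."""
    n_experiments: int = 3
    n_fields_per_experiment: int = 2
    cells_per_field: int = 50
    base_seed: int = 0
    shape: tuple[int, int] = (512, 512)
    shading: bool = True
    gain: float = 1.0
    read_noise_sd: float = 2.0

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("design needs at least one group")
        if self.n_experiments < 1:
            raise ValueError("n_experiments must be >= 1")
        if self.n_fields_per_experiment < 1:
            raise ValueError("n_fields_per_experiment must be >= 1")

    @property
    def group_names(self) -> list[str]:
        return [f"{s}:{c}" for s, c, _ in self.groups]


@dataclass
class FieldRecord:
    group: str
    strain: str
    construct: str
    experiment_id: str
    field_id: str
    seed: int
    fluorescence: Micrograph
    phase: Micrograph
    ground_truth: FieldGroundTruth


@dataclass
class SimulatedExperiment:
    design: ExperimentDesign
    records: list[FieldRecord]

    @property
    def amplitude_means(self) -> dict[str, float]:
        """Ground-truth mean punctum amplitude per group (the effect size)."""
        return {
            f"{s}:{c}": p.punctum_amplitude_mean for s, c, p in self.design.groups
        }

    def amplitude_ratio(self, group_a: str, group_b: str) -> float:
        means = self.amplitude_means
        if means[group_b] == 0.0:
            return math.inf if means[group_a] > 0 else 1.0
        return means[group_a] / means[group_b]


def _field_seed(base_seed: int, index: int) -> int:
    # distinct by construction for index < 2**31; stays below 2**31
    return (base_seed * 1_000_003 + index) % 2**31


def generate_experiment(design: ExperimentDesign) -> SimulatedExperiment:
    """Simulate every group x experiment x field of a design.

    Per-field seeds derive deterministically from ``base_seed`` and are
    pairwise distinct, so reruns reproduce every image bit for bit.
    """
    records: list[FieldRecord] = []
    idx = 0
    for strain, construct, preset in design.groups:
        group = f"{strain}:{construct}"
        for e in range(design.n_experiments):
            for f in range(design.n_fields_per_experiment):
                seed = _field_seed(design.base_seed, idx)
                idx += 1
                fluor, phase, gt = generate_field(
                    preset,
                    design.cells_per_field,
                    shading=design.shading,
                    seed=seed,
                    shape=design.shape,
                    gain=design.gain,
                    read_noise_sd=design.read_noise_sd,
                )
                records.append(
                    FieldRecord(
                        group=group,
                        strain=strain,
                        construct=construct,
                        experiment_id=f"E{e + 1}",
                        field_id=f"F{f + 1}",
                        seed=seed,
                        fluorescence=fluor,
                        phase=phase,
                        ground_truth=gt,
                    )
                )
    return SimulatedExperiment(design=design, records=records)
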