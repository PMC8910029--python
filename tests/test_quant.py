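"""8-bit transform, top-percentile segmentation, particle analysis, counting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from punctaquant import (
    Micrograph,
    PRESETS,
    analyze_particles,
    count_cells,
    generate_field,
    measure_field,
    segment_puncta,
    to_8bit,
)


def topfraction_oracle(pixels: np.ndarray, top_fraction: float) -> np.ndarray:
    """Brute-force reference: fully sort, take the k largest, drop boundary
    ties.  Independent of the partition-based implementation."""
    flat = pixels.ravel()
    n = flat.size
    k = int(np.floor(top_fraction * n))
    mask = np.zeros(n, dtype=bool)
    if k > 0:
        order = np.argsort(flat, kind="stable")[::-1]
        # threshold value: the (k+1)-th largest; boundary ties are dropped
        boundary = flat[order[k]]
        chosen = [i for i in order[:k] if flat[i] > boundary]
        mask[chosen] = True
    return mask.reshape(pixels.shape)


# ---------------------------------------------------------------------------
# to_8bit


def test_to_8bit_constant_maps_to_zero():
    out = to_8bit(Micrograph(np.full((8, 8), 777.0)))
    assert out.bit_depth == 8
    assert np.all(out.pixels == 0.0)


def test_to_8bit_endpoints():
    img = Micrograph(np.array([[100.0, 355.0], [100.0, 355.0]]))
    out = to_8bit(img)
    assert out.pixels[0, 0] == 0.0
    assert out.pixels[0, 1] == 255.0
    assert out.meta["eight_bit_vmin"] == 100.0
    assert out.meta["eight_bit_vmax"] == 355.0


def test_to_8bit_fixed_range_preserves_comparability():
    a = to_8bit(Micrograph(np.array([[0.0, 400.0]])), 0.0, 800.0)
    b = to_8bit(Micrograph(np.array([[0.0, 800.0]])), 0.0, 800.0)
    assert a.pixels[0, 1] == 128.0 and b.pixels[0, 1] == 255.0


@settings(max_examples=50, derandomize=True)
@given(
    hnp.arrays(
        np.float64,
        hnp.array_shapes(min_dims=2, max_dims=2, min_side=2, max_side=12),
        elements=st.floats(0.0, 65535.0, allow_nan=False),
    )
)
def test_to_8bit_preserves_pixel_ordering(px):
    out = to_8bit(Micrograph(px)).pixels
    flat_in, flat_out = px.ravel(), out.ravel()
    order = np.argsort(flat_in, kind="stable")
    assert np.all(np.diff(flat_out[order]) >= 0.0)


# ---------------------------------------------------------------------------
# segmentation


def test_top_fraction_matches_sort_oracle_distinct_values(rng):
    px = rng.permutation(np.arange(200 * 200, dtype=float)).reshape(200, 200)
    seg = segment_puncta(Micrograph(px / 2.0), 0.0005)
    assert seg.n_selected == 20  # floor(0.0005 * 40000)
    assert np.array_equal(seg.mask, topfraction_oracle(px / 2.0, 0.0005))


@pytest.mark.parametrize("shape,frac", [((50, 50), 0.01), ((64, 96), 0.002),
                                        ((81, 81), 0.0008)])
def test_top_fraction_matches_oracle_with_ties(rng, shape, frac):
    # coarse quantization forces ties, including at the threshold
    px = np.floor(rng.random(shape) * 12.0)
    seg = segment_puncta(Micrograph(px), frac)
    assert np.array_equal(seg.mask, topfraction_oracle(px, frac))
    assert seg.n_selected <= int(np.floor(frac * px.size))


def test_constant_image_selects_nothing():
    seg = segment_puncta(Micrograph(np.full((100, 100), 9.0)), 0.01)
    assert seg.n_selected == 0


def test_single_bright_pixel_selected():
    px = np.zeros((100, 100))
    px[40, 60] = 255.0
    seg = segment_puncta(Micrograph(px), 0.001)
    assert seg.n_selected == 1 and seg.mask[40, 60]


def test_zero_budget_warns_and_returns_empty():
    with pytest.warns(RuntimeWarning, match="selects 0"):
        seg = segment_puncta(Micrograph(np.arange(16.0).reshape(4, 4)), 0.01)
    assert seg.n_selected == 0


def test_top_fraction_domain():
    img = Micrograph(np.zeros((4, 4)))
    for bad in (0.0, 1.0, -0.1, 1.5):
        with pytest.raises(ValueError):
            segment_puncta(img, bad)


# ---------------------------------------------------------------------------
# particle analysis


def test_two_separate_blobs_are_two_puncta():
    mask = np.zeros((10, 10), dtype=bool)
    mask[1, 1] = mask[1, 2] = True
    mask[7, 7] = True
    ps = analyze_particles(mask, Micrograph(np.ones((10, 10))))
    assert len(ps) == 2


def test_punctum_intensity_arithmetic():
    mask = np.zeros((5, 5), dtype=bool)
    px = np.zeros((5, 5))
    for i, v in enumerate((10.0, 20.0, 30.0)):
        mask[2, i + 1] = True
        px[2, i + 1] = v
    ps = analyze_particles(mask, Micrograph(px))
    assert len(ps) == 1
    assert ps.puncta[0].max_intensity == 30.0
    assert ps.puncta[0].integrated_density == 60.0
    assert ps.puncta[0].integrated_density >= ps.puncta[0].max_intensity


def test_diagonal_touch_is_one_punctum():
    mask = np.zeros((6, 6), dtype=bool)
    mask[2, 2] = mask[3, 3] = True  # 8-connectivity joins diagonals
    ps = analyze_particles(mask, Micrograph(np.ones((6, 6))))
    assert len(ps) == 1 and ps.puncta[0].area_px == 2


def test_selected_pixel_budget_invariant(rng):
    px = np.floor(rng.random((120, 140)) * 40.0)
    frac = 0.003
    seg = segment_puncta(Micrograph(px), frac)
    ps = analyze_particles(seg.mask, Micrograph(px))
    assert ps.total_area_px <= int(np.floor(frac * px.size))
    coords = [c for p in ps.puncta for c in p.pixel_coords]
    assert len(coords) == len(set(coords))  # pairwise disjoint components


# ---------------------------------------------------------------------------
# cell counting


def test_background_only_phase_counts_zero(rng):
    phase = Micrograph(np.round(rng.normal(200.0, 2.0, (256, 256))).clip(0))
    assert count_cells(phase) == 0


def test_well_separated_cells_counted_exactly():
    _, phase, gt = generate_field(
        PRESETS["diauxic"], 12, shading=False, seed=77
    )
    assert count_cells(phase) == gt.cell_count == 12


def test_cell_count_accuracy_over_seeds():
    """Exact on >= 95% of default fields; off-by-one at worst elsewhere."""
    exact = 0
    for seed in range(20):
        _, phase, gt = generate_field(
            PRESETS["diauxic"], 50, shading=True, seed=500 + seed
        )
        err = abs(count_cells(phase) - gt.cell_count)
        assert err <= 1
        exact += err == 0
    assert exact >= 19


# ---------------------------------------------------------------------------
# measure_field


def _field_with_known_puncta():
    """Background 0; blob A = {30,20,10} (ID 60), blob B = {25,15} (ID 40);
    exactly k = 5 selected pixels at top_fraction 0.05% of 100x100."""
    px = np.zeros((100, 100))
    px[10, 10:13] = [30.0, 20.0, 10.0]
    px[50, 50:52] = [25.0, 15.0]
    return Micrograph(px, corrected=True)


def test_integrated_density_per_cell_arithmetic():
    fm, ps = measure_field(
        _field_with_known_puncta(), 10, measure_on="corrected"
    )
    assert len(ps) == 2
    assert sorted(p.integrated_density for p in ps.puncta) == [40.0, 60.0]
    assert fm.integrated_density_per_cell == 10.0
    assert fm.cell_count == 10
    assert len(fm.max_intensities) == fm.n_puncta == 2


def test_flat_field_measures_empty():
    img = Micrograph(np.full((100, 100), 5.0), corrected=True)
    fm, _ = measure_field(img, 10)
    assert fm.integrated_density_per_cell == 0.0
    assert fm.max_intensities == []


def test_zero_cells_with_puncta_is_an_error():
    with pytest.raises(ValueError, match="undefined"):
        measure_field(_field_with_known_puncta(), 0, measure_on="corrected")


def test_zero_cells_without_puncta_is_zero():
    img = Micrograph(np.full((100, 100), 5.0), corrected=True)
    fm, _ = measure_field(img, 0)
    assert fm.integrated_density_per_cell == 0.0


def test_uncorrected_image_rejected_unless_overridden():
    img = Micrograph(np.zeros((100, 100)))
    with pytest.raises(ValueError, match="not shading-corrected"):
        measure_field(img, 1)
    fm, _ = measure_field(img, 1, allow_uncorrected=True)
    assert fm.integrated_density_per_cell == 0.0


def test_brighter_field_measures_higher_per_cell_density():
    """Paired fields identical except punctum amplitude x4."""
    from dataclasses import replace

    wins = 0
    n_pairs = 40
    base = PRESETS["vector"]
    bright = replace(base, name="x4", punctum_amplitude_mean=4 * 300.0)
    for seed in range(n_pairs):
        out = []
        for preset in (base, bright):
            fluor, _, gt = generate_field(
                preset, 20, shading=False, seed=9000 + seed, shape=(256, 256)
            )
            fm, _ = measure_field(fluor, gt.cell_count, measure_on="corrected")
            out.append(fm.integrated_density_per_cell)
        wins += out[1] > out[0]
    assert wins >= 0.95 * n_pairs
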