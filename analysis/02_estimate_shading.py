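#!/usr/bin/env python
"""Estimate the flat-field/dark-field from a shaded synthetic stack and
score the recovery against the known ground truth.

Findings (seed 0): the flat-field is recovered to about 1% relative RMSE
from 32 fields; the estimated dark-field converges to
``flatfield * ambient + darkfield`` (the retrospective identifiability
limit — a uniform ambient flux is indistinguishable from camera offset);
and on a zero-offset stack the correction flattens the cell-free
background's coefficient of variation by an order of magnitude.  The
profile is saved under ``results/shading_profile/``.
"""

import argparse
from pathlib import Path

import numpy as np

from punctaquant import (
    ImageStack,
    PRESETS,
    correct_image,
    estimate_shading,
    generate_field,
    save_shading_profile,
)

AMBIENT = 20.0


def radial_flatfield(shape, lo=0.8, hi=1.2):
    h, w = shape
    rr, cc = np.mgrid[0:h, 0:w]
    rho2 = ((rr - (h - 1) / 2) / (h / 2)) ** 2 + (
        (cc - (w - 1) / 2) / (w / 2)
    ) ** 2
    f = hi - (hi - lo) * rho2 / rho2.max()
    return f / f.mean()


def make_stack(seed, shape, ff, df, **kw):
    images = []
    for i in range(32):
        fluor, _, _ = generate_field(
            PRESETS["diauxic"], 20, shading=True,
            seed=(seed * 1_000_003 + i) % 2**31, shape=shape,
            flatfield=ff, darkfield=df, cell_radius_range=(7, 11), **kw,
        )
        images.append(fluor)
    return ImageStack(images)


def main(seed: int = 0, out_dir: str = "results/shading_profile") -> None:
    shape = (128, 128)
    ff_true = radial_flatfield(shape)
    df_true = np.full(shape, 10.0)

    # recovery on a realistic noisy stack
    model = estimate_shading(make_stack(seed, shape, ff_true, df_true))
    rel_rmse = float(
        np.sqrt(np.mean((model.flatfield - ff_true) ** 2 / ff_true**2))
    )
    dark_vs_absorbed = float(
        np.abs(model.darkfield - (ff_true * AMBIENT + df_true)).mean()
    )
    print(f"flat-field relative RMSE              : {rel_rmse:.4f}")
    print(
        "dark-field vs flatfield*ambient+offset: "
        f"{dark_vs_absorbed:.2f} counts mean abs deviation"
    )

    # background flattening, isolated from noise and offset
    flat_stack = make_stack(
        seed + 1, shape, ff_true, np.zeros(shape),
        gain=0.0, read_noise_sd=0.0,
    )
    flat_model = estimate_shading(flat_stack, assume_zero_darkfield=True)
    raw_cv, cor_cv = [], []
    for im in flat_stack.images:
        bg = im.pixels < np.percentile(im.pixels, 40)
        cor = correct_image(im, flat_model).pixels
        raw_cv.append(im.pixels[bg].std() / im.pixels[bg].mean())
        cor_cv.append(cor[bg].std() / max(cor[bg].mean(), 1e-9))
    print(
        f"background CV (noise-free, no offset) : raw {np.mean(raw_cv):.3f} "
        f"-> corrected {np.mean(cor_cv):.3f}"
    )

    save_shading_profile(model, out_dir)
    print(f"profile saved to {Path(out_dir)}")


if __name__ == "__main__":
    p = argparse.ArgumentParser(description=__doc__)
    p.add_argument("--seed", type=int, default=0)
    p.add_argument("--out", default="results/shading_profile")
    a = p.parse_args()
    main(a.seed, a.out)
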