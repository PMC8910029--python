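"""Declarative pipeline configuration: parsing, defaulting, validation.

A run is described by a single YAML (or dict) document.  Validation is
strict — unknown keys, undefined group references and out-of-range values
are collected into one human-readable error — and every resolved value is
echoed into the run manifest so no default stays hidden.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import yaml

from .quant import DEFAULT_TOP_FRACTION
from .synthetic import PRESETS

__all__ = ["PipelineConfig", "GroupSpec", "ComparisonSpec", "RRRSpec",
           "ConfigError", "validate_config"]


class ConfigError(ValueError):
    """Invalid pipeline configuration; the message lists every problem."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__(
            "invalid pipeline configuration:\n" +
            "\n".join(f"  - {p}" for p in problems)
        )


@dataclass(frozen=True)
class GroupSpec:
    strain: str
    construct: str
    preset: str

    @property
    def name(self) -> str:
        return f"{self.strain}:{self.construct}"


@dataclass(frozen=True)
class ComparisonSpec:
    a: str
    b: str
    metric: str = "max_intensity"  # "max_intensity" | "intden_per_cell"
    test: str = "nested"  # "student" | "welch" | "nested"


@dataclass(frozen=True)
class RRRSpec:
    """Role assignment for the relative response ratio.

    ``test``/``neg``/``pos`` are construct labels; ``mut``/``wt`` strain
    labels.  The six integrated-density-per-cell inputs come from the grand
    means of the corresponding strain x construct groups.
    """

    test: str
    neg: str
    pos: str
    mut: str
    wt: str


@dataclass
class PipelineConfig:
    mode: str = "simulate"  # "simulate" | "directory"
    groups: tuple[GroupSpec, ...] = ()
    n_experiments: int = 3
    n_fields_per_experiment: int = 2
    cells_per_field: int = 50
    image_shape: tuple[int, int] = (512, 512)
    simulate_shading: bool = True
    manifest: str | None = None  # directory mode: CSV describing the fields
    top_fraction: float = DEFAULT_TOP_FRACTION
    shading: str = "estimate"  # "estimate" | "identity" | profile directory
    measure_on: str = "8bit"
    eight_bit_range: tuple[float, float] | None = None
    comparisons: tuple[ComparisonSpec, ...] = ()
    rrr: RRRSpec | None = None
    base_seed: int = 0
    out_dir: str = "results/run"

    def resolved(self) -> dict[str, Any]:
        """Every resolved value, for the run manifest."""
        return {
            "mode": self.mode,
            "groups": [
                {"strain": g.strain, "construct": g.construct,
                 "preset": g.preset} for g in self.groups
            ],
            "n_experiments": self.n_experiments,
            "n_fields_per_experiment": self.n_fields_per_experiment,
            "cells_per_field": self.cells_per_field,
            "image_shape": list(self.image_shape),
            "simulate_shading": self.simulate_shading,
            "manifest": self.manifest,
            "top_fraction": self.top_fraction,
            "shading": self.shading,
            "measure_on": self.measure_on,
            "eight_bit_range": (
                list(self.eight_bit_range) if self.eight_bit_range else None
            ),
            "comparisons": [
                {"a": c.a, "b": c.b, "metric": c.metric, "test": c.test}
                for c in self.comparisons
            ],
            "rrr": (
                {"test": self.rrr.test, "neg": self.rrr.neg,
                 "pos": self.rrr.pos, "mut": self.rrr.mut, "wt": self.rrr.wt}
                if self.rrr else None
            ),
            "base_seed": self.base_seed,
            "out_dir": self.out_dir,
        }


_TOP_KEYS = {
    "mode", "design", "manifest", "top_fraction", "shading", "measure_on",
    "eight_bit_range", "comparisons", "rrr", "base_seed", "out_dir",
}
_DESIGN_KEYS = {
    "groups", "n_experiments", "n_fields_per_experiment", "cells_per_field",
    "image_shape", "shading",
}


def validate_config(source: str | Path | Mapping[str, Any]) -> PipelineConfig:
    """Parse, default and validate a pipeline configuration.

    Raises :class:`ConfigError` carrying the full list of problems.
    """
    if isinstance(source, (str, Path)):
        doc = yaml.safe_load(Path(source).read_text())
    else:
        doc = dict(source)
    if not isinstance(doc, Mapping):
        raise ConfigError(["configuration document is not a mapping"])

    problems: list[str] = []
    for key in doc:
        if key not in _TOP_KEYS:
            problems.append(f"unknown key {key!r}")

    cfg = PipelineConfig()
    cfg.mode = str(doc.get("mode", "simulate"))
    if cfg.mode not in ("simulate", "directory"):
        problems.append(f"mode must be 'simulate' or 'directory', got {cfg.mode!r}")

    design = doc.get("design", {}) or {}
    if not isinstance(design, Mapping):
        problems.append("design must be a mapping")
        design = {}
    for key in design:
        if key not in _DESIGN_KEYS:
            problems.append(f"unknown design key {key!r}")
    groups: list[GroupSpec] = []
    for i, g in enumerate(design.get("groups", []) or []):
        try:
            spec = GroupSpec(
                strain=str(g["strain"]),
                construct=str(g["construct"]),
                preset=str(g["preset"]),
            )
        except (KeyError, TypeError):
            problems.append(
                f"group #{i + 1} needs 'strain', 'construct' and 'preset'"
            )
            continue
        if spec.preset not in PRESETS:
            problems.append(
                f"group {spec.name!r}: unknown preset {spec.preset!r} "
                f"(available: {', '.join(sorted(PRESETS))})"
            )
        groups.append(spec)
    cfg.groups = tuple(groups)
    if cfg.mode == "simulate" and not groups:
        problems.append("simulate mode needs at least one design group")

    cfg.n_experiments = int(design.get("n_experiments", cfg.n_experiments))
    cfg.n_fields_per_experiment = int(
        design.get("n_fields_per_experiment", cfg.n_fields_per_experiment)
    )
    cfg.cells_per_field = int(design.get("cells_per_field", cfg.cells_per_field))
    if cfg.n_experiments < 1:
        problems.append("n_experiments must be >= 1")
    if cfg.n_fields_per_experiment < 1:
        problems.append("n_fields_per_experiment must be >= 1")
    if cfg.cells_per_field < 0:
        problems.append("cells_per_field must be >= 0")
    shp = design.get("image_shape", list(cfg.image_shape))
    try:
        cfg.image_shape = (int(shp[0]), int(shp[1]))
        if min(cfg.image_shape) <= 0:
            problems.append("image_shape dimensions must be positive")
    except (TypeError, ValueError, IndexError):
        problems.append(f"image_shape must be [rows, cols], got {shp!r}")
    cfg.simulate_shading = bool(design.get("shading", True))

    cfg.manifest = doc.get("manifest")
    if cfg.mode == "directory":
        if not cfg.manifest:
            problems.append("directory mode needs a 'manifest' CSV path")
        elif not Path(cfg.manifest).exists():
            problems.append(f"manifest path does not exist: {cfg.manifest}")

    cfg.top_fraction = float(doc.get("top_fraction", DEFAULT_TOP_FRACTION))
    if not 0.0 < cfg.top_fraction < 1.0:
        problems.append(
            f"top_fraction must lie strictly in (0, 1), got {cfg.top_fraction}"
        )

    cfg.shading = str(doc.get("shading", "estimate"))
    if cfg.shading not in ("estimate", "identity") and not Path(cfg.shading).exists():
        problems.append(
            f"shading must be 'estimate', 'identity' or an existing profile "
            f"directory, got {cfg.shading!r}"
        )

    cfg.measure_on = str(doc.get("measure_on", "8bit"))
    if cfg.measure_on not in ("8bit", "corrected"):
        problems.append("measure_on must be '8bit' or 'corrected'")

    rng8 = doc.get("eight_bit_range")
    if rng8 is not None:
        try:
            lo, hi = float(rng8[0]), float(rng8[1])
            if hi <= lo:
                problems.append("eight_bit_range must satisfy vmax > vmin")
            cfg.eight_bit_range = (lo, hi)
        except (TypeError, ValueError, IndexError):
            problems.append(f"eight_bit_range must be [vmin, vmax], got {rng8!r}")

    known = {g.name for g in groups}
    comps: list[ComparisonSpec] = []
    for i, c in enumerate(doc.get("comparisons", []) or []):
        try:
            spec = ComparisonSpec(
                a=str(c["a"]), b=str(c["b"]),
                metric=str(c.get("metric", "max_intensity")),
                test=str(c.get("test", "nested")),
            )
        except (KeyError, TypeError):
            problems.append(f"comparison #{i + 1} needs group labels 'a' and 'b'")
            continue
        for lbl in (spec.a, spec.b):
            if cfg.mode == "simulate" and lbl not in known:
                problems.append(
                    f"comparison #{i + 1} references undefined group {lbl!r}"
                )
        if spec.metric not in ("max_intensity", "intden_per_cell"):
            problems.append(
                f"comparison #{i + 1}: unknown metric {spec.metric!r}"
            )
        if spec.test not in ("student", "welch", "nested"):
            problems.append(f"comparison #{i + 1}: unknown test {spec.test!r}")
        comps.append(spec)
    cfg.comparisons = tuple(comps)

    rrr = doc.get("rrr")
    if rrr is not None:
        try:
            cfg.rrr = RRRSpec(
                test=str(rrr["test"]), neg=str(rrr["neg"]), pos=str(rrr["pos"]),
                mut=str(rrr["mut"]), wt=str(rrr["wt"]),
            )
        except (KeyError, TypeError):
            problems.append("rrr needs 'test', 'neg', 'pos', 'mut' and 'wt'")
        else:
            if cfg.mode == "simulate":
                strains = {g.strain for g in groups}
                constructs = {g.construct for g in groups}
                for role, lbl, pool, kind in (
                    ("test", cfg.rrr.test, constructs, "construct"),
                    ("neg", cfg.rrr.neg, constructs, "construct"),
                    ("pos", cfg.rrr.pos, constructs, "construct"),
                    ("mut", cfg.rrr.mut, strains, "strain"),
                    ("wt", cfg.rrr.wt, strains, "strain"),
                ):
                    if lbl not in pool:
                        problems.append(
                            f"rrr role {role!r} references undefined "
                            f"{kind} {lbl!r}"
                        )

    cfg.base_seed = int(doc.get("base_seed", 0))
    cfg.out_dir = str(doc.get("out_dir", "results/run"))

    if problems:
        raise ConfigError(problems)
    return cfg
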