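"""End-to-end orchestration: simulate/ingest -> correct -> measure -> stats.

``run_pipeline`` executes a validated :class:`~punctaquant.config.PipelineConfig`
and returns a :class:`ResultsBundle` of tidy tables (per-punctum, per-field,
per-comparison, RRR report) plus a run manifest that echoes every resolved
setting, seed and per-image 8-bit mapping — identical config and seed
reproduce every output file byte for byte.
"""

from __future__ import annotations

import json
import logging
import os
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Callable

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig, RRRSpec
from .micrograph import Micrograph, read_tiff
from .quant import measure_field
from .shading import (
    ImageStack,
    ShadingModel,
    correct_image,
    estimate_shading,
    identity_model,
    load_shading_profile,
    save_shading_profile,
)
from .stats import (
    NestedSample,
    RRRInputs,
    TestResult,
    compute_rrr,
    mean_sem,
    nested_t,
    student_t,
)
from .synthetic import ExperimentDesign, PRESETS, generate_experiment

__all__ = ["ResultsBundle", "run_pipeline"]

log = logging.getLogger("punctaquant")

_FLOAT_FMT = "%.10g"


@dataclass
class ResultsBundle:
    """All tables produced by one pipeline run."""

    fields: pd.DataFrame
    puncta: pd.DataFrame
    comparisons: pd.DataFrame
    rrr_report: dict[str, Any] | None
    manifest: dict[str, Any]
    shading_model: ShadingModel | None = None

    def write(self, out_dir: str | Path) -> None:
        """Write every table atomically under ``out_dir``."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        _atomic_csv(self.fields, out / "fields.csv")
        _atomic_csv(self.puncta, out / "puncta.csv")
        _atomic_csv(self.comparisons, out / "comparisons.csv")
        if self.rrr_report is not None:
            _atomic_text(
                json.dumps(self.rrr_report, indent=2, sort_keys=True) + "\n",
                out / "rrr.json",
            )
        _atomic_text(
            json.dumps(self.manifest, indent=2, sort_keys=True) + "\n",
            out / "manifest.json",
        )
        if self.shading_model is not None:
            save_shading_profile(self.shading_model, out / "shading_profile")


def _atomic_text(text: str, path: Path) -> None:
    fd, tmp = tempfile.mkstemp(dir=str(path.parent), prefix=".tmp-")
    try:
        with os.fdopen(fd, "w", newline="\n") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _atomic_csv(df: pd.DataFrame, path: Path) -> None:
    _atomic_text(
        df.to_csv(index=False, float_format=_FLOAT_FMT, lineterminator="\n"),
        path,
    )


# ---------------------------------------------------------------------------


@dataclass
class _Field:
    group: str
    strain: str
    construct: str
    experiment_id: str
    field_id: str
    seed: int | None
    fluorescence: Micrograph
    cell_source: Micrograph | int


def _stage(name: str, fn: Callable[[], Any]) -> Any:
    try:
        return fn()
    except Exception as exc:  # pragma: no cover - context tagging
        raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc


def _collect_fields(config: PipelineConfig) -> list[_Field]:
    if config.mode == "simulate":
        design = ExperimentDesign(
            groups=tuple(
                (g.strain, g.construct, PRESETS[g.preset]) for g in config.groups
            ),
            n_experiments=config.n_experiments,
            n_fields_per_experiment=config.n_fields_per_experiment,
            cells_per_field=config.cells_per_field,
            base_seed=config.base_seed,
            shape=config.image_shape,
            shading=config.simulate_shading,
        )
        sim = generate_experiment(design)
        return [
            _Field(
                group=r.group, strain=r.strain, construct=r.construct,
                experiment_id=r.experiment_id, field_id=r.field_id,
                seed=r.seed, fluorescence=r.fluorescence,
                cell_source=r.phase,
            )
            for r in sim.records
        ]
    # directory mode: manifest CSV with one row per field
    man = pd.read_csv(config.manifest)
    required = {"fluor_path", "condition", "experiment_id", "field_id"}
    missing = required - set(man.columns)
    if missing:
        raise ValueError(f"manifest is missing columns: {sorted(missing)}")
    root = Path(config.manifest).parent
    out: list[_Field] = []
    for _, row in man.iterrows():
        fluor = read_tiff(root / str(row["fluor_path"]))
        src: Micrograph | int
        if "cell_count" in man.columns and not pd.isna(row.get("cell_count")):
            src = int(row["cell_count"])
        elif "phase_path" in man.columns and not pd.isna(row.get("phase_path")):
            src = read_tiff(root / str(row["phase_path"]), channel="phase")
        else:
            raise ValueError(
                f"field {row['field_id']}: need 'cell_count' or 'phase_path'"
            )
        cond = str(row["condition"])
        strain, _, construct = cond.partition(":")
        out.append(
            _Field(
                group=cond, strain=strain, construct=construct or "",
                experiment_id=str(row["experiment_id"]),
                field_id=str(row["field_id"]), seed=None,
                fluorescence=fluor, cell_source=src,
            )
        )
    return out


def _resolve_shading(
    config: PipelineConfig, fields: list[_Field]
) -> ShadingModel:
    shape = fields[0].fluorescence.shape
    if config.shading == "identity":
        return identity_model(shape)
    if config.shading == "estimate":
        stack = ImageStack(
            [f.fluorescence for f in fields],
            channel=fields[0].fluorescence.channel,
            exposure=fields[0].fluorescence.exposure,
        )
        return estimate_shading(stack)
    prof = Path(config.shading)
    return load_shading_profile(prof / "flatfield.tif", prof / "darkfield.tif")


def _comparison_samples(
    fields_df: pd.DataFrame, puncta_df: pd.DataFrame, group: str, metric: str
) -> NestedSample:
    if metric == "max_intensity":
        sub = puncta_df[puncta_df["group"] == group]
        return NestedSample(
            group=group,
            values=sub["max_intensity"].tolist(),
            experiment_of=sub["experiment_id"].tolist(),
        )
    sub = fields_df[fields_df["group"] == group]
    return NestedSample(
        group=group,
        values=sub["integrated_density_per_cell"].tolist(),
        experiment_of=sub["experiment_id"].tolist(),
    )


def _grand_mean_intden(fields_df: pd.DataFrame, group: str) -> float:
    sub = fields_df[fields_df["group"] == group]
    if sub.empty:
        raise ValueError(f"no fields measured for group {group!r}")
    return float(sub["integrated_density_per_cell"].mean())


def _rrr_report(
    spec: RRRSpec, fields_df: pd.DataFrame
) -> dict[str, Any]:
    def grp(strain: str, construct: str) -> str:
        return f"{strain}:{construct}"

    inputs = RRRInputs(
        I_test_mut=_grand_mean_intden(fields_df, grp(spec.mut, spec.test)),
        I_test_wt=_grand_mean_intden(fields_df, grp(spec.wt, spec.test)),
        I_neg_mut=_grand_mean_intden(fields_df, grp(spec.mut, spec.neg)),
        I_neg_wt=_grand_mean_intden(fields_df, grp(spec.wt, spec.neg)),
        I_pos_mut=_grand_mean_intden(fields_df, grp(spec.mut, spec.pos)),
        I_pos_wt=_grand_mean_intden(fields_df, grp(spec.wt, spec.pos)),
    )
    return {
        "roles": {"test": spec.test, "neg": spec.neg, "pos": spec.pos,
                  "mut": spec.mut, "wt": spec.wt},
        "inputs": {
            "I_test_mut": inputs.I_test_mut, "I_test_wt": inputs.I_test_wt,
            "I_neg_mut": inputs.I_neg_mut, "I_neg_wt": inputs.I_neg_wt,
            "I_pos_mut": inputs.I_pos_mut, "I_pos_wt": inputs.I_pos_wt,
        },
        "rrr": compute_rrr(inputs),
    }


def run_pipeline(
    config: PipelineConfig, write: bool = True
) -> ResultsBundle:
    """Execute the full analysis described by ``config``.

    Stages: simulate or ingest the fields, resolve the shading model and
    correct every fluorescence image, measure each field (segmentation +
    particle analysis + per-cell aggregation), then run the configured group
    comparisons and optional RRR normalization.  Outputs are written under
    ``config.out_dir`` unless ``write=False``.
    """
    fields: list[_Field] = _stage("input", lambda: _collect_fields(config))
    log.info("collected %d fields", len(fields))

    model: ShadingModel = _stage(
        "shading", lambda: _resolve_shading(config, fields)
    )

    field_rows: list[dict[str, Any]] = []
    puncta_rows: list[dict[str, Any]] = []

    def _measure() -> None:
        for f in fields:
            corrected = correct_image(f.fluorescence, model)
            if config.eight_bit_range is not None:
                vmin8, vmax8 = config.eight_bit_range
            else:
                vmin8 = float(corrected.pixels.min())
                vmax8 = float(corrected.pixels.max())
            fm, ps = measure_field(
                corrected,
                f.cell_source,
                top_fraction=config.top_fraction,
                condition=f.group,
                experiment_id=f.experiment_id,
                field_id=f.field_id,
                measure_on=config.measure_on,
                eight_bit_range=config.eight_bit_range,
            )
            key = f"{f.group}/{f.experiment_id}/{f.field_id}"
            log.info(
                "%s: %d cells, %d puncta, threshold %.4g (budget k=%d)",
                key, fm.cell_count, fm.n_puncta, fm.threshold_used,
                int(np.floor(config.top_fraction
                             * corrected.pixels.size)),
            )
            field_rows.append(
                {
                    "group": f.group, "strain": f.strain,
                    "construct": f.construct,
                    "experiment_id": f.experiment_id, "field_id": f.field_id,
                    "seed": f.seed, "cell_count": fm.cell_count,
                    "n_puncta": fm.n_puncta,
                    "integrated_density_per_cell":
                        fm.integrated_density_per_cell,
                    "threshold_used": fm.threshold_used,
                    "measured_on": fm.measured_on,
                    "eight_bit_vmin": vmin8,
                    "eight_bit_vmax": vmax8,
                }
            )
            for p in ps.puncta:
                puncta_rows.append(
                    {
                        "group": f.group, "experiment_id": f.experiment_id,
                        "field_id": f.field_id, "label": p.label,
                        "area_px": p.area_px,
                        "max_intensity": p.max_intensity,
                        "integrated_density": p.integrated_density,
                    }
                )

    _stage("measure", _measure)

    sort_f = ["group", "experiment_id", "field_id"]
    fields_df = pd.DataFrame(field_rows).sort_values(sort_f, kind="mergesort")
    fields_df = fields_df.reset_index(drop=True)
    if puncta_rows:
        puncta_df = pd.DataFrame(puncta_rows).sort_values(
            sort_f + ["label"], kind="mergesort"
        ).reset_index(drop=True)
    else:
        puncta_df = pd.DataFrame(
            columns=sort_f + ["label", "area_px", "max_intensity",
                              "integrated_density"]
        )

    comp_rows: list[dict[str, Any]] = []

    def _compare() -> None:
        for c in config.comparisons:
            sa = _comparison_samples(fields_df, puncta_df, c.a, c.metric)
            sb = _comparison_samples(fields_df, puncta_df, c.b, c.metric)
            if c.test == "nested":
                res: TestResult = nested_t(sa, sb)
            else:
                res = student_t(sa.values, sb.values, welch=(c.test == "welch"))
            mean_a, sem_a = mean_sem(sa.values)
            mean_b, sem_b = mean_sem(sb.values)
            comp_rows.append(
                {
                    "group_a": c.a, "group_b": c.b, "metric": c.metric,
                    "test": res.method, "mean_a": mean_a, "sem_a": sem_a,
                    "mean_b": mean_b, "sem_b": sem_b,
                    "statistic": res.statistic, "df": res.df, "p": res.p,
                    "stars": res.stars,
                }
            )

    _stage("stats", _compare)
    comparisons_df = pd.DataFrame(
        comp_rows,
        columns=["group_a", "group_b", "metric", "test", "mean_a", "sem_a",
                 "mean_b", "sem_b", "statistic", "df", "p", "stars"],
    )

    rrr_report = None
    if config.rrr is not None:
        rrr_report = _stage("rrr", lambda: _rrr_report(config.rrr, fields_df))

    manifest = {
        "software": {"name": "punctaquant", "version": __version__},
        "config": config.resolved(),
        "shading": {
            "provenance": model.provenance,
            "converged": model.converged,
            **model.meta,
        },
        "field_seeds": {
            f"{f.group}/{f.experiment_id}/{f.field_id}": f.seed for f in fields
        },
        "n_fields": len(fields),
        "n_puncta": int(len(puncta_df)),
    }

    bundle = ResultsBundle(
        fields=fields_df,
        puncta=puncta_df,
        comparisons=comparisons_df,
        rrr_report=rrr_report,
        manifest=manifest,
        shading_model=model,
    )
    if write:
        bundle.write(config.out_dir)
    return bundle
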