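"""End-to-end orchestration: cohort generation → (baseline segmentation and
Dice evaluation) → global morphometry → VOI-restricted local analysis →
hypothesis tests, with CSV outputs and a checksummed run manifest.

All stages are deterministic given the configured seed; rerunning a config
reproduces byte-identical CSV outputs (the manifest's timestamps differ, its
checksums do not).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

from . import __version__
from .morphometry import (
    _edt_um,
    compartment_volumes,
    local_metrics,
    local_thickness,
    total_volume_mask,
)
from .phantom import CohortSample, CohortSpec, generate_cohort, render_intensity
from .segeval import SegmenterParams, baseline_segment, dice_report
from .stats import results_frame, run_study_comparisons
from .volume import METASTASIS, VESSEL

logger = logging.getLogger("osteovasc")

__all__ = [
    "PipelineConfig",
    "RunManifest",
    "run_pipeline",
    "sample_reports",
    "cohort_table",
    "run_t2_treatment_comparison",
]

DEFAULT_VOI_THRESHOLDS = (300.0, 700.0, 1000.0)


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    ``cohorts`` holds one :class:`CohortSpec` per time point.  VOI thresholds
    default to 300/700/1000 µm; ``stats_threshold_um`` selects which of them
    feeds the local-metric group comparisons.  ``seed`` overrides every cohort
    seed (offset per cohort) so one integer reproduces the whole run.
    """

    cohorts: list[CohortSpec]
    out_dir: Path = Path("osteovasc_out")
    voi_thresholds_um: tuple[float, ...] = DEFAULT_VOI_THRESHOLDS
    stats_threshold_um: float = 700.0
    tv_closing_um: float | None = None
    evaluate_baseline: bool = False
    segmenter: SegmenterParams | None = None
    seed: int | None = None
    n_montecarlo: int = 2000

    def validate(self) -> None:
        if not self.cohorts:
            raise ValueError("pipeline needs at least one cohort")
        th = list(self.voi_thresholds_um)
        if any(t <= 0 for t in th) or sorted(th) != th or len(set(th)) != len(th):
            raise ValueError("VOI thresholds must be positive and strictly increasing")
        if self.stats_threshold_um not in th:
            raise ValueError("stats_threshold_um must be one of the VOI thresholds")


@dataclass
class RunManifest:
    version: str
    config: dict
    seeds: dict
    outputs: dict[str, str] = field(default_factory=dict)  # filename -> sha256
    started: float = 0.0
    finished: float = 0.0

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(self.__dict__, indent=1, default=str))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def sample_reports(
    sample: CohortSample,
    voi_thresholds_um=DEFAULT_VOI_THRESHOLDS,
    tv_closing_um: float | None = None,
) -> list[dict]:
    """Global + per-VOI morphometry for one sample, as flat dict rows."""
    labels = sample.labels
    tv = total_volume_mask(labels, tv_closing_um)
    vessel = labels.mask(VESSEL)
    met = labels.mask(METASTASIS)
    undefined: dict[str, str] = {}
    thickness = None
    # fast internal EDT: VMI is a mean and the VOI a thresholded set, so
    # float32 distances are ample here (the public ops stay exact)
    met_dist = _edt_um(met, labels.voxel_size_um) if met.any() else None
    if vessel.any():
        thickness, vth = local_thickness(vessel, labels.voxel_size_um)
        if met_dist is not None:
            vmi_um = float(met_dist[vessel].mean())
        else:
            vmi_um = None
            undefined["vmi"] = "no metastases present"
    else:
        vth, vmi_um = None, None
        undefined["vth"] = undefined["vmi"] = "no vessels present"
    rows = [
        dict(
            sample_id=sample.sample_id,
            time_point=sample.time_point,
            group=sample.group,
            **compartment_volumes(labels, tv, vth_um=vth, vmi_um=vmi_um, undefined=undefined).as_dict(),
        )
    ]
    if met_dist is not None:
        for t in voi_thresholds_um:
            voi = (met_dist < t) & tv
            rep = local_metrics(labels, voi, thickness=thickness, scope=f"voi<{t:g}um")
            rows.append(
                dict(
                    sample_id=sample.sample_id,
                    time_point=sample.time_point,
                    group=sample.group,
                    **rep.as_dict(),
                )
            )
    return rows


def cohort_table(report_rows: list[dict], stats_threshold_um: float = 700.0) -> pd.DataFrame:
    """Long-form (sample, metric, value) table feeding the hypothesis tests."""
    local_scope = f"voi<{stats_threshold_um:g}um"
    records = []
    for row in report_rows:
        base = {k: row[k] for k in ("sample_id", "time_point", "group")}
        if row["scope"] == "global":
            for metric, key in [
                ("BV/TV", "BV/TV"),
                ("VV/TV", "VV/TV"),
                ("MeV/TV", "MeV/TV"),
                ("V.Th", "V.Th_um"),
                ("VMI", "VMI_um"),
            ]:
                records.append({**base, "metric": metric, "value": row[key]})
        elif row["scope"] == local_scope:
            records.append({**base, "metric": "local VV/TV", "value": row["VV/TV"]})
            records.append({**base, "metric": "local V.Th", "value": row["V.Th_um"]})
    return pd.DataFrame(records, columns=["sample_id", "time_point", "group", "metric", "value"])


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Run the full analysis and write CSV reports plus a manifest.

    Outputs in ``config.out_dir``: ``morphometry.csv`` (one row per sample and
    scope), ``cohort_table.csv`` (long form), ``stats.csv`` (test results with
    assumption checks), optionally ``dice.csv``, and ``manifest.json``.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(version=__version__, config=_config_echo(config), seeds={}, started=time.time())

    all_rows: list[dict] = []
    dice_rows: list[dict] = []
    for ci, cohort in enumerate(config.cohorts):
        if config.seed is not None:
            cohort = replace(cohort, seed=config.seed + 1000 * ci)
        manifest.seeds[f"cohort_{cohort.time_point}"] = cohort.seed
        samples = generate_cohort(cohort)
        for sample in samples:
            try:
                all_rows.extend(
                    sample_reports(sample, config.voi_thresholds_um, config.tv_closing_um)
                )
                if config.evaluate_baseline:
                    img = render_intensity(sample.labels, sample.spec or cohort.base)
                    seg = baseline_segment(img, config.segmenter)
                    rep = dice_report(seg, sample.labels).as_frame()
                    rep.insert(0, "sample_id", sample.sample_id)
                    dice_rows.extend(rep.to_dict("records"))
            except Exception as exc:
                raise RuntimeError(
                    f"pipeline stage failed for sample {sample.sample_id!r}: {exc}"
                ) from exc
            logger.info("processed %s", sample.sample_id)

    morpho = pd.DataFrame(all_rows)
    table = cohort_table(all_rows, config.stats_threshold_um)
    try:
        results = run_study_comparisons(
            table.dropna(subset=["value"]),
            n_montecarlo=config.n_montecarlo,
            seed=(config.seed or 0) + 99,
        )
        stats_df = results_frame(results)
    except ValueError as exc:
        logger.warning("statistics stage skipped: %s", exc)
        stats_df = pd.DataFrame()
    files = {
        "morphometry.csv": morpho,
        "cohort_table.csv": table,
        "stats.csv": stats_df,
    }
    if dice_rows:
        files["dice.csv"] = pd.DataFrame(dice_rows)
    for name, frame in files.items():
        frame.to_csv(out / name, index=False)
        manifest.outputs[name] = _sha256(out / name)
    manifest.finished = time.time()
    manifest.write(out / "manifest.json")
    return manifest


def run_t2_treatment_comparison(
    cohort_seed: int,
    c_radius_factor: float = 0.6,
    n_per_group: int = 7,
    threshold_um: float = 700.0,
    base: "PhantomSpec | None" = None,
    n_montecarlo: int = 1000,
):
    """One end-to-end replication of the T2 treatment-arm study.

    Generates a four-group cohort (placebo P, single agents B and V, and the
    combined anti-angiogenic treatment C whose vessel radii shrink by
    ``c_radius_factor`` within ``threshold_um`` of the lesions), measures the
    VOI-restricted vessel metrics per sample, and runs the group comparisons.
    Returns ``(results, table)``.
    """
    from .phantom import GroupEffect, PhantomSpec

    groups = [
        GroupEffect("P", n_per_group),
        GroupEffect("B", n_per_group),
        GroupEffect("V", n_per_group),
        GroupEffect(
            "C", n_per_group, vessel_radius_factor=c_radius_factor, effect_distance_um=threshold_um
        ),
    ]
    cohort = CohortSpec(groups=groups, base=base or PhantomSpec(), time_point="T2", seed=cohort_seed)
    rows: list[dict] = []
    for sample in generate_cohort(cohort):
        rows.extend(sample_reports(sample, voi_thresholds_um=(threshold_um,)))
    table = cohort_table(rows, stats_threshold_um=threshold_um)
    results = run_study_comparisons(
        table.dropna(subset=["value"]), n_montecarlo=n_montecarlo, seed=cohort_seed + 7
    )
    return results, table


def _config_echo(config: PipelineConfig) -> dict:
    def enc(obj):
        if hasattr(obj, "__dict__"):
            return {k: enc(v) for k, v in vars(obj).items()}
        if isinstance(obj, (list, tuple)):
            return [enc(v) for v in obj]
        if isinstance(obj, Path):
            return str(obj)
        return obj

    return enc(config)
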