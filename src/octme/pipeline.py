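"""End-to-end reproducible runs: simulate -> segment -> thickness ->
classify -> trend -> cohort.

A single integer seed governs every stochastic stage; per-ear scenario
seeds are derived from it with :class:`numpy.random.SeedSequence`, so a
rerun with the same resolved config produces byte-identical tabular
outputs.
"""

from __future__ import annotations

import dataclasses
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import me_classify, scan_io, tm_segment, thickness_quant, trend_stats
from .cohort_summary import summarize_cohort
from .me_classify import ClassifierParams, EarObservation
from .phantom import OpticsConfig, ScenarioConfig, render_series
from .scan_io import write_bscan, write_observations
from .thickness_quant import CorrectionParams, ScanUnusable
from .tm_segment import NoMembraneDetected, SegmentationParams

log = logging.getLogger("octme.pipeline")

#: Default demo cohort: three animals per group, two groups, eight days.
DEFAULT_ARMS = (
    {"scenario": "control", "n_animals": 3, "n_ears": 2},
    {"scenario": "om_progression", "n_animals": 3, "n_ears": 2},
)


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run."""

    seed: int = 0
    out_dir: str = "octme_run"
    arms: tuple = DEFAULT_ARMS
    # daily for the first five days post-inoculation, then every other day
    days: tuple = (0, 1, 2, 3, 4, 5, 7, 9, 11, 13)
    scans_per_day: int = 2
    optics: dict = field(default_factory=lambda: {"image_rows": 600, "image_cols": 300})
    scenario_overrides: dict = field(default_factory=dict)
    segmentation: dict = field(default_factory=dict)
    correction: dict = field(default_factory=lambda: {"n_points": 80})
    classifier: dict = field(default_factory=dict)
    trend_degree: str | int = "auto"
    save_images: bool = False
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(_to_plain(dataclasses.asdict(self)), fh, sort_keys=True)


def _to_plain(obj):
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def derive_seed(master_seed: int, index: int) -> int:
    """Stable per-ear seed below 2**31 derived from the master seed."""
    return int(np.random.SeedSequence([master_seed, index]).generate_state(1)[0] % (2**31))


def process_scan(scan, seg_params, corr_params, clf_params):
    """Segment, quantify and classify one scan.

    Returns ``(classification, profile)`` or ``(None, None)`` when the
    scan is unusable (no membrane, bad quality, or no qualifying run of
    valid thickness points).
    """
    try:
        boundaries = tm_segment.segment_tm(scan, seg_params)
    except NoMembraneDetected:
        return None, None
    quality = tm_segment.mask_quality(boundaries)
    if not quality.usable:
        return None, None
    try:
        profile = thickness_quant.compute_profile(boundaries, corr_params)
        thickness_quant.summarize_scan(profile, corr_params)
    except ScanUnusable:
        return None, None
    classification = me_classify.classify_scan(scan, boundaries, profile, clf_params)
    return classification, profile


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full pipeline and write all artifacts to the run directory.

    Outputs: ``observations.csv``, ``fits.csv``, ``group_summary.csv``,
    ``cohort.csv``, ``cohort.txt``, ``config_resolved.yaml``, ``run.log``
    and (optionally) per-scan TIFF images with sidecars under ``images/``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(config.log_level)
    try:
        return _run(config, out)
    finally:
        log.removeHandler(handler)
        handler.close()


def _run(config: RunConfig, out: Path) -> Path:
    optics = OpticsConfig(**config.optics)
    seg_params = SegmentationParams(**config.segmentation)
    corr_params = CorrectionParams(**config.correction)
    clf_params = ClassifierParams(**config.classifier)
    config.to_yaml(out / "config_resolved.yaml")
    if config.save_images:
        (out / "images").mkdir(exist_ok=True)

    observations: list[EarObservation] = []
    end_rows = []
    ear_index = 0
    for arm in config.arms:
        scenario_name = arm["scenario"]
        for a in range(int(arm["n_animals"])):
            animal = f"{scenario_name[:4]}_{a + 1:02d}"
            for e in range(int(arm.get("n_ears", 2))):
                ear = "LR"[e % 2]
                scen = ScenarioConfig(
                    scenario=scenario_name,
                    days=tuple(config.days),
                    scans_per_day=config.scans_per_day,
                    seed=derive_seed(config.seed, ear_index),
                    animal=animal,
                    ear=ear,
                    **config.scenario_overrides,
                )
                ear_index += 1
                log.info("simulate: %s ear %s scenario %s", animal, ear, scenario_name)
                series = render_series(optics, scen)
                by_day: dict[int, list] = {}
                for day, scan, truth in series:
                    if config.save_images:
                        stem = f"{animal}_{ear}_d{day:02d}_{len(by_day.get(day, []))}"
                        write_bscan(scan, out / "images" / f"{stem}.tif", out / "images" / f"{stem}.yaml")
                    result = process_scan(scan, seg_params, corr_params, clf_params)
                    if result[0] is None:
                        log.warning("scan excluded: %s ear %s day %s", animal, ear, day)
                    by_day.setdefault(day, []).append(result)
                ear_obs = [
                    me_classify.aggregate_ear_day(results, animal, ear, day, scen.group)
                    for day, results in sorted(by_day.items())
                ]
                observations.extend(ear_obs)
                end_rows.append(
                    {
                        "animal": animal,
                        "ear": ear,
                        "group": scen.group,
                        "end_state": me_classify.ear_end_state(ear_obs),
                    }
                )

    write_observations(observations, out / "observations.csv")
    obs_frame = scan_io.observations_to_frame(observations)

    fit_rows = []
    usable = obs_frame[~obs_frame["blocked"]]
    for (animal, group), sub in usable.groupby(["animal", "group"]):
        per_day = sub.groupby("day")["thickness_mean_um"].mean()
        days, vals = per_day.index.to_numpy(float), per_day.to_numpy(float)
        if days.size < 3:
            log.warning("trend skipped for %s: only %d days", animal, days.size)
            continue
        if config.trend_degree == "auto":
            degree = trend_stats.select_degree(days, vals) if days.size >= 5 else 1
        else:
            degree = int(config.trend_degree)
        try:
            fit = trend_stats.fit_polynomial_trend(days, vals, degree)
        except ValueError as err:
            log.warning("trend failed for %s: %s", animal, err)
            continue
        row = {
            "animal": animal,
            "group": group,
            "degree": fit.degree,
            "r_squared": fit.r_squared,
            "n_days": fit.n,
            "trend_call": fit.trend_call,
        }
        for k in range(fit.degree + 1):
            row[f"beta{k}"] = fit.coefficients[k]
            row[f"p{k}"] = fit.p_values[k]
        fit_rows.append(row)
    pd.DataFrame(fit_rows).to_csv(out / "fits.csv", index=False)

    summaries = []
    for group in sorted(usable["group"].unique()):
        try:
            gs = trend_stats.group_summary(obs_frame, group)
        except ValueError as err:
            log.warning("group summary failed for %s: %s", group, err)
            continue
        gs.insert(0, "group", group)
        summaries.append(gs)
    if summaries:
        pd.concat(summaries, ignore_index=True).to_csv(out / "group_summary.csv", index=False)

    table = summarize_cohort(pd.DataFrame(end_rows))
    table.to_frame().to_csv(out / "cohort.csv", index=False)
    (out / "cohort.txt").write_text(table.to_text() + "\n", encoding="utf-8")
    log.info("run complete: %s", out)
    return out
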