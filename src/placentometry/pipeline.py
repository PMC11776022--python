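"""End-to-end orchestration: simulate -> segment -> quantify -> accel -> stats.

A run is fully determined by ``(config, seed)``: the config carries every
stage's parameters (serialisable to YAML losslessly) and the seed feeds a
SeedSequence from which each stage draws its own stream.  The report lists
per-stage output files with content hashes and every exclusion with its
reason, mirroring how a cohort flows through the analysis (slide QC
failures, accelerometer validity failures).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import accelerometry, io, stats, stereology
from .errors import NoVillousTissueError, ValidationError
from .imaging import (classify_villous_tissue, extract_stain_channel,
                      qc_slide, segment_vessels)
from .synthetic_data import (ActivityProfile, CohortGenSpec, SlideParams,
                             generate_accel_series, generate_cohort,
                             generate_slide)

log = logging.getLogger("placentometry.pipeline")

__all__ = ["RunConfig", "RunReport", "run_pipeline", "default_config"]


@dataclass
class RunConfig:
    """All pipeline knobs in one serialisable object."""

    seed: int = 0
    n_subjects: int = 92
    n_slides_per_subject: int = 2
    slide: dict = field(default_factory=lambda: dict(
        width_px=512, height_px=512, pixel_size_um=2.0,
        fibrin_fraction=0.03, artifact_fraction=0.01,
        vessel_density_per_mm2=1324.0))
    activity: dict = field(default_factory=lambda: dict(
        wear_minutes_per_day=900.0, n_days=4, swim_minutes_per_day=1.5))
    cohort: dict = field(default_factory=dict)
    stereology: dict = field(default_factory=lambda: dict(
        k_regions=2, region_diameter_um=500.0, min_villous_fraction=0.30))
    imaging: dict = field(default_factory=dict)
    #: per-subject overrides of slide parameters, e.g. forcing a QC failure:
    #: {"S001": {"artifact_fraction": 0.3}}
    slide_overrides: dict = field(default_factory=dict)
    statistics: dict = field(default_factory=lambda: dict(
        outcomes=["density_villi_whole_measured", "density_villi_regions",
                  "vessel_area_pct", "vessel_count_per_mm2"]))

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "RunConfig":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        data = yaml.safe_load(text) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def default_config() -> RunConfig:
    return RunConfig()


@dataclass
class RunReport:
    seed: int
    n_subjects_in: int
    n_subjects_analyzed: int
    exclusions: list = field(default_factory=list)
    manifests: dict = field(default_factory=dict)
    tables: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2, default=str)
        if path is not None:
            Path(path).write_text(text)
        return text


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _segment_and_measure(image, cfg: RunConfig, region_seed: int):
    """Segmentation + stereology for one slide; returns a metrics dict."""
    labels = classify_villous_tissue(image)
    stain = extract_stain_channel(image)
    qc = qc_slide(labels, stain)
    vessels = segment_vessels(stain, labels, **cfg.imaging)
    whole = stereology.compute_metrics(labels, vessels)
    st_cfg = cfg.stereology
    try:
        regions = stereology.place_regions(
            labels, k=st_cfg.get("k_regions", 2),
            diameter_um=st_cfg.get("region_diameter_um", 500.0),
            seed=region_seed,
            min_villous_fraction=st_cfg.get("min_villous_fraction", 0.30))
        reg_metrics = [stereology.compute_metrics(labels, vessels, r)
                       for r in regions]
        reg_density = float(np.mean([m.density_villi_pct for m in reg_metrics]))
    except (NoVillousTissueError, ValidationError):
        reg_density = np.nan
    return dict(
        qc_pass=qc.passed, qc_reason=qc.reason,
        density_villi_whole_measured=whole.density_villi_pct,
        density_villi_regions=reg_density,
        vessel_area_pct=whole.vessel_area_pct,
        vessel_count_per_mm2=whole.vessel_count_per_mm2,
    )


def run_pipeline(config: RunConfig, outdir, seed: int | None = None) -> RunReport:
    """Execute all stages and write tables + report under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = config.seed if seed is None else seed
    ss = np.random.SeedSequence(seed)
    s_cohort, s_accel, s_slides, s_regions = (
        int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(4))

    # --- cohort (generative truth: exposures, covariates, outcome) ---------
    log.info("stage cohort: simulating %d subjects", config.n_subjects)
    spec = CohortGenSpec(n=config.n_subjects, seed=s_cohort, **config.cohort)
    cohort = generate_cohort(spec)
    cohort_path = outdir / "cohort.csv"
    cohort.to_csv(cohort_path, index=False)

    # --- accelerometry -----------------------------------------------------
    log.info("stage accel: simulating and summarising wear data")
    act = config.activity
    wear = float(act.get("wear_minutes_per_day", 900.0))
    swim = float(act.get("swim_minutes_per_day", 1.5))
    frames, swims = [], []
    for i, row in cohort.iterrows():
        mv = max(float(row.mvpa) - swim, 0.0) / wear
        sed = float(np.clip(row.st_pct / 100.0, 0.0, 0.98 - mv))
        profile = ActivityProfile(
            mean_sed_fraction=sed, mean_light_fraction=1.0 - sed - mv,
            mean_mvpa_fraction=mv, wear_minutes_per_day=wear,
            n_days=int(act.get("n_days", 4)), swim_minutes_per_day=swim)
        ep, sw = generate_accel_series(profile, seed=s_accel + i,
                                       subject_ids=[row.subject_id])
        frames.append(ep)
        swims.append(sw)
    epochs = pd.concat(frames, ignore_index=True)
    swim_diary = pd.concat(swims, ignore_index=True)
    epochs.to_csv(outdir / "epochs.csv", index=False)
    swim_diary.to_csv(outdir / "swim_diary.csv", index=False)
    exposures, accel_excl = accelerometry.process_cohort(epochs, swim_diary)
    exposures = exposures.rename(columns={
        "mean_mvpa_min_per_day": "mvpa_measured", "mean_st_pct": "st_pct_measured"})
    exposures.to_csv(outdir / "exposures.csv", index=False)

    exclusions = [dict(subject_id=e.subject_id, stage="accelerometry",
                       reason=e.reason) for e in accel_excl]

    # --- slides ------------------------------------------------------------
    log.info("stage imaging: %d slides per subject", config.n_slides_per_subject)
    slide_rows = []
    for i, row in cohort.iterrows():
        vf = float(np.clip(row[spec.outcome_name] / 100.0, 0.05, 0.90))
        per_subject = []
        for j in range(config.n_slides_per_subject):
            slide_kw = dict(config.slide)
            slide_kw.update(config.slide_overrides.get(row.subject_id, {}))
            params = SlideParams(villous_fraction=vf,
                                 seed=s_slides + 1000 * i + j, **slide_kw)
            image, _ = generate_slide(params)
            m = _segment_and_measure(image, config, region_seed=s_regions + i)
            m.update(subject_id=row.subject_id, slide_id=f"{row.subject_id}-{j}")
            slide_rows.append(m)
            if m["qc_pass"]:
                per_subject.append(m)
        if not per_subject:
            exclusions.append(dict(subject_id=row.subject_id, stage="slide_qc",
                                   reason=slide_rows[-1]["qc_reason"]))
    slide_df = pd.DataFrame(slide_rows)
    slide_df.to_csv(outdir / "slide_metrics.csv", index=False)

    metric_cols = ["density_villi_whole_measured", "density_villi_regions",
                   "vessel_area_pct", "vessel_count_per_mm2"]
    per_woman = (slide_df[slide_df.qc_pass]
                 .groupby("subject_id")[metric_cols].mean().reset_index())

    # --- analysis table ----------------------------------------------------
    excluded_ids = {e["subject_id"] for e in exclusions}
    analysis = (cohort.merge(exposures, on="subject_id")
                .merge(per_woman, on="subject_id"))
    analysis = analysis[~analysis.subject_id.isin(excluded_ids)]
    analysis = analysis.rename(columns={"mvpa": "mvpa_generative",
                                        "st_pct": "st_pct_generative",
                                        "mvpa_measured": "mvpa",
                                        "st_pct_measured": "st_pct"})
    analysis.to_csv(outdir / "analysis_table.csv", index=False)

    # --- statistics --------------------------------------------------------
    log.info("stage statistics: %d subjects analysed", len(analysis))
    tables = {}
    outcomes = config.statistics.get("outcomes", metric_cols)
    if len(analysis) < 8:
        log.warning("too few subjects (%d) after exclusions; statistics skipped",
                    len(analysis))
        manifests = {p.name: _sha256(p) for p in sorted(outdir.glob("*.csv"))}
        report = RunReport(seed=seed, n_subjects_in=config.n_subjects,
                           n_subjects_analyzed=len(analysis),
                           exclusions=exclusions, manifests=manifests, tables={})
        report.to_json(outdir / "run_report.json")
        return report
    adj_rows = []
    for outcome in outcomes:
        fit = stats.fit_adjusted_model(analysis, outcome)
        for _, r in fit.params.iterrows():
            adj_rows.append(dict(outcome=outcome, **r))
    adj = pd.DataFrame(adj_rows)
    adj.to_csv(outdir / "adjusted_models.csv", index=False)
    tables["adjusted_models"] = "adjusted_models.csv"

    tert_rows = []
    for expo in ("mvpa", "st_pct"):
        labels_t, cuts = stats.assign_tertiles(analysis[expo].to_numpy())
        for outcome in outcomes:
            tr = stats.compare_tertiles(analysis[outcome].to_numpy(), labels_t,
                                        cut_points=cuts)
            tert_rows.append(dict(exposure=expo, outcome=outcome,
                                  cut_low=tr.cut_points[0], cut_high=tr.cut_points[1],
                                  test=tr.test_used, statistic=tr.statistic,
                                  p=tr.p_value))
    pd.DataFrame(tert_rows).to_csv(outdir / "tertiles.csv", index=False)
    tables["tertiles"] = "tertiles.csv"

    mixed_rows = []
    for outcome in outcomes:
        mf = stats.fit_mixed_model(analysis, outcome)
        mixed_rows.append(dict(outcome=outcome, cluster_variance=mf.cluster_variance,
                               cluster_variance_se=mf.cluster_variance_se,
                               lrt_statistic=mf.lrt_statistic, lrt_df=mf.lrt_df,
                               lrt_p=mf.lrt_p))
    pd.DataFrame(mixed_rows).to_csv(outdir / "mixed_models.csv", index=False)
    tables["mixed_models"] = "mixed_models.csv"

    sens = stats.sensitivity_table(
        stats.sensitivity_analysis(analysis, outcomes[0]))
    sens.to_csv(outdir / "sensitivity.csv", index=False)
    tables["sensitivity"] = "sensitivity.csv"

    manifests = {p.name: _sha256(p) for p in sorted(outdir.glob("*.csv"))}
    report = RunReport(seed=seed, n_subjects_in=config.n_subjects,
                       n_subjects_analyzed=len(analysis),
                       exclusions=exclusions, manifests=manifests, tables=tables)
    report.to_json(outdir / "run_report.json")
    return report
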