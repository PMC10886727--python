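"""End-to-end orchestration: simulate -> preprocess -> connectivity ->
surrogate pruning -> ROI summaries -> behaviour -> statistics.

The in-memory entry point is :func:`analyse_study`, which takes a
:class:`~thetaconn.simulate.SyntheticStudy` and returns tidy result tables;
:func:`run_pipeline` wraps it with file artefacts and a content-hash
manifest so a run is fully reproducible from its config.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from . import __version__
from .behaviour import skill_metrics
from .connectivity import ConnectivityTensor, windowed_connectivity
from .io import dump_yaml, sha256_file, write_epochs
from .network import CONTRASTS, summarise_cells
from .preprocess import CONDITIONS, SESSIONS, EpochedRecording, bandpass_theta, normalise_trials
from .simulate import BehaviouralEffects, SimulationConfig, SyntheticStudy, generate_study
from .stats import bootstrap_correlation, posthoc, rm_anova
from .surrogates import SignificanceMask, build_null, significance_prune

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "StudyResults", "analyse_study", "run_pipeline",
           "preprocess_study", "prune_study"]


class PipelineConfig(BaseModel):
    """Validated configuration covering every pipeline stage."""

    # simulation
    n_subjects: int = Field(16, ge=1)
    n_trials_per_cell: int = Field(60, ge=1)
    fs: float = Field(100.0, gt=0)
    snr: float = Field(2.0, gt=0)
    noise_exponent: float = 1.0
    seed: int = Field(0, ge=0)
    behaviour_link_sd: float = Field(0.0, ge=0)
    # preprocessing
    band: tuple[float, float] = (3.0, 8.0)
    # connectivity
    metrics: list[Literal["plv", "wpli"]] = ["plv"]
    # surrogate testing
    n_surrogates: int = Field(100, ge=1)
    surrogate_method: Literal["phase", "time"] = "phase"
    alpha: float = Field(0.05, gt=0, lt=1)
    # stability filter
    within_thr: float = Field(0.60, ge=0, le=1)
    across_thr: float = Field(0.50, ge=0, le=1)
    # statistics
    n_boot: int = Field(50_000, ge=100)
    anova_window: str = "w3"
    correlation_window: str = "w2"

    @model_validator(mode="after")
    def _check_band(self) -> "PipelineConfig":
        lo, hi = self.band
        if not 0 < lo < hi < self.fs / 2:
            raise ValueError("band must satisfy 0 < lo < hi < fs/2")
        return self

    def simulation_config(self) -> SimulationConfig:
        return SimulationConfig(
            n_subjects=self.n_subjects,
            n_trials_per_cell=self.n_trials_per_cell,
            fs=self.fs,
            snr=self.snr,
            noise_exponent=self.noise_exponent,
            carrier_band=self.band,
            seed=self.seed,
        )


@dataclass
class StudyResults:
    """Tidy outputs of one full analysis run."""

    roi: pd.DataFrame
    roi_pooled: pd.DataFrame
    skill: pd.DataFrame
    anova: pd.DataFrame
    session_posthoc: pd.DataFrame
    hand_posthoc: pd.DataFrame
    correlation: dict[str, Any] = field(default_factory=dict)
    counts: dict[str, Any] = field(default_factory=dict)


def preprocess_study(
    study: SyntheticStudy, band: tuple[float, float] = (3.0, 8.0)
) -> dict[tuple[int, str, str], EpochedRecording]:
    """Theta-filter every cell, then normalise the two conditions of each
    (subject, session) pair by their pooled per-channel RMS."""
    filtered = {k: bandpass_theta(rec, band) for k, rec in study.recordings.items()}
    out: dict[tuple[int, str, str], EpochedRecording] = {}
    subjects = sorted({k[0] for k in filtered})
    sessions = sorted({k[1] for k in filtered})
    for subj in subjects:
        for session in sessions:
            kl, kr = (subj, session, "L"), (subj, session, "R")
            if kl in filtered and kr in filtered:
                out[kl], out[kr] = normalise_trials(filtered[kl], filtered[kr])
            else:  # single-condition cell: nothing to pool
                for k in (kl, kr):
                    if k in filtered:
                        out[k] = filtered[k]
    return out


def prune_study(
    recs: dict[tuple[int, str, str], EpochedRecording],
    metric: str,
    n_surrogates: int = 100,
    method: str = "phase",
    alpha: float = 0.05,
    seed: int = 0,
) -> dict[tuple[int, str, str], tuple[ConnectivityTensor, SignificanceMask]]:
    """Connectivity + surrogate pruning for every cell of one metric.

    Each cell's surrogate RNG is derived from ``SeedSequence(seed,
    spawn_key=(97, subject, session_idx, condition_idx))`` so cells are
    independent and reproducible in isolation.
    """
    out = {}
    for (subj, session, condition), rec in sorted(recs.items()):
        tensor = windowed_connectivity(rec, metric=metric)
        rng = np.random.default_rng(
            np.random.SeedSequence(
                seed, spawn_key=(97, subj, SESSIONS.index(session), CONDITIONS.index(condition))
            )
        )
        null = build_null(rec, metric=metric, n=n_surrogates, method=method, rng=rng)
        out[(subj, session, condition)] = significance_prune(tensor, null, alpha=alpha)
    return out


def _session_anova(roi: pd.DataFrame, metric: str, window: str) -> pd.DataFrame:
    """Session RM-ANOVA per contrast (conditions averaged within subject)."""
    rows = []
    sub = roi[(roi["metric"] == metric) & (roi["window"] == window)]
    for contrast, grp in sub.groupby("contrast"):
        cell = (
            grp.groupby(["subject", "session"], observed=True)["value"].mean().reset_index()
        )
        try:
            res = rm_anova(cell, dv="value", within="session", subject="subject")
        except ValueError as err:
            logger.warning("ANOVA skipped for %s: %s", contrast, err)
            continue
        row = res.effect("session").to_dict()
        row.update(contrast=contrast, metric=metric, window=window,
                   n_subjects=res.n_subjects, n_dropped=len(res.dropped_subjects))
        rows.append(row)
    return pd.DataFrame(rows)


def _session_posthoc(roi: pd.DataFrame, metric: str, window: str) -> pd.DataFrame:
    rows = []
    sub = roi[(roi["metric"] == metric) & (roi["window"] == window)]
    pairs = [("Sleep", "Pre"), ("Sleep", "Post"), ("Pre", "Post")]
    for contrast, grp in sub.groupby("contrast"):
        cell = grp.groupby(["subject", "session"], observed=True)["value"].mean().reset_index()
        try:
            ph = posthoc(cell, pairs, dv="value", factor="session", subject="subject")
        except ValueError as err:
            logger.warning("post-hoc skipped for %s: %s", contrast, err)
            continue
        ph["contrast"] = contrast
        ph["metric"] = metric
        ph["window"] = window
        rows.append(ph)
    return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()


def _hand_posthoc(roi: pd.DataFrame, metric: str) -> pd.DataFrame:
    """L vs R cued hand on within-hemisphere summaries, per session and window."""
    rows = []
    sub = roi[(roi["metric"] == metric) & roi["contrast"].isin(["within-LHem", "within-RHem"])]
    for (contrast, session, window), grp in sub.groupby(["contrast", "session", "window"]):
        try:
            ph = posthoc(grp, [("L", "R")], dv="value", factor="condition", subject="subject")
        except ValueError as err:
            logger.warning("hand post-hoc skipped for %s %s %s: %s", contrast, session, window, err)
            continue
        ph["contrast"] = contrast
        ph["session"] = session
        ph["window"] = window
        ph["metric"] = metric
        rows.append(ph)
    if not rows:
        return pd.DataFrame()
    out = pd.concat(rows, ignore_index=True)
    return out


def analyse_study(
    study: SyntheticStudy,
    config: PipelineConfig | None = None,
) -> StudyResults:
    """Run the full analysis chain on an in-memory study."""
    config = config or PipelineConfig(seed=study.seed_used)
    recs = preprocess_study(study, band=config.band)

    roi_frames, pooled_frames = [], []
    cells_by_metric = {}
    for metric in config.metrics:
        cells = prune_study(
            recs, metric,
            n_surrogates=config.n_surrogates,
            method=config.surrogate_method,
            alpha=config.alpha,
            seed=config.seed,
        )
        cells_by_metric[metric] = cells
        roi_frames.append(
            summarise_cells(cells, within_thr=config.within_thr, across_thr=config.across_thr)
        )
        # condition-pooled link retention: the summary used for L-vs-R
        # contrasts, so the two conditions share one link selection
        pooled_frames.append(
            summarise_cells(cells, within_thr=config.within_thr,
                            across_thr=config.across_thr, pool_conditions=True)
        )
    roi = pd.concat(roi_frames, ignore_index=True)
    roi_pooled = pd.concat(pooled_frames, ignore_index=True)
    skill = skill_metrics(study.behavioural)

    metric0 = config.metrics[0]
    anova = _session_anova(roi, metric0, config.anova_window)
    session_ph = _session_posthoc(roi, metric0, config.anova_window)
    hand_ph = _hand_posthoc(roi_pooled, metric0)

    # connectivity-behaviour link: within-RHem Sleep connectivity (L cues, w2)
    # against overnight improvement of the reactivated sequence on the left hand
    correlation: dict[str, Any] = {}
    x = (
        roi_pooled[
            (roi_pooled["metric"] == metric0)
            & (roi_pooled["contrast"] == "within-RHem")
            & (roi_pooled["session"] == "Sleep")
            & (roi_pooled["condition"] == "L")
            & (roi_pooled["window"] == config.correlation_window)
        ]
        .set_index("subject")["value"]
    )
    y = (
        skill[(skill["hand"] == "L") & (skill["sequence"] == "Re")]
        .set_index("subject")["ssi_early"]
    )
    common = x.dropna().index.intersection(y.dropna().index)
    if len(common) >= 5:
        res = bootstrap_correlation(
            x.loc[common].to_numpy(), y.loc[common].to_numpy(),
            n_boot=config.n_boot,
            rng=np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(11,))),
        )
        correlation = {
            "x": "within-RHem Sleep L " + config.correlation_window,
            "y": "Re ssi_early (L hand)",
            "rho": res.rho, "p": res.p, "ci": res.ci, "n": res.n, "n_boot": res.n_boot,
        }

    keep_counts = {
        metric: float(np.mean([m.keep.mean() for _, m in cells.values()]))
        for metric, cells in cells_by_metric.items()
    }
    return StudyResults(
        roi=roi,
        roi_pooled=roi_pooled,
        skill=skill,
        anova=anova,
        session_posthoc=session_ph,
        hand_posthoc=hand_ph,
        correlation=correlation,
        counts={"mean_keep_rate": keep_counts,
                "n_cells": len(study.recordings),
                "n_subjects": study.config.n_subjects},
    )


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict[str, Any]:
    """File-based run: simulate, analyse, and write all artefacts + manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "version": __version__,
        "config": json.loads(config.model_dump_json()),
        "stages": [],
    }

    def record(stage: str, paths: list[Path], **extra: Any) -> None:
        manifest["stages"].append(
            {
                "stage": stage,
                "outputs": [{"path": str(p.relative_to(out)), "sha256": sha256_file(p)} for p in paths],
                **extra,
            }
        )

    sim = config.simulation_config()
    study = generate_study(
        sim, effects=BehaviouralEffects(), behaviour_link_sd=config.behaviour_link_sd
    )
    epochs_path = write_epochs(out / "epochs.h5", study.recordings, {"seed": sim.seed})
    behav_path = out / "behaviour.csv"
    study.behavioural.to_csv(behav_path, index=False)
    truth_path = out / "truth.json"
    truth_path.write_text(json.dumps([c.to_dict() for c in study.truth], indent=1))
    record("simulate", [epochs_path, behav_path, truth_path], seed=sim.seed)

    results = analyse_study(study, config)
    roi_path = out / "roi.csv"
    results.roi.to_csv(roi_path, index=False)
    roi_pooled_path = out / "roi_pooled.csv"
    results.roi_pooled.to_csv(roi_pooled_path, index=False)
    record("summarise", [roi_path, roi_pooled_path], counts=results.counts)
    skill_path = out / "skill.csv"
    results.skill.to_csv(skill_path, index=False)
    record("behaviour", [skill_path])

    stats_paths = []
    for name, frame in (
        ("anova", results.anova),
        ("session_posthoc", results.session_posthoc),
        ("hand_posthoc", results.hand_posthoc),
    ):
        p = out / f"stats_{name}.csv"
        frame.to_csv(p, index=False)
        stats_paths.append(p)
    corr_path = out / "stats_correlation.json"
    corr_path.write_text(json.dumps(results.correlation, indent=1))
    stats_paths.append(corr_path)
    record("stats", stats_paths)

    dump_yaml(json.loads(config.model_dump_json()), out / "config.yaml")
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1))
    logger.info("pipeline complete: %d stages -> %s", len(manifest["stages"]), out)
    return {"manifest": manifest, "results": results, "out_dir": out}
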