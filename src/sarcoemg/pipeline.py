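"""End-to-end orchestration: synth -> preprocess -> features -> balance ->
select -> evaluate, with a reproducible run manifest.

Every stage's outputs are persisted so any stage can be rerun in isolation;
the manifest records the effective configuration, SHA-256 digests of every
written artefact, per-stage wall times and the package version.

Note on balancing placement: with the default cohort (3/22/7 subjects) the
level-1 class is smaller than the fold count, so stratified 10-fold CV is
only possible after global augmentation — the full-pipeline default
therefore follows the published order (SMOTE+ENN on the whole dataset, then
CV).  When enough real subjects exist, set ``paper_mode: false`` to balance
inside each training fold instead (leakage-safe).
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .balancing import BalancingParams, smote_enn
from .core_io import (PipelineConfig, ValidationError, logger,
                      write_assessments, write_recording)
from .evaluation import EvaluationReport, run_cv
from .features import (FeatureMatrix, FeatureParams, WindowPlan,
                       build_feature_matrix)
from .preprocessing import preprocess
from .selection import FeatureMask, TgaParams, fixed_paper_subset, mbtga_select
from .synthetic import CohortSpec, SyntheticSubject, generate_cohort


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    config: dict
    package_version: str = __version__
    stages: dict[str, dict] = field(default_factory=dict)

    def record(self, stage: str, seconds: float, outputs: list[Path]) -> None:
        if stage in self.stages:
            raise ValidationError(f"stage {stage} recorded twice")
        self.stages[stage] = {
            "seconds": round(seconds, 3),
            "outputs": {p.name: _sha256(p) for p in outputs},
        }

    def to_json(self, path: str | Path) -> Path:
        Path(path).write_text(json.dumps(
            {"package_version": self.package_version, "config": self.config,
             "stages": self.stages}, indent=2, sort_keys=True))
        return Path(path)


def extract_cohort_features(subjects: list[SyntheticSubject],
                            config: PipelineConfig) -> FeatureMatrix:
    """Preprocess every subject and assemble the feature matrix.

    By default all 12 features are computed on the band-passed, MVC-scaled
    signal (the 10 Hz envelope would make ZC/SSC/WAMP/AIF degenerate); the
    count-feature threshold 0.1 mV is divided by each channel's MVC
    reference so it keeps its physical meaning in normalised units.
    """
    recordings, labels, channel_thrs = [], [], []
    for s in subjects:
        filt_scaled, env_norm, mvc = preprocess(
            s.recording, config.band_low, config.band_high, config.filter_order,
            config.envelope_cutoff, config.filter_phase, config.baseline_subtract)
        source = filt_scaled if config.feature_source == "filtered" else env_norm
        recordings.append(source)
        labels.append(s.level)
        channel_thrs.append({ch: config.thr_mv / ref
                             for ch, ref in mvc.refs_mv.items()})

    plan = WindowPlan(config.window_ms, config.step_ms, config.sampling_rate)
    # threshold differs per subject (its own MVC), so extract subject by
    # subject and concatenate
    parts = [
        build_feature_matrix([rec], [lvl], plan,
                             FeatureParams(thr=config.thr_mv, channel_thr=thr),
                             features=config.features,
                             edge_trim_s=config.edge_trim_s,
                             aggregate=config.aggregate)
        for rec, lvl, thr in zip(recordings, labels, channel_thrs)
    ]
    data = pd.concat([p.data for p in parts])
    lab = pd.concat([p.labels for p in parts])
    return FeatureMatrix(data=data, labels=lab)


def run_all(config: PipelineConfig, out_dir: str | Path,
            write_signals: bool = True) -> tuple[RunManifest, EvaluationReport]:
    """Execute the full pipeline and persist all stage outputs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config.to_dict())

    # synth
    t0 = time.perf_counter()
    spec = CohortSpec(seed=config.seed, sampling_rate=config.sampling_rate)
    subjects = generate_cohort(spec)
    outputs: list[Path] = []
    if write_signals:
        sig_dir = out / "signals"
        sig_dir.mkdir(exist_ok=True)
        for s in subjects:
            p_sig = sig_dir / f"{s.recording.subject_id}.csv"
            p_ann = sig_dir / f"{s.recording.subject_id}_ann.csv"
            write_recording(s.recording, p_sig, p_ann)
            outputs += [p_sig, p_ann]
    p_assess = out / "assessments.csv"
    write_assessments([s.assessment for s in subjects], p_assess,
                      levels=[s.level for s in subjects])
    outputs.append(p_assess)
    manifest.record("synth", time.perf_counter() - t0, outputs)

    # preprocess + features
    t0 = time.perf_counter()
    fm = extract_cohort_features(subjects, config)
    p_feat = out / "features.csv"
    fm.to_csv(p_feat)
    manifest.record("features", time.perf_counter() - t0, [p_feat])

    # balance (global, published order) unless per-fold balancing is requested
    t0 = time.perf_counter()
    if config.paper_mode:
        fm_bal = smote_enn(fm, BalancingParams(
            smote_k=config.smote_k, enn_k=config.enn_k,
            target=config.smote_target, seed=config.seed))
    else:
        fm_bal = fm
        min_count = min(fm.class_counts().values())
        if min_count < config.cv_folds:
            raise ValidationError(
                f"smallest class has {min_count} instances < {config.cv_folds} "
                "folds; enable paper_mode (global balancing) or reduce folds")
    p_bal = out / "balanced.csv"
    fm_bal.to_csv(p_bal)
    manifest.record("balance", time.perf_counter() - t0, [p_bal])

    # select
    t0 = time.perf_counter()
    if config.selection == "fixed_paper_subset":
        mask = fixed_paper_subset(fm_bal.columns)
    elif config.selection == "mbtga":
        mask, _trace = mbtga_select(fm_bal, TgaParams(seed=config.seed))
    else:
        mask = None
    p_mask = out / "mask.json"
    if mask is not None:
        mask.to_json(p_mask)
        manifest.record("select", time.perf_counter() - t0, [p_mask])
    else:
        manifest.record("select", time.perf_counter() - t0, [])

    # evaluate
    t0 = time.perf_counter()
    report = run_cv(fm_bal, folds=config.cv_folds, seed=config.seed,
                    balance_in_fold=not config.paper_mode, mask=mask,
                    balance_params=BalancingParams(
                        smote_k=config.smote_k, enn_k=config.enn_k,
                        seed=config.seed))
    p_report = out / "report.json"
    report.to_json(p_report)
    p_table = out / "report_table.txt"
    p_table.write_text(report.table().to_string(float_format="%.3f") + "\n")
    manifest.record("evaluate", time.perf_counter() - t0, [p_report, p_table])

    p_manifest = manifest.to_json(out / "manifest.json")
    logger.info("run complete: %s", p_manifest)
    return manifest, report
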