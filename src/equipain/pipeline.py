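"""End-to-end study pipeline: data in, tables and curves out.

Stages (each persisted as CSV so runs are restartable and independently
inspectable):

1. acquire  — generate a synthetic study or ingest trace TSVs + CSVs,
2. gait     — stride segmentation and HDmin/PDmin/TAS per occasion,
3. timeline — proportional-time normalization and pain status (TAS > cut-off),
4. table1   — descriptive score summaries per scale and phase,
5. icc      — inter-observer ICC(2, A1) per scale,
6. models   — spline mixed model per observer x scale (+ partial effects),
7. roc      — ROC/AUC of model predictions against pain status,
8. manifest — config snapshot, seed, file inventory with checksums.

Everything is deterministic from the config seed; the manifest carries no
timestamps, so identical runs are byte-identical.
"""
from __future__ import annotations

import hashlib
import json
import logging
import shutil
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import association, gait, reliability, roc, scales, synthetic, timeline
from .config import StudyConfig, load_config, save_config
from .exceptions import EquipainError, InsufficientDataError, ValidationError

__all__ = ["RunManifest", "run_analysis", "make_fixtures", "compute_study_asymmetry"]

log = logging.getLogger(__name__)

MIN_MODEL_ROWS = 20


@dataclass
class RunManifest:
    config: dict
    seed: int
    inputs: Dict[str, str]  # path -> sha256
    outputs: Dict[str, str]
    row_counts: Dict[str, int]
    warnings: List[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {"config": self.config, "seed": self.seed, "inputs": self.inputs,
             "outputs": self.outputs, "row_counts": self.row_counts,
             "warnings": self.warnings},
            indent=2, sort_keys=True, default=str)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def compute_study_asymmetry(occasions: pd.DataFrame, trace_dir: Path,
                            warnings_sink: Optional[List[str]] = None
                            ) -> pd.DataFrame:
    """Gait metrics for every occasion; TAS versus each horse's baseline.

    ``occasions`` needs columns ``horse, occasion, clock_time_h, trace_file``
    (several trace files per occasion may be given separated by ``;``; their
    trial means are averaged).
    """
    req = {"horse", "occasion", "clock_time_h", "trace_file"}
    if not req <= set(occasions.columns):
        raise ValidationError(f"occasion table needs columns {sorted(req)}")
    rows = []
    for (horse, occ), grp in occasions.groupby(["horse", "occasion"], sort=True):
        results = []
        for files in grp["trace_file"]:
            for fname in str(files).split(";"):
                trace = gait.read_trace_tsv(trace_dir / fname.strip(),
                                            horse_id=horse, occasion_id=occ)
                results.append(gait.analyze_trial(trace))
        combined = gait.combine_trials(results)
        rows.append({"horse": horse, "occasion": occ,
                     "clock_time_h": float(grp["clock_time_h"].iloc[0]),
                     "hdmin_mm": combined.hdmin, "pdmin_mm": combined.pdmin,
                     "n_strides": combined.n_strides})
    df = pd.DataFrame(rows).sort_values(["horse", "clock_time_h"]).reset_index(drop=True)

    out = []
    for horse, grp in df.groupby("horse", sort=True):
        base = grp[grp["clock_time_h"] <= 0]
        if len(base) != 1:
            raise ValidationError(
                f"horse {horse}: exactly one baseline occasion required, "
                f"found {len(base)}")
        b = gait.AsymmetryResult(hdmin=float(base["hdmin_mm"].iloc[0]),
                                 pdmin=float(base["pdmin_mm"].iloc[0]),
                                 n_strides=int(base["n_strides"].iloc[0]))
        for _, r in grp.iterrows():
            cur = gait.AsymmetryResult(hdmin=float(r["hdmin_mm"]),
                                       pdmin=float(r["pdmin_mm"]),
                                       n_strides=int(r["n_strides"]))
            rec = dict(r)
            rec["tas_mm"] = gait.compute_tas(cur, b)
            out.append(rec)
    return pd.DataFrame(out)


def run_analysis(config: StudyConfig | str | Path, out_dir: str | Path,
                 in_dir: Optional[str | Path] = None,
                 pain_cutoff_mm: float = timeline.DEFAULT_PAIN_CUTOFF_MM,
                 basis_dim: int = 10) -> RunManifest:
    """Execute the full pipeline; returns (and writes) the run manifest.

    With ``in_dir=None`` a synthetic study is generated from the config
    (written under ``out_dir/data``); otherwise ``in_dir`` must hold
    ``occasions.csv``, ``assessments.csv`` and the referenced trace TSVs.
    On any stage error, partial outputs are removed and the error re-raised
    with stage context.
    """
    cfg = load_config(config) if isinstance(config, (str, Path)) else config
    cfg.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    warnings_log: List[str] = []
    produced: List[Path] = []
    stage = "setup"
    t_start = time.time()
    try:
        # ---- stage 1: acquire -------------------------------------------
        stage = "acquire"
        if in_dir is None:
            data_dir = out / "data"
            study = synthetic.generate_study(cfg, out_dir=data_dir)
            occasions, assessments = study.occasions, study.assessments
            trace_dir = data_dir
        else:
            trace_dir = Path(in_dir)
            occasions = pd.read_csv(trace_dir / "occasions.csv")
            assessments = pd.read_csv(trace_dir / "assessments.csv")
        assessments["observer"] = assessments["observer"].astype(str)
        _validate_assessments(assessments)
        log.info("acquire: %d occasions, %d assessment rows (%.1fs)",
                 len(occasions), len(assessments), time.time() - t_start)

        # ---- stage 2: gait metrics --------------------------------------
        stage = "gait"
        asym = compute_study_asymmetry(occasions, trace_dir, warnings_log)
        p = out / "occasion_asymmetry.csv"
        asym.to_csv(p, index=False, float_format="%.4f")
        produced.append(p)

        # ---- stage 3: timeline ------------------------------------------
        stage = "timeline"
        asym_t = timeline.add_timeline_columns(asym, cutoff=pain_cutoff_mm)
        p = out / "occasion_timeline.csv"
        asym_t.to_csv(p, index=False, float_format="%.4f")
        produced.append(p)

        # ---- stage 4: score summaries -----------------------------------
        stage = "table1"
        table1 = scales.summarize_scores(assessments, by="phase")
        p = out / "table1_summary.csv"
        table1.to_csv(p, index=False, float_format="%.4f")
        produced.append(p)

        # ---- stage 5: reliability ---------------------------------------
        stage = "icc"
        scale_names = [s.name for s in scales.builtin_scales()
                       if s.name in set(assessments["scale"])]
        icc = reliability.icc_by_scale(assessments, scale_names)
        p = out / "icc.csv"
        icc.to_csv(p, index=False, float_format="%.4f")
        produced.append(p)

        # ---- stage 6: association models --------------------------------
        stage = "models"
        merged = assessments.merge(
            asym_t[["horse", "occasion", "tas_mm", "prop_time_pct", "pain_status"]],
            on=["horse", "occasion"], how="inner")
        model_rows, curves = [], {}
        fits = {}
        for obs in sorted(merged["observer"].unique()):
            for scale_name in scale_names:
                cell = merged[(merged["observer"] == obs)
                              & (merged["scale"] == scale_name)]
                if len(cell) < MIN_MODEL_ROWS or cell["horse"].nunique() < 2:
                    warnings_log.append(
                        f"models: observer {obs} x {scale_name} skipped "
                        f"({len(cell)} rows)")
                    continue
                try:
                    fit = association.fit_association_model(cell, k=basis_dim)
                except EquipainError as exc:
                    warnings_log.append(
                        f"models: observer {obs} x {scale_name} failed: {exc}")
                    continue
                fits[(obs, scale_name)] = (fit, cell)
                model_rows.append({
                    "observer": obs, "scale": scale_name, "n": fit.n,
                    "p_association": fit.p_association,
                    "p_timing": fit.p_timing, "r2_adj": fit.r2_adj,
                    "edf": fit.edf, "phi": fit.phi,
                    "sigma2_horse": fit.sigma2_horse,
                })
                grid = np.linspace(cell["tas_mm"].min(), cell["tas_mm"].max(), 50)
                curves[(obs, scale_name)] = association.partial_effect_curve(fit, grid)
        table2 = pd.DataFrame(model_rows)
        p = out / "table2_models.csv"
        table2.to_csv(p, index=False, float_format="%.6g")
        produced.append(p)
        pe_dir = out / "partial_effects"
        pe_dir.mkdir(exist_ok=True)
        for (obs, scale_name), curve in curves.items():
            p = pe_dir / f"obs{obs}_{scale_name}.csv"
            curve.to_csv(p, index=False, float_format="%.5f")
            produced.append(p)

        # ---- stage 7: diagnostic accuracy -------------------------------
        stage = "roc"
        auc_rows = []
        for (obs, scale_name), (fit, cell) in fits.items():
            labels = cell["pain_status"].to_numpy(bool)
            if labels.all() or not labels.any():
                warnings_log.append(
                    f"roc: observer {obs} x {scale_name} has a single class")
                continue
            preds = association.predict_scores(fit, cell)
            curve = roc.compute_roc(preds, labels)
            auc_rows.append({"observer": obs, "scale": scale_name,
                             "auc": curve.auc, "ci_low": curve.ci_low,
                             "ci_high": curve.ci_high, "label": curve.label,
                             "n_obs": len(cell)})
        auc_df = pd.DataFrame(auc_rows)
        p = out / "auc.csv"
        auc_df.to_csv(p, index=False, float_format="%.4f")
        produced.append(p)

        # ---- stage 8: manifest ------------------------------------------
        stage = "manifest"
        inputs = {}
        for f in sorted(Path(trace_dir).glob("*")):
            if f.is_file():
                inputs[str(f.relative_to(out) if out in f.parents else f.name)] = _sha256(f)
        outputs = {str(f.relative_to(out)): _sha256(f) for f in produced}
        manifest = RunManifest(
            config=cfg.to_dict(), seed=cfg.seed, inputs=inputs, outputs=outputs,
            row_counts={"occasions": len(occasions),
                        "assessments": len(assessments),
                        "models": len(table2), "auc": len(auc_df)},
            warnings=sorted(warnings_log),
        )
        (out / "manifest.json").write_text(manifest.to_json() + "\n")
        log.info("pipeline complete in %.1fs (%d warnings)",
                 time.time() - t_start, len(warnings_log))
        return manifest
    except Exception as exc:
        for f in produced:
            f.unlink(missing_ok=True)
        if isinstance(exc, EquipainError):
            raise type(exc)(f"stage '{stage}': {exc}") from exc
        raise EquipainError(f"stage '{stage}': {exc}") from exc


def _validate_assessments(assessments: pd.DataFrame) -> None:
    """Range-check every total against its scale; abort naming the row."""
    for i, row in assessments.iterrows():
        sc = scales.get_scale(row["scale"])
        a = scales.PainAssessment(
            horse_id=str(row["horse"]), occasion_id=str(row["occasion"]),
            observer_id=str(row["observer"]), scale=row["scale"],
            total_score=int(row["total"]), timing=str(row["timing"]),
            phase=str(row["phase"]))
        try:
            scales.validate_and_total(a, sc)
        except ValidationError as exc:
            raise ValidationError(f"assessments row {i}: {exc}") from exc


def make_fixtures(out_dir: str | Path, seed: int = 0) -> StudyConfig:
    """Write a small deterministic fixture study (3 horses, baseline + 4
    post-induction occasions, observers 1-3) used by the test suite."""
    from .config import ObserverParams, TrialSpec

    cfg = StudyConfig(
        n_horses=3,
        occasions_per_horse_mean=5.0, occasions_per_horse_sd=0.0,
        min_post_occasions=4,
        assessments_per_horse_mean=10.0, assessments_per_horse_sd=0.0,
        observer_params={
            "1": ObserverParams(gain=0.40, bias=0.02, noise_sd=0.03,
                                zero_inflation_prob=0.25),
            "2": ObserverParams(gain=0.35, bias=0.00, noise_sd=0.04,
                                zero_inflation_prob=0.30),
            "3": ObserverParams(gain=0.30, bias=0.01, noise_sd=0.05,
                                zero_inflation_prob=0.35),
        },
        third_observer_weights={"3": 1.0},
        trial=TrialSpec(duration=10.0),
        seed=seed,
    )
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    synthetic.generate_study(cfg, out_dir=out)
    save_config(cfg, out / "config.yaml")
    return cfg
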