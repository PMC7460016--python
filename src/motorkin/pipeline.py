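"""End-to-end orchestration: simulate -> segment -> features -> reliability.

Each stage reads and writes plain files (recording CSVs, segments.json,
features CSVs, report CSVs plus a full-precision JSON twin), so a run can
be resumed from any intermediate.  A single top-level seed drives all
randomness through named substreams; identical config + seed reproduces
byte-identical full-precision JSON outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator

from . import features as ft
from . import reliability as rel
from . import segmentation as seg
from . import synthesis as syn
from .skeleton_io import (Recording, SubjectProfile, read_recording,
                          read_subjects, write_recording, write_subjects)

__all__ = [
    "RunConfig",
    "run_pipeline",
    "simulate_stage",
    "segment_stage",
    "features_stage",
    "reliability_stage",
    "segment_recording",
]

log = logging.getLogger("motorkin")


class RunConfig(BaseModel):
    """Validated configuration of one reproducible pipeline run."""

    out_dir: str = "run"
    seed: int = 0
    n_subjects: int = 10
    n_series: int = 3
    order: tuple[str, ...] = syn.DEFAULT_ORDER
    script: dict = Field(default_factory=dict)  # MotionScript overrides
    sensor: dict = Field(default_factory=dict)  # SensorModel overrides
    icc_form: str = "oneway"
    alpha: float = 0.05
    cv_threshold_pct: float = 10.0
    es_moderate: float = 0.41
    es_large: float = 0.70
    greeting_min_amplitude_m: float = 0.2
    greeting_band_hz: tuple[float, float] = (0.5, 3.0)
    repetitions: int = 5

    @field_validator("alpha")
    @classmethod
    def _alpha_open_unit(cls, v: float) -> float:
        if not 0.0 < v < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        return v

    @field_validator("cv_threshold_pct", "es_moderate", "es_large")
    @classmethod
    def _positive(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("thresholds must be positive")
        return v

    @field_validator("n_subjects", "n_series", "repetitions")
    @classmethod
    def _at_least_one(cls, v: int) -> int:
        if v < 1:
            raise ValueError("counts must be >= 1")
        return v

    @field_validator("icc_form")
    @classmethod
    def _known_form(cls, v: str) -> str:
        if v not in ("oneway", "twoway"):
            raise ValueError("icc_form must be 'oneway' or 'twoway'")
        return v

    def motion_script(self) -> syn.MotionScript:
        return syn.MotionScript(**{"repetitions": self.repetitions,
                                   **self.script})

    def sensor_model(self) -> syn.SensorModel:
        return syn.SensorModel(**self.sensor)

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True,
                               allow_nan=True) + "\n")


def _rec_path(out: Path, subject_id: str, series: int) -> Path:
    return out / "recordings" / f"{subject_id}_s{series}.rec.csv"


def _iter_recordings(out: Path) -> list[tuple[str, int, Path]]:
    """(subject_id, series_index, path) for every recording on disk."""
    items = []
    for path in sorted((out / "recordings").glob("*.rec.csv")):
        stem = path.name[: -len(".rec.csv")]
        sid, _, s = stem.rpartition("_s")
        items.append((sid, int(s), path))
    return items


# --------------------------------------------------------------------------
# stages
# --------------------------------------------------------------------------


def simulate_stage(config: RunConfig, out: Path) -> None:
    """Write one recording file per subject x series, plus subjects.csv and
    the generator's ground_truth.json."""
    (out / "recordings").mkdir(parents=True, exist_ok=True)
    profiles, recordings = syn.simulate_cohort(
        config.n_subjects, config.n_series, seed=config.seed,
        script=config.motion_script(), sensor=config.sensor_model(),
        order=config.order,
    )
    write_subjects(profiles, out / "subjects.csv")
    truth = {}
    for (sid, series), (rec, gt) in recordings.items():
        write_recording(rec, _rec_path(out, sid, series))
        truth[f"{sid}_s{series}"] = gt.to_dict()
    _json_dump(truth, out / "ground_truth.json")
    log.info("simulated %d subjects x %d series", config.n_subjects,
             config.n_series)


def segment_recording(rec: Recording, config: RunConfig
                      ) -> list[seg.ManeuverSegment]:
    """Detect greetings, carve the protocol, split repetitions."""
    script = config.motion_script()
    greetings = seg.detect_greetings(
        rec, min_amplitude=config.greeting_min_amplitude_m,
        band=config.greeting_band_hz,
    )
    segments = seg.segment_protocol(
        rec, greetings, order=config.order,
        greeting_duration_s=script.greeting_duration_s,
    )
    out = []
    for s in segments:
        if s.maneuver in ("FNT", "SST", "CST"):
            s = seg.split_repetitions(s, rec, n_expected=config.repetitions)
        out.append(s)
    return out


def segment_stage(config: RunConfig, out: Path) -> None:
    result = {}
    for sid, series, path in _iter_recordings(out):
        rec = read_recording(path)
        try:
            segments = segment_recording(rec, config)
        except seg.SegmentationError as exc:
            raise seg.SegmentationError(
                f"segmentation failed for {sid} series {series}: "
                f"{exc}") from exc
        result[f"{sid}_s{series}"] = [
            {
                "maneuver": s.maneuver, "start": s.start, "end": s.end,
                "side": s.side,
                "repetitions": [
                    {"start": r.start, "end": r.end, "side": r.side,
                     "apex": r.apex}
                    for r in s.repetitions
                ],
            }
            for s in segments
        ]
    _json_dump(result, out / "segments.json")
    log.info("segmented %d recordings", len(result))


def _load_segments(out: Path) -> dict[str, list[seg.ManeuverSegment]]:
    raw = json.loads((out / "segments.json").read_text())
    result = {}
    for key, items in raw.items():
        result[key] = [
            seg.ManeuverSegment(
                maneuver=d["maneuver"], start=d["start"], end=d["end"],
                side=d["side"],
                repetitions=tuple(
                    seg.Repetition(r["start"], r["end"], r["side"], r["apex"])
                    for r in d["repetitions"]
                ),
            )
            for d in items
        ]
    return result


def features_stage(config: RunConfig, out: Path) -> None:
    """Long-format sub-measure table and the wide 20-variable table."""
    seg_map = _load_segments(out)
    cfg = ft.FeatureConfig()
    rows = []
    for sid, series, path in _iter_recordings(out):
        rec = read_recording(path)
        measures = ft.extract_trial_measures(
            rec, seg_map[f"{sid}_s{series}"], cfg)
        for name, value in measures.items():
            rows.append({
                "subject_id": sid, "series_index": series,
                "variable": name, "value": value,
                "valid": bool(np.isfinite(value)),
            })
    long_df = pd.DataFrame(rows)
    long_df.to_csv(out / "features.csv", index=False)
    sub = long_df.pivot_table(index=["subject_id", "series_index"],
                              columns="variable", values="value")
    wide = ft.compose_variables(sub)
    wide.to_csv(out / "features_wide.csv")
    log.info("extracted features for %d recordings", len(sub))


def _variable_matrix(wide: pd.DataFrame, var: str) -> tuple[np.ndarray, int]:
    """n x k matrix for one variable; incomplete subjects dropped (logged)."""
    piv = wide[var].unstack("series_index")
    complete = piv.dropna()
    n_dropped = len(piv) - len(complete)
    if n_dropped:
        log.warning("%s: dropped %d subject(s) with missing trials",
                    var, n_dropped)
    return complete.to_numpy(), n_dropped


def reliability_stage(config: RunConfig, out: Path) -> None:
    """Reliability, attempt-difference and group-difference reports.

    Writes 2-decimal CSVs plus a full-precision JSON twin.
    """
    wide = pd.read_csv(out / "features_wide.csv",
                       index_col=["subject_id", "series_index"])
    subjects = read_subjects(out / "subjects.csv")
    groups = {p.subject_id: p.activity_class for p in subjects}
    report_dir = out / "report"
    report_dir.mkdir(exist_ok=True)

    rel_rows, att_rows, grp_rows, full = [], [], [], {}
    for var in ft.VARIABLE_NAMES:
        X, n_dropped = _variable_matrix(wide, var)
        row = rel.reliability_row(
            var, X, alpha=config.alpha, icc_form=config.icc_form,
            es_seed=config.seed, cv_threshold=config.cv_threshold_pct,
            n_dropped=n_dropped,
        )
        a = row.anova
        rel_rows.append({
            "variable": var, "F": a.f_trials, "p": a.p,
            "ICC": row.icc, "CI_lower": row.ci_lower,
            "CI_upper": row.ci_upper, "category": row.category,
            "SEM": row.sem, "CV_pct": row.cv,
            "CV_acceptable": row.cv_acceptable,
        })
        att = {
            "variable": var,
            **{f"attempt{j + 1}_mean": float(X[:, j].mean())
               for j in range(X.shape[1])},
            **{f"attempt{j + 1}_sd": float(X[:, j].std(ddof=1))
               for j in range(X.shape[1])},
            "df": a.df_trials if a.sphericity_assumed else a.df_trials_adj,
            "sphericity_assumed": a.sphericity_assumed,
            "F": a.f_trials, "p": a.p,
            "ES": row.es.es, "ES_CI_lower": row.es.ci_lower,
            "ES_CI_upper": row.es.ci_upper, "ES_band": row.es.band,
        }
        att_rows.append(att)
        means = wide[var].groupby("subject_id").mean()
        labels = np.array([groups[s] for s in means.index])
        if len(set(labels)) == 2:
            cmp_ = rel.compare_groups(means.to_numpy(), labels,
                                      alpha=config.alpha)
            grp_rows.append({
                "variable": var, "test": cmp_.test,
                "active_mean": float(means[labels == "active"].mean()),
                "active_sd": float(means[labels == "active"].std(ddof=1)),
                "sedentary_mean": float(means[labels == "sedentary"].mean()),
                "sedentary_sd": float(means[labels == "sedentary"].std(ddof=1)),
                "statistic": cmp_.statistic, "p": cmp_.p,
                "CI_lower": cmp_.ci_lower, "CI_upper": cmp_.ci_upper,
            })
        full[var] = {
            "reliability": rel_rows[-1],
            "attempts": att,
            "groups": grp_rows[-1] if grp_rows and
            grp_rows[-1]["variable"] == var else None,
            "anova": dataclasses.asdict(a),
            "n_dropped": n_dropped,
        }

    pd.DataFrame(rel_rows).to_csv(report_dir / "reliability.csv",
                                  index=False, float_format="%.2f")
    pd.DataFrame(att_rows).to_csv(report_dir / "attempts.csv",
                                  index=False, float_format="%.2f")
    pd.DataFrame(grp_rows).to_csv(report_dir / "groups.csv",
                                  index=False, float_format="%.2f")
    _json_dump(json.loads(json.dumps(full, default=_jsonable)),
               report_dir / "reliability.json")
    log.info("reliability report written for %d variables", len(rel_rows))


def _jsonable(obj):
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.bool_):
        return bool(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")


# --------------------------------------------------------------------------
# full run
# --------------------------------------------------------------------------


def run_pipeline(config: RunConfig) -> Path:
    """Simulate, segment, extract and report in one deterministic run."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        _json_dump(config.model_dump(), out / "config.json")
        log.info("config hash %s", config.config_hash())
        for stage in (simulate_stage, segment_stage, features_stage,
                      reliability_stage):
            log.info("stage: %s", stage.__name__)
            stage(config, out)
    finally:
        log.removeHandler(handler)
        handler.close()
    return out
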