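"""End-to-end orchestration: simulate -> fit-norms -> score -> vlsm -> stats
-> predict -> report.

Every stage reads and writes plain interchange files (CSV for tabular data,
NIfTI for lesion volumes, JSON for the normative model and manifests)
inside one run directory, so each stage is independently re-runnable on
disk artefacts.  All randomness flows from the single ``RunConfig.seed``;
rerunning an unchanged configuration rewrites byte-identical outputs, and
the final manifest records a SHA-256 per artefact so that can be checked.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import models as om
from . import stats as cs
from .apm import sessions_from_frame, session_parameters
from .lesions import LesionMask, lesion_volume, vlsm_mean_z, vlsm_mean_z_loo, vlsm_zmap
from .normative import NormativeModel, fit_normative_model, score_observations
from .synthetic import (
    SyntheticConfig,
    control_observations,
    generate_control_cohort,
    generate_stroke_cohort,
)

__all__ = [
    "RunConfig",
    "PipelineError",
    "run_pipeline",
    "build_feature_table",
    "stage_simulate",
    "stage_fit_norms",
    "stage_score",
    "stage_vlsm",
    "stage_stats",
    "stage_predict",
    "stage_report",
]

log = logging.getLogger("propriokit")

STAGES = ("simulate", "fit-norms", "score", "vlsm", "stats", "predict", "report")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending input."""


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    out_dir: str | Path = "run"
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    vlsm_fraction: float = 0.05
    vlsm_test: str = "t"
    vlsm_leave_one_out: bool = False  # recompute the map without each participant
    k_folds: int = 10
    seed: int = 0
    sex_code_female: int = 1  # encoding of 'female' in the feature table
    arm_code_left: int = 1  # encoding of a left affected arm

    def __post_init__(self) -> None:
        # one seed rules every stochastic stage
        self.synthetic = replace(self.synthetic, seed=self.seed)

    def save(self, path: str | Path) -> None:
        doc = {
            "out_dir": str(self.out_dir),
            "synthetic": self.synthetic.to_dict(),
            "vlsm_fraction": self.vlsm_fraction,
            "vlsm_test": self.vlsm_test,
            "vlsm_leave_one_out": self.vlsm_leave_one_out,
            "k_folds": self.k_folds,
            "seed": self.seed,
            "sex_code_female": self.sex_code_female,
            "arm_code_left": self.arm_code_left,
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text())
        syn = doc.pop("synthetic", {})
        for key in ("age_range", "lesion_grid", "voxel_size", "tlt_thresholds"):
            if key in syn and syn[key] is not None:
                syn[key] = tuple(syn[key])
        if "critical_region" in syn:
            syn["critical_region"] = tuple(tuple(b) for b in syn["critical_region"])
        return cls(synthetic=SyntheticConfig(**syn), **doc)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def _dir(base: str | Path, *parts: str, create: bool = False) -> Path:
    p = Path(base).joinpath(*parts)
    if create:
        p.mkdir(parents=True, exist_ok=True)
    return p


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def stage_simulate(config: RunConfig) -> None:
    """Generate control + stroke cohorts and write all raw interchange files."""
    out = _dir(config.out_dir, "cohort", create=True)
    syn = config.synthetic
    controls = generate_control_cohort(syn)
    _write_csv(controls.demographics, out / "controls_demographics.csv")
    _write_csv(controls.trials_frame(), out / "controls_trials.csv")

    # held-out controls for normative validation share the generator but not the seed
    model = fit_normative_model(control_observations(controls))
    stroke = generate_stroke_cohort(syn, model)
    _write_csv(stroke.demographics, out / "stroke_demographics.csv")
    _write_csv(stroke.trials_frame(), out / "stroke_trials.csv")
    _write_csv(stroke.clinical, out / "stroke_clinical.csv")
    _write_csv(stroke.scores, out / "stroke_scores.csv")
    lesion_dir = _dir(out, "lesions", create=True)
    for pid, mask in stroke.lesions.items():
        mask.save(lesion_dir / f"{pid}.nii.gz")
    syn.save(out / "synthetic_config.yaml")
    log.info(
        "simulate: %d controls (%d sessions), %d stroke participants, %d lesions",
        len(controls.demographics), len(controls.sessions), len(stroke.demographics), len(stroke.lesions),
    )


def stage_fit_norms(config: RunConfig) -> NormativeModel:
    """Fit the normative model from the control trial files."""
    cohort_dir = _dir(config.out_dir, "cohort")
    trials_path = cohort_dir / "controls_trials.csv"
    if not trials_path.exists():
        raise PipelineError(f"fit-norms: missing control trials file {trials_path}")
    demo = pd.read_csv(cohort_dir / "controls_demographics.csv").set_index("subject")
    sessions = sessions_from_frame(pd.read_csv(trials_path))
    rows = []
    for s in sessions:
        d = demo.loc[s.participant]
        row = {"subject": s.participant, "age": d["age"], "sex": d["sex"], "handedness": d["handedness"]}
        row.update(session_parameters(s).as_dict())
        rows.append(row)
    model = fit_normative_model(pd.DataFrame(rows))
    norms_dir = _dir(config.out_dir, "norms", create=True)
    model.to_json(norms_dir / "normative_model.json")
    log.info("fit-norms: %d control observations", model.n_observations)
    return model


def _load_model(config: RunConfig) -> NormativeModel:
    path = _dir(config.out_dir, "norms") / "normative_model.json"
    if not path.exists():
        raise PipelineError(f"score: missing normative model {path}")
    return NormativeModel.from_json(path)


def _stroke_observations(config: RunConfig, timepoint: float) -> pd.DataFrame:
    cohort_dir = _dir(config.out_dir, "cohort")
    trials = pd.read_csv(cohort_dir / "stroke_trials.csv")
    demo = pd.read_csv(cohort_dir / "stroke_demographics.csv").set_index("participant")
    sessions = sessions_from_frame(trials[trials["timepoint"] == timepoint])
    rows = []
    for s in sessions:
        d = demo.loc[s.participant]
        row = {"subject": s.participant, "age": d["age"], "sex": d["sex"], "handedness": d["handedness"]}
        row.update(session_parameters(s).as_dict())
        rows.append(row)
    return pd.DataFrame(rows)


def stage_score(config: RunConfig) -> pd.DataFrame:
    """Score stroke sessions at both timepoints; write the parameter/score table."""
    model = _load_model(config)
    scored_2wk = score_observations(_stroke_observations(config, 2.0), model)
    scored_6mo = score_observations(_stroke_observations(config, 26.0), model)
    out = _dir(config.out_dir, "scores", create=True)
    _write_csv(scored_2wk, out / "scored_2wk.csv")
    _write_csv(scored_6mo, out / "scored_6mo.csv")
    log.info("score: %d participants at 2 weeks, %d at 6 months", len(scored_2wk), len(scored_6mo))
    return scored_2wk


def stage_vlsm(config: RunConfig) -> pd.DataFrame:
    """Lesion volumes + VLSM map (on two-week Task Scores) + per-lesion mean Z."""
    lesion_dir = _dir(config.out_dir, "cohort", "lesions")
    if not lesion_dir.exists():
        raise PipelineError(f"vlsm: missing lesion directory {lesion_dir}")
    scored = pd.read_csv(_dir(config.out_dir, "scores") / "scored_2wk.csv")
    masks, pids = [], []
    for pid in scored["subject"]:
        path = lesion_dir / f"{pid}.nii.gz"
        if not path.exists():
            raise PipelineError(f"vlsm: missing lesion mask {path}")
        masks.append(LesionMask.load(path))
        pids.append(pid)
    scores = scored["task_score"].to_numpy()
    zmap = vlsm_zmap(masks, scores, fraction=config.vlsm_fraction, test=config.vlsm_test)
    out = _dir(config.out_dir, "vlsm", create=True)
    zmap.save(out / "zmap.nii.gz")
    if config.vlsm_leave_one_out:
        mz = vlsm_mean_z_loo(masks, scores, fraction=config.vlsm_fraction, test=config.vlsm_test)
    else:
        mz = [vlsm_mean_z(m, zmap) for m in masks]
    feats = pd.DataFrame(
        {
            "participant": pids,
            "lesion_volume": [lesion_volume(m) for m in masks],
            "vlsm_mean_z": [r.value for r in mz],
            "vlsm_n_tested_voxels": [r.n_voxels for r in mz],
        }
    )
    _write_csv(feats, out / "lesion_features.csv")
    log.info("vlsm: %d voxels tested (min overlap %d)", int(zmap.tested.sum()), zmap.min_overlap)
    return feats


def build_feature_table(config: RunConfig) -> pd.DataFrame:
    """Assemble the per-participant feature table from the stage outputs.

    Columns: age, sex (1 = female by default), affected_arm (1 = left by
    default), tlt, bit, fim, vlsm_mean_z, lesion_volume, the eight robotic
    parameter z-scores at two weeks, the continuous Task Scores at both
    timepoints, and the binary six-month impairment label.
    """
    cohort_dir = _dir(config.out_dir, "cohort")
    demo = pd.read_csv(cohort_dir / "stroke_demographics.csv")
    clinical = pd.read_csv(cohort_dir / "stroke_clinical.csv")
    scored_2wk = pd.read_csv(_dir(config.out_dir, "scores") / "scored_2wk.csv")
    scored_6mo = pd.read_csv(_dir(config.out_dir, "scores") / "scored_6mo.csv")
    lesion_feats = pd.read_csv(_dir(config.out_dir, "vlsm") / "lesion_features.csv")

    z_cols = [c for c in scored_2wk.columns if c.startswith("z_")]
    table = demo.rename(columns={"participant": "participant"}).copy()
    table["sex"] = np.where(demo["sex"] == "female", config.sex_code_female, 1 - config.sex_code_female)
    table["affected_arm"] = np.where(demo["affected_arm"] == "left", config.arm_code_left, 1 - config.arm_code_left)
    table = table.drop(columns=["handedness"])
    table = table.merge(clinical, on="participant")
    table = table.merge(lesion_feats[["participant", "lesion_volume", "vlsm_mean_z"]], on="participant")
    table = table.merge(
        scored_2wk[["subject", "task_score"] + z_cols].rename(
            columns={"subject": "participant", "task_score": "task_score_2wk"}
        ),
        on="participant",
    )
    table = table.merge(
        scored_6mo[["subject", "task_score", "impaired"]].rename(
            columns={"subject": "participant", "task_score": "task_score_6mo", "impaired": "impaired_6mo"}
        ),
        on="participant",
    )
    table["impaired_6mo"] = table["impaired_6mo"].astype(int)
    return table


def stage_stats(config: RunConfig) -> pd.DataFrame:
    """Univariate association battery + impaired/unimpaired group tests."""
    table = build_feature_table(config)
    out = _dir(config.out_dir, "stats", create=True)
    _write_csv(table, out / "feature_table.csv")
    assoc = cs.association_battery(table)
    groups = cs.group_difference_battery(table)
    _write_csv(assoc, out / "associations.csv")
    _write_csv(groups, out / "group_differences.csv")
    log.info("stats: %d associations, %d group comparisons", len(assoc), len(groups))
    return groups


def stage_predict(config: RunConfig) -> pd.DataFrame:
    """Train and evaluate the five canonical classifiers; write the report table."""
    table_path = _dir(config.out_dir, "stats") / "feature_table.csv"
    if not table_path.exists():
        raise PipelineError(f"predict: missing feature table {table_path}")
    table = pd.read_csv(table_path)
    out = _dir(config.out_dir, "predict", create=True)
    rows, predictions = [], {}
    for spec in om.canonical_specs():
        result = om.evaluate(spec, table, k=config.k_folds, seed=config.seed)
        rows.append(
            {
                "model": spec.name,
                "accuracy": result.accuracy,
                "f1": result.f1,
                "auc": result.auc,
                "sensitivity": result.sensitivity,
                "specificity": result.specificity,
                "aic": result.aic,
            }
        )
        predictions[spec.name] = {
            "proba": [round(float(p), 10) for p in result.proba],
            "predicted": result.predicted.tolist(),
            "coefficients": {
                f: round(float(c), 10)
                for f, c in zip(result.coefficients["feature"], result.coefficients["coefficient"])
            },
        }
        _write_csv(om.roc_points(result), out / f"roc_{spec.name.lower()}.csv")
    results = pd.DataFrame(rows)
    _write_csv(results, out / "model_results.csv")
    (out / "predictions.json").write_text(json.dumps(predictions, indent=2, sort_keys=True))
    log.info("predict: %d models, k=%d folds", len(results), config.k_folds)
    return results


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def stage_report(config: RunConfig) -> dict:
    """Write the run manifest: per-artefact SHA-256 plus stage counts."""
    base = Path(config.out_dir)
    # run_config.yaml embeds the run directory path, so it is provenance,
    # not a computed artefact; hash everything else
    skip = {"manifest.json", "run_config.yaml"}
    files = sorted(p for p in base.rglob("*") if p.is_file() and p.name not in skip)
    manifest = {
        "seed": config.seed,
        "artifacts": {str(p.relative_to(base)): _sha256(p) for p in files},
    }
    results_path = base / "predict" / "model_results.csv"
    if results_path.exists():
        manifest["n_models"] = int(len(pd.read_csv(results_path)))
    (base / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "fit-norms": stage_fit_norms,
    "score": stage_score,
    "vlsm": stage_vlsm,
    "stats": stage_stats,
    "predict": stage_predict,
    "report": stage_report,
}


def run_pipeline(config: RunConfig, stages: tuple[str, ...] = STAGES) -> Path:
    """Run the requested stages in order; returns the run directory."""
    Path(config.out_dir).mkdir(parents=True, exist_ok=True)
    config.save(Path(config.out_dir) / "run_config.yaml")
    for stage in stages:
        if stage not in _STAGE_FUNCS:
            raise PipelineError(f"unknown stage {stage!r}; valid stages: {', '.join(STAGES)}")
        log.info("stage %s: starting", stage)
        try:
            _STAGE_FUNCS[stage](config)
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001 - annotate with the stage name
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    return Path(config.out_dir)
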