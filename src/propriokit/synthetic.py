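"""Synthetic control and stroke cohorts with the structure the analysis assumes.

No public dataset of trial-level arm-position-matching (APM) sessions,
clinical scores and lesion masks exists, so this module generates one.  A
single non-negative latent severity ``s`` per stroke participant links all
modalities: matching noise and workspace contraction scale with ``s``,
clinical scores (TLT, BIT, FIM) are monotone transforms of ``s`` plus
discretised noise clamped to each instrument's legal range, lesions are
random ellipsoids whose volume grows with ``s`` and which are biased to
intersect a configurable critical region when ``s`` is high.  Two features
are deliberately generated with *no* dependence on ``s``: age, and the
subject-level matching bias that drives the Shift parameters — the
downstream univariate battery should find those associations null.

Severity follows a two-component mixture (a point mass near zero for mild
strokes and a log-normal tail for substantial proprioceptive deficits) and
recovers partially between the two-week and six-month assessments for a
random subgroup.  Because the Task Score is a nonlinear composite, the
overall severity scale is calibrated empirically — by bisection against a
supplied fitted normative model, with common random numbers — so that the
realised six-month impairment fraction matches the configured prevalence.

Controls get the same session-generation machinery without severity:
matching noise increases linearly with age and differs by sex and
handedness by configured amounts, so the normative engine has demographic
structure to remove.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .apm import (
    APMSession,
    N_BLOCKS,
    N_TARGETS,
    PARAMETER_NAMES,
    session_parameters,
    sessions_to_frame,
    target_layout,
)
from .lesions import LesionMask
from .normative import NormativeModel, score_observations

__all__ = [
    "SyntheticConfig",
    "ControlCohort",
    "StrokeCohort",
    "CalibrationError",
    "generate_control_cohort",
    "generate_stroke_cohort",
    "control_observations",
]

_WS_OFFSET_X = 0.20  # workspace centre offset from the midline, metres
_WS_CENTER_Y = 0.30


class CalibrationError(RuntimeError):
    """Raised when prevalence calibration cannot reach the configured target."""


@dataclass
class SyntheticConfig:
    """All knobs of the synthetic cohort generator.

    Counts and the impairment prevalence default to the study conditions
    (799 controls contributing ~2229 assessments; 133 stroke participants,
    36.1% impaired at six months).  Effect sizes are generator choices,
    documented in the methods note.
    """

    # cohort sizes
    n_controls: int = 799
    assessments_per_control: float = 2.79  # mean; per-subject count is 1 + Poisson(mean-1)
    n_stroke: int = 133
    prop_impaired_6mo: float = 0.361

    # control demographics
    age_range: tuple[float, float] = (20.0, 85.0)
    p_female: float = 0.5
    p_left_handed: float = 0.1

    # matching-noise model (metres)
    base_noise_sd: float = 0.008
    effect_age: float = 1.0e-4  # noise-SD increase per year of age
    effect_sex: float = 0.001  # additive SD term for females
    effect_handedness: float = 0.001  # additive SD term for left-handers
    bias_sd: float = 0.006  # per-assessment matching bias SD per axis
    scale_sd: float = 0.05  # per-assessment workspace scale jitter per axis

    # stroke demographics
    stroke_age_mean: float = 60.2
    stroke_age_sd: float = 13.0
    p_female_stroke: float = 42.0 / 133.0
    p_left_affected: float = 78.0 / 133.0

    # latent severity
    p_severe: float = 0.5  # baseline probability of the log-normal tail component
    effect_left_affected: float = 1.2  # log-odds shift of tail membership for left-affected
    severity_mild_sd: float = 0.15  # half-normal SD of the mild component
    severity_tail_logmean: float = 0.0
    severity_tail_logsd: float = 0.5
    p_recover: float = 0.5
    recovery_factor: float = 0.45  # fractional severity shrink 2wk -> 6mo for recoverers
    severity_scale: float | None = None  # fixed scale; None = calibrate against the normative model

    # severity -> behaviour couplings
    sev_noise_sd: float = 0.005  # extra matching-noise SD (m) per unit severity
    sev_contract: float = 0.07  # workspace contraction per unit severity
    tlt_thresholds: tuple[float, float, float] = (0.35, 0.9, 1.6)
    tlt_noise_sd: float = 0.35
    bit_slope: float = 20.0
    bit_noise_sd: float = 4.0
    fim_slope: float = 25.0
    fim_noise_sd: float = 6.0

    # lesions
    lesion_grid: tuple[int, int, int] = (40, 48, 40)
    voxel_size: tuple[float, float, float] = (4.0, 4.0, 4.0)  # mm
    critical_region: tuple[tuple[int, int], tuple[int, int], tuple[int, int]] = (
        (22, 30),
        (20, 30),
        (16, 26),
    )
    lesion_base_radius: float = 10.0  # mm
    lesion_radius_per_s: float = 0.5  # fractional radius growth per unit severity
    lesion_radius_logsd: float = 0.5
    crit_bias_intercept: float = -1.5  # logit of critical-region placement at s = 0
    crit_bias_slope: float = 2.0
    generate_lesions: bool = True

    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_controls, self.n_stroke) <= 0:
            raise ValueError("cohort counts must be positive")
        if self.assessments_per_control < 1:
            raise ValueError("assessments_per_control must be >= 1")
        if not 0.0 < self.prop_impaired_6mo < 1.0:
            raise ValueError("prop_impaired_6mo must lie in (0, 1)")
        if not 0.0 <= self.recovery_factor <= 1.0:
            raise ValueError("recovery_factor must lie in [0, 1]")
        for ax in range(3):
            lo, hi = self.critical_region[ax]
            if not (0 < lo < hi < self.lesion_grid[ax]):
                raise ValueError("critical_region must lie strictly inside lesion_grid")

    # -- (de)serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        doc = self.to_dict()
        if path.suffix in (".yaml", ".yml"):
            path.write_text(yaml.safe_dump(doc, sort_keys=True))
        else:
            path.write_text(json.dumps(doc, indent=2, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "SyntheticConfig":
        path = Path(path)
        text = path.read_text()
        doc = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
        for key in ("age_range", "lesion_grid", "voxel_size", "tlt_thresholds"):
            if key in doc and doc[key] is not None:
                doc[key] = tuple(doc[key])
        if "critical_region" in doc:
            doc["critical_region"] = tuple(tuple(b) for b in doc["critical_region"])
        return cls(**doc)


@dataclass
class ControlCohort:
    """Control population: demographics plus repeated APM sessions."""

    demographics: pd.DataFrame  # subject, age, sex, handedness, n_sessions
    sessions: list[APMSession]

    def trials_frame(self) -> pd.DataFrame:
        return sessions_to_frame(self.sessions)


@dataclass
class StrokeCohort:
    """Stroke cohort bundle: sessions at two timepoints plus all covariates."""

    demographics: pd.DataFrame  # participant, age, sex, handedness, affected_arm
    sessions: dict[tuple[str, float], APMSession]  # keyed by (participant, timepoint weeks)
    clinical: pd.DataFrame  # participant, tlt, bit, fim
    lesions: dict[str, LesionMask]
    scores: pd.DataFrame  # participant, task_score_2wk, task_score_6mo, impaired_6mo
    severity: pd.DataFrame  # participant, s_2wk, s_6mo, recovers (latent; for validation)
    severity_scale: float
    calibration_iterations: int

    @property
    def timepoints(self) -> tuple[float, float]:
        return (2.0, 26.0)

    def sessions_at(self, timepoint: float) -> list[APMSession]:
        return [s for (pid, tp), s in sorted(self.sessions.items()) if tp == timepoint]

    def trials_frame(self) -> pd.DataFrame:
        return sessions_to_frame([self.sessions[k] for k in sorted(self.sessions)])


# ---------------------------------------------------------------------------
# session machinery
# ---------------------------------------------------------------------------


def _noise_sd_control(cfg: SyntheticConfig, age: float, female: bool, left_handed: bool) -> float:
    sd = (
        cfg.base_noise_sd
        + cfg.effect_age * (age - cfg.age_range[0])
        + cfg.effect_sex * float(female)
        + cfg.effect_handedness * float(left_handed)
    )
    return max(sd, 0.0)


def _build_session(
    *,
    participant: str,
    arm: str,
    timepoint: float,
    block_orders: np.ndarray,  # (N_BLOCKS, N_TARGETS) target ids
    noise: np.ndarray,  # (N_TRIALS, 2) standard-normal draws
    noise_sd: float,
    bias: np.ndarray,  # (2,)
    scale: np.ndarray,  # (2,)
) -> APMSession:
    """Assemble one APM session from pre-drawn randomness.

    The matched position is modelled in the matching arm's workspace as the
    mirror of the robot position, distorted by a subject-level affine scale
    about the workspace centre, a constant bias, and i.i.d. Gaussian trial
    noise.
    """
    ws_center = np.array([-_WS_OFFSET_X if arm == "left" else _WS_OFFSET_X, _WS_CENTER_Y])
    targets = target_layout(tuple(ws_center))
    block = np.repeat(np.arange(1, N_BLOCKS + 1), N_TARGETS)
    target = block_orders.reshape(-1)
    robot = targets[target - 1]
    m_center = ws_center * np.array([-1.0, 1.0])  # mirrored about midline_x = 0
    mirrored_robot = robot * np.array([-1.0, 1.0])
    match = m_center + scale * (mirrored_robot - m_center) + bias + noise_sd * noise
    return APMSession(
        participant=participant,
        arm_assessed=arm,
        timepoint_weeks=timepoint,
        block=block,
        target=target,
        robot_pos=robot,
        match_pos=match,
        midline_x=0.0,
    )


def _block_orders(rng: np.random.Generator) -> np.ndarray:
    return np.array([rng.permutation(N_TARGETS) + 1 for _ in range(N_BLOCKS)])


# ---------------------------------------------------------------------------
# controls
# ---------------------------------------------------------------------------


def generate_control_cohort(
    config: SyntheticConfig,
    n_controls: int | None = None,
    seed: int | None = None,
) -> ControlCohort:
    """Generate a control population with repeated APM assessments.

    Subjects contribute ``1 + Poisson(assessments_per_control - 1)``
    sessions each; ages are uniform on ``age_range``; sex and handedness
    are Bernoulli.  Matching-noise SD rises linearly with age and shifts
    additively with sex and handedness by the configured effects.
    ``n_controls``/``seed`` override the config (used for held-out sets).
    """
    n = config.n_controls if n_controls is None else int(n_controls)
    if n <= 0:
        raise ValueError("n_controls must be positive")
    root = np.random.default_rng(config.seed if seed is None else seed)
    demo_rows = []
    sessions: list[APMSession] = []
    for i in range(n):
        sid = f"C{i:05d}"
        age = root.uniform(*config.age_range)
        female = root.random() < config.p_female
        left_handed = root.random() < config.p_left_handed
        arm = "left" if root.random() < 0.5 else "right"
        k = 1 + root.poisson(max(config.assessments_per_control - 1.0, 0.0))
        sd = _noise_sd_control(config, age, female, left_handed)
        for j in range(k):
            # bias and workspace scale are assessment-level (set-up and
            # postural drift of the day), redrawn per session
            bias = root.normal(0.0, config.bias_sd, size=2) if config.bias_sd > 0 else np.zeros(2)
            scale = np.clip(root.normal(1.0, config.scale_sd, size=2), 0.6, 1.4)
            sessions.append(
                _build_session(
                    participant=sid,
                    arm=arm,
                    timepoint=0.0 + j,  # session index stands in for assessment date
                    block_orders=_block_orders(root),
                    noise=root.standard_normal((N_BLOCKS * N_TARGETS, 2)),
                    noise_sd=sd,
                    bias=bias,
                    scale=scale,
                )
            )
        demo_rows.append(
            {
                "subject": sid,
                "age": age,
                "sex": "female" if female else "male",
                "handedness": "left" if left_handed else "right",
                "n_sessions": k,
            }
        )
    return ControlCohort(demographics=pd.DataFrame(demo_rows), sessions=sessions)


def control_observations(cohort: ControlCohort) -> pd.DataFrame:
    """One row per control assessment: demographics + the eight parameters.

    This is the input layout expected by
    :func:`propriokit.normative.fit_normative_model`.
    """
    demo = cohort.demographics.set_index("subject")
    rows = []
    for s in cohort.sessions:
        d = demo.loc[s.participant]
        row = {
            "subject": s.participant,
            "age": d["age"],
            "sex": d["sex"],
            "handedness": d["handedness"],
        }
        row.update(session_parameters(s).as_dict())
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# stroke cohort
# ---------------------------------------------------------------------------


def _stroke_draws(config: SyntheticConfig, rng: np.random.Generator, n: int) -> dict:
    """Pre-draw all randomness so severity can be rescaled with common random numbers."""
    draws = {
        "age": np.clip(rng.normal(config.stroke_age_mean, config.stroke_age_sd, n), 25.0, 95.0),
        "female": rng.random(n) < config.p_female_stroke,
        "left_handed": rng.random(n) < config.p_left_handed,
        "left_affected": rng.random(n) < config.p_left_affected,
        "tail_u": rng.random(n),
        "mild_s": np.abs(rng.normal(0.0, config.severity_mild_sd, n)),
        "tail_s": rng.lognormal(config.severity_tail_logmean, config.severity_tail_logsd, n),
        "recovers": rng.random(n) < config.p_recover,
        "bias": {tp: rng.normal(0.0, config.bias_sd, (n, 2)) for tp in (2.0, 26.0)},
        "scale_jitter": {tp: np.clip(rng.normal(1.0, config.scale_sd, (n, 2)), 0.6, 1.4) for tp in (2.0, 26.0)},
        "block_orders": {
            tp: [_block_orders(rng) for _ in range(n)] for tp in (2.0, 26.0)
        },
        "noise": {
            tp: rng.standard_normal((n, N_BLOCKS * N_TARGETS, 2)) for tp in (2.0, 26.0)
        },
        "tlt_eps": rng.normal(0.0, config.tlt_noise_sd, n),
        "bit_eps": rng.normal(0.0, config.bit_noise_sd, n),
        "fim_eps": rng.normal(0.0, config.fim_noise_sd, n),
        "crit_u": rng.random(n),
        "crit_center_u": rng.random((n, 3)),
        "free_center_u": rng.random((n, 3)),
        "radius_logjit": rng.normal(0.0, config.lesion_radius_logsd, (n, 3)),
    }
    # mixture membership with a left-affected log-odds shift
    base_logit = np.log(config.p_severe / (1.0 - config.p_severe))
    logit = base_logit + config.effect_left_affected * draws["left_affected"]
    p_tail = 1.0 / (1.0 + np.exp(-logit))
    in_tail = draws["tail_u"] < p_tail
    draws["s2_base"] = np.where(in_tail, draws["tail_s"], draws["mild_s"])
    draws["s6_base"] = draws["s2_base"] * np.where(draws["recovers"], 1.0 - config.recovery_factor, 1.0)
    return draws


def _stroke_sessions(
    config: SyntheticConfig, draws: dict, scale_c: float, timepoint: float, severities: np.ndarray
) -> list[APMSession]:
    sessions = []
    n = len(severities)
    for i in range(n):
        s = scale_c * severities[i]
        sd = (
            _noise_sd_control(config, draws["age"][i], draws["female"][i], draws["left_handed"][i])
            + config.sev_noise_sd * s
        )
        contr = max(1.0 - config.sev_contract * s, 0.15)
        sessions.append(
            _build_session(
                participant=f"S{i:04d}",
                arm="left" if draws["left_affected"][i] else "right",
                timepoint=timepoint,
                block_orders=draws["block_orders"][timepoint][i],
                noise=draws["noise"][timepoint][i],
                noise_sd=sd,
                bias=draws["bias"][timepoint][i],
                scale=draws["scale_jitter"][timepoint][i] * contr,
            )
        )
    return sessions


def _score_sessions(
    sessions: list[APMSession], draws: dict, model: NormativeModel
) -> pd.DataFrame:
    rows = []
    for i, s in enumerate(sessions):
        row = {
            "subject": s.participant,
            "age": draws["age"][i],
            "sex": "female" if draws["female"][i] else "male",
            "handedness": "left" if draws["left_handed"][i] else "right",
        }
        row.update(session_parameters(s).as_dict())
        rows.append(row)
    return score_observations(pd.DataFrame(rows), model)


def _calibrate_scale(
    config: SyntheticConfig, draws: dict, model: NormativeModel, tol: float = 0.02, max_iter: int = 40
) -> tuple[float, int]:
    """Bisect the severity scale so the realised 6-month prevalence hits target.

    Uses common random numbers, so the impaired fraction is (near-)monotone
    in the scale.  Raises :class:`CalibrationError` if no scale within the
    search bracket gets within 5 percentage points of the target.
    """
    target = config.prop_impaired_6mo

    def frac(c: float) -> float:
        sessions = _stroke_sessions(config, draws, c, 26.0, draws["s6_base"])
        return float(_score_sessions(sessions, draws, model)["impaired"].mean())

    lo, hi = 0.02, 40.0
    f_lo, f_hi = frac(lo), frac(hi)
    best_c, best_gap = (lo, abs(f_lo - target)) if abs(f_lo - target) < abs(f_hi - target) else (hi, abs(f_hi - target))
    iterations = 2
    for _ in range(max_iter):
        mid = np.sqrt(lo * hi)  # geometric bisection: scale acts multiplicatively
        f_mid = frac(mid)
        iterations += 1
        gap = abs(f_mid - target)
        if gap < best_gap:
            best_c, best_gap = mid, gap
        if gap <= tol:
            return mid, iterations
        if f_mid < target:
            lo = mid
        else:
            hi = mid
    if best_gap > 0.05:
        raise CalibrationError(
            f"prevalence calibration failed: best realised fraction differs from "
            f"target {target:.3f} by {best_gap:.3f} after {iterations} evaluations"
        )
    return best_c, iterations


def _make_lesion(
    config: SyntheticConfig, draws: dict, i: int, severity: float
) -> LesionMask:
    grid = np.asarray(config.lesion_grid)
    vox = np.asarray(config.voxel_size)
    crit = np.asarray(config.critical_region, dtype=float)
    p_crit = 1.0 / (1.0 + np.exp(-(config.crit_bias_intercept + config.crit_bias_slope * severity)))
    if draws["crit_u"][i] < p_crit:
        center = crit[:, 0] + draws["crit_center_u"][i] * (crit[:, 1] - crit[:, 0])
    else:
        margin = 4.0
        center = margin + draws["free_center_u"][i] * (grid - 2 * margin)
    radii_mm = (
        config.lesion_base_radius
        * (1.0 + config.lesion_radius_per_s * severity)
        * np.exp(draws["radius_logjit"][i])
    )
    radii_vox = np.maximum(radii_mm / vox, 0.5)
    idx = [np.arange(g) for g in grid]
    dx = (idx[0][:, None, None] - center[0]) / radii_vox[0]
    dy = (idx[1][None, :, None] - center[1]) / radii_vox[1]
    dz = (idx[2][None, None, :] - center[2]) / radii_vox[2]
    data = (dx**2 + dy**2 + dz**2) <= 1.0
    if not data.any():
        c = np.clip(np.round(center).astype(int), 0, grid - 1)
        data[c[0], c[1], c[2]] = True
    return LesionMask(data=data, voxel_size=tuple(float(v) for v in vox), space="synthetic-grid")


def generate_stroke_cohort(config: SyntheticConfig, model: NormativeModel) -> StrokeCohort:
    """Generate the full stroke cohort bundle.

    Requires a fitted :class:`~propriokit.normative.NormativeModel` so the
    latent severity scale can be calibrated against the 1.96 impairment
    threshold (unless ``config.severity_scale`` pins it).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1_001]))
    draws = _stroke_draws(config, rng, config.n_stroke)

    if config.severity_scale is not None:
        scale_c, iterations = float(config.severity_scale), 0
    else:
        scale_c, iterations = _calibrate_scale(config, draws, model)

    s2 = scale_c * draws["s2_base"]
    s6 = scale_c * draws["s6_base"]
    sess_2wk = _stroke_sessions(config, draws, scale_c, 2.0, draws["s2_base"])
    sess_6mo = _stroke_sessions(config, draws, scale_c, 26.0, draws["s6_base"])
    scored_2wk = _score_sessions(sess_2wk, draws, model)
    scored_6mo = _score_sessions(sess_6mo, draws, model)

    pids = [s.participant for s in sess_2wk]
    demographics = pd.DataFrame(
        {
            "participant": pids,
            "age": draws["age"],
            "sex": np.where(draws["female"], "female", "male"),
            "handedness": np.where(draws["left_handed"], "left", "right"),
            "affected_arm": np.where(draws["left_affected"], "left", "right"),
        }
    )
    tlt = np.digitize(s2 + draws["tlt_eps"], config.tlt_thresholds)
    bit = np.clip(np.round(146.0 - config.bit_slope * s2 + draws["bit_eps"]), 0, 146).astype(int)
    fim = np.clip(np.round(126.0 - config.fim_slope * s2 + draws["fim_eps"]), 18, 126).astype(int)
    clinical = pd.DataFrame({"participant": pids, "tlt": tlt, "bit": bit, "fim": fim})

    lesions: dict[str, LesionMask] = {}
    if config.generate_lesions:
        for i, pid in enumerate(pids):
            lesions[pid] = _make_lesion(config, draws, i, s2[i])

    scores = pd.DataFrame(
        {
            "participant": pids,
            "task_score_2wk": scored_2wk["task_score"].to_numpy(),
            "task_score_6mo": scored_6mo["task_score"].to_numpy(),
            "impaired_6mo": scored_6mo["impaired"].to_numpy().astype(int),
        }
    )
    severity = pd.DataFrame(
        {"participant": pids, "s_2wk": s2, "s_6mo": s6, "recovers": draws["recovers"]}
    )
    sessions = {(s.participant, s.timepoint_weeks): s for s in sess_2wk + sess_6mo}
    return StrokeCohort(
        demographics=demographics,
        sessions=sessions,
        clinical=clinical,
        lesions=lesions,
        scores=scores,
        severity=severity,
        severity_scale=scale_c,
        calibration_iterations=iterations,
    )
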