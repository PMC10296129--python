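"""Normative z-scoring of APM parameters and the composite zeta Task Score.

Raw APM parameters are not directly comparable across people: performance
worsens with age and differs by sex and handedness, and most parameters
have skewed distributions.  The normative engine removes both problems
using a large control population:

1. each parameter is Box-Cox transformed to approximate normality
   (location shift + power exponent fitted by profile maximum likelihood
   on a fixed exponent grid);
2. outliers beyond +/-3.29 SD of the transformed distribution are trimmed;
3. a weighted linear regression on age, sex and handedness (weights
   1/sessions-per-subject, so subjects with repeat assessments do not
   dominate) removes demographic effects, and the residual SD converts the
   transformed value into a z-score with control mean 0 and SD 1;
4. per-parameter z-scores are folded so that 0 is the best attainable
   score: one-sided parameters (absolute error, variability — only large
   values are bad) are clamped at zero from below, two-sided parameters
   (shift, contraction/expansion — any deviation is bad) take the absolute
   value;
5. the root-sum-square (RSS) of the folded scores is itself normalised
   (Box-Cox + mean/SD learned on the controls) into an RSS z-score;
6. the **Task Score** is the half-normal (zeta) transform of that z-score,
   ``zeta = Phi^-1((Phi(z) + 1) / 2)``: non-negative, 0 = best, and by
   construction 95% of controls fall below 1.96, so a Task Score > 1.96
   flags impairment.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.special as sc
import statsmodels.api as sm

from .apm import PARAMETER_NAMES

__all__ = [
    "IMPAIRMENT_THRESHOLD",
    "OUTLIER_SD",
    "PARAMETER_DIRECTION",
    "Demographics",
    "ParameterNorm",
    "RSSNorm",
    "NormativeModel",
    "TaskScore",
    "boxcox_transform",
    "fit_boxcox",
    "trim_outliers",
    "fit_normative_model",
    "parameter_z",
    "one_sided_transform",
    "zeta_transform",
    "task_score",
    "score_observations",
]

#: Task Scores above this value indicate abnormal performance (95th centile
#: of the control distribution under the half-normal construction).
IMPAIRMENT_THRESHOLD = 1.96

#: Trim threshold on standardized transformed values (two-sided 0.001 tail).
OUTLIER_SD = 3.29

#: Direction convention per parameter: for one-sided parameters only large
#: values indicate poor performance, for two-sided parameters deviation in
#: either direction does.
PARAMETER_DIRECTION = {
    "abs_error_x": "one_sided_high_bad",
    "abs_error_y": "one_sided_high_bad",
    "variability_x": "one_sided_high_bad",
    "variability_y": "one_sided_high_bad",
    "contract_expand_x": "two_sided",
    "contract_expand_y": "two_sided",
    "shift_x": "two_sided",
    "shift_y": "two_sided",
}

_BOXCOX_GRID = np.round(np.arange(-5.0, 5.0 + 1e-9, 0.01), 2)
_DOMAIN_EPS = 1e-9


@dataclass(frozen=True)
class Demographics:
    """Covariates the normative model adjusts for."""

    age: float
    sex: str  # "male" | "female"
    handedness: str  # "left" | "right"
    affected_arm: str | None = None  # stroke participants only

    def __post_init__(self) -> None:
        if self.age <= 0:
            raise ValueError("age must be positive")
        if self.sex not in ("male", "female"):
            raise ValueError("sex must be 'male' or 'female'")
        if self.handedness not in ("left", "right"):
            raise ValueError("handedness must be 'left' or 'right'")


def boxcox_transform(values: np.ndarray, shift: float, exponent: float) -> np.ndarray:
    """Box-Cox power transform ``((x + shift)^lambda - 1)/lambda`` (log at 0)."""
    x = np.asarray(values, dtype=float) + shift
    x = np.maximum(x, _DOMAIN_EPS)
    if exponent == 0.0:
        return np.log(x)
    return (np.power(x, exponent) - 1.0) / exponent


def fit_boxcox(values: np.ndarray) -> tuple[float, float, np.ndarray]:
    """Fit a Box-Cox transform by profile maximum likelihood.

    The location shift makes all values positive (``1 - min`` when the
    minimum is <= 0, else 0); the exponent is chosen on the fixed grid
    [-5, 5] in steps of 0.01 by maximising the profile log-likelihood.

    Returns ``(shift, exponent, transformed values)``.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 20:
        raise ValueError("Box-Cox fit requires at least 20 values")
    if np.ptp(x) == 0:
        raise ValueError("cannot fit Box-Cox to constant input")
    shift = 1.0 - x.min() if x.min() <= 0 else 0.0
    xs = x + shift
    n = len(xs)
    logx = np.log(xs)
    sum_logx = logx.sum()
    # profile llf(lambda) = (lambda-1) sum(log x) - n/2 log(var(y_lambda))
    best_lmb, best_llf = None, -np.inf
    for lmb in _BOXCOX_GRID:
        if lmb == 0.0:
            y = logx
        else:
            y = (np.power(xs, lmb) - 1.0) / lmb
        var = y.var()
        if var <= 0 or not np.isfinite(var):
            continue
        llf = (lmb - 1.0) * sum_logx - 0.5 * n * np.log(var)
        if llf > best_llf:
            best_llf, best_lmb = llf, float(lmb)
    if best_lmb is None:
        raise ValueError("Box-Cox profile likelihood degenerate on the whole grid")
    return shift, best_lmb, boxcox_transform(x, shift, best_lmb)


def trim_outliers(values: np.ndarray, threshold: float = OUTLIER_SD) -> tuple[np.ndarray, np.ndarray]:
    """Remove values beyond ``threshold`` SDs from the mean.

    Returns ``(retained values, removed mask)`` where the mask is True for
    removed entries.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 20:
        raise ValueError("outlier trimming requires at least 20 values")
    z = (x - x.mean()) / x.std(ddof=1)
    removed = np.abs(z) > threshold
    return x[~removed], removed


@dataclass
class ParameterNorm:
    """Fitted normative state for one APM parameter."""

    shift: float
    exponent: float
    coef: np.ndarray  # (intercept, age, sex=female, handedness=left)
    resid_sd: float
    direction: str

    def __post_init__(self) -> None:
        self.coef = np.asarray(self.coef, dtype=float)
        if self.resid_sd <= 0:
            raise ValueError("residual SD must be positive")
        if self.direction not in ("one_sided_high_bad", "two_sided"):
            raise ValueError(f"unknown direction {self.direction!r}")


@dataclass
class RSSNorm:
    """Fitted Box-Cox + mean/SD state for the RSS composite."""

    shift: float
    exponent: float
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("RSS SD must be positive")


@dataclass
class NormativeModel:
    """Complete fitted normative model for the eight APM parameters."""

    params: dict[str, ParameterNorm]
    rss: RSSNorm
    n_observations: int
    schema_version: int = field(default=1)

    def __post_init__(self) -> None:
        missing = set(PARAMETER_NAMES) - set(self.params)
        if missing:
            raise ValueError(f"missing parameter norms: {sorted(missing)}")

    # -- serialisation ----------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        doc = {
            "schema_version": self.schema_version,
            "n_observations": self.n_observations,
            "rss": {
                "shift": self.rss.shift,
                "exponent": self.rss.exponent,
                "mean": self.rss.mean,
                "sd": self.rss.sd,
            },
            "params": {
                name: {
                    "shift": p.shift,
                    "exponent": p.exponent,
                    "coef": p.coef.tolist(),
                    "resid_sd": p.resid_sd,
                    "direction": p.direction,
                }
                for name, p in self.params.items()
            },
        }
        Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "NormativeModel":
        doc = json.loads(Path(path).read_text())
        if doc.get("schema_version") != 1:
            raise ValueError(f"unsupported schema version {doc.get('schema_version')!r}")
        params = {
            name: ParameterNorm(
                shift=p["shift"],
                exponent=p["exponent"],
                coef=np.asarray(p["coef"]),
                resid_sd=p["resid_sd"],
                direction=p["direction"],
            )
            for name, p in doc["params"].items()
        }
        rss = RSSNorm(**doc["rss"])
        return cls(params=params, rss=rss, n_observations=doc["n_observations"])


@dataclass(frozen=True)
class TaskScore:
    """Composite zeta Task Score; non-negative, >1.96 indicates impairment."""

    value: float
    impaired: bool
    at_domain_edge: bool = False

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("Task Score is non-negative")


def _design_matrix(age: np.ndarray, sex: np.ndarray, handedness: np.ndarray) -> np.ndarray:
    """Design: intercept, age (years), sex (1=female), handedness (1=left)."""
    return np.column_stack(
        [np.ones_like(age, dtype=float), age.astype(float), sex.astype(float), handedness.astype(float)]
    )


def _encode_demo(demo: Demographics) -> np.ndarray:
    return np.array([1.0, demo.age, 1.0 if demo.sex == "female" else 0.0, 1.0 if demo.handedness == "left" else 0.0])


def fit_normative_model(observations: pd.DataFrame) -> NormativeModel:
    """Fit the full normative model from control observations.

    ``observations`` has one row per control assessment with columns
    ``subject``, ``age``, ``sex`` (``male``/``female``), ``handedness``
    (``left``/``right``) and the eight parameter columns of
    ``PARAMETER_NAMES``.  Per-observation regression weight is
    1/(assessments contributed by that subject).

    Requires at least 50 observations.
    """
    obs = observations.reset_index(drop=True)
    if len(obs) < 50:
        raise ValueError("normative calibration requires at least 50 control observations")
    age = obs["age"].to_numpy(dtype=float)
    sex = (obs["sex"].astype(str) == "female").to_numpy()
    hand = (obs["handedness"].astype(str) == "left").to_numpy()
    weights = 1.0 / obs.groupby("subject")["subject"].transform("size").to_numpy(dtype=float)
    X = _design_matrix(age, sex, hand)

    params: dict[str, ParameterNorm] = {}
    z_cols = np.empty((len(obs), len(PARAMETER_NAMES)))
    for j, name in enumerate(PARAMETER_NAMES):
        raw = obs[name].to_numpy(dtype=float)
        shift, lmb, transformed = fit_boxcox(raw)
        _, removed = trim_outliers(transformed)
        keep = ~removed
        fit = sm.WLS(transformed[keep], X[keep], weights=weights[keep]).fit()
        resid = transformed[keep] - X[keep] @ fit.params
        w = weights[keep]
        resid_sd = float(np.sqrt(np.sum(w * resid**2) / np.sum(w)))
        norm = ParameterNorm(
            shift=shift,
            exponent=lmb,
            coef=fit.params,
            resid_sd=resid_sd,
            direction=PARAMETER_DIRECTION[name],
        )
        params[name] = norm
        # score *all* observations (including trimmed ones) for the RSS stage
        z_cols[:, j] = (transformed - X @ norm.coef) / norm.resid_sd

    folded = np.column_stack(
        [one_sided_transform(z_cols[:, j], PARAMETER_DIRECTION[name]) for j, name in enumerate(PARAMETER_NAMES)]
    )
    rss_values = np.sqrt((folded**2).sum(axis=1))
    r_shift, r_lmb, r_transformed = fit_boxcox(rss_values)
    rss = RSSNorm(shift=r_shift, exponent=r_lmb, mean=float(r_transformed.mean()), sd=float(r_transformed.std(ddof=1)))
    return NormativeModel(params=params, rss=rss, n_observations=len(obs))


def parameter_z(
    raw: dict[str, float], demo: Demographics, model: NormativeModel
) -> tuple[dict[str, float], bool]:
    """Demographically adjusted z-score per parameter.

    Returns ``(z-scores, at_domain_edge)``; the flag is True when any raw
    value fell below the Box-Cox domain and was scored at the domain edge
    (a warning is also emitted).
    """
    x = _encode_demo(demo)
    zs: dict[str, float] = {}
    edge = False
    for name in PARAMETER_NAMES:
        p = model.params[name]
        value = raw[name]
        if value + p.shift <= 0:
            edge = True
            warnings.warn(
                f"{name}={value:.4g} below Box-Cox domain; scored at the domain edge",
                RuntimeWarning,
                stacklevel=2,
            )
        t = boxcox_transform(np.array([value]), p.shift, p.exponent)[0]
        zs[name] = float((t - x @ p.coef) / p.resid_sd)
    return zs, edge


def one_sided_transform(z: np.ndarray | float, direction: str) -> np.ndarray | float:
    """Fold a z-score so 0 is best and larger is worse.

    ``one_sided_high_bad`` clamps negative z at 0 (better-than-average is
    simply "not bad"); ``two_sided`` takes the absolute value.
    """
    if direction == "one_sided_high_bad":
        return np.maximum(z, 0.0)
    if direction == "two_sided":
        return np.abs(z)
    raise ValueError(f"unknown direction {direction!r}")


def zeta_transform(z: np.ndarray | float) -> np.ndarray | float:
    """Half-normal quantile map ``zeta = Phi^-1((Phi(z) + 1)/2)``.

    Monotone, non-negative; if z is standard normal, zeta is distributed as
    |N(0, 1)|, so P(zeta < 1.96) = P(z < 1.645) = 0.95.  Evaluated through
    log-space tail quantities so extreme z do not overflow.
    """
    z = np.asarray(z, dtype=float)
    # (Phi(z)+1)/2 = 1 - Phi(-z)/2; use the complementary quantile in log space
    log_q = np.log(0.5) + sc.log_ndtr(-z)
    zeta = -sc.ndtri_exp(log_q)
    zeta = np.maximum(zeta, 0.0)
    return float(zeta) if zeta.ndim == 0 else zeta


def task_score(z_scores: dict[str, float], model: NormativeModel) -> TaskScore:
    """Composite Task Score from per-parameter z-scores.

    RSS of the folded scores, normalised by the model's stored RSS Box-Cox
    + mean/SD, then mapped through the zeta transform; impairment flagged
    above ``IMPAIRMENT_THRESHOLD``.
    """
    folded = np.array(
        [one_sided_transform(z_scores[name], model.params[name].direction) for name in PARAMETER_NAMES]
    )
    rss = float(np.sqrt((folded**2).sum()))
    edge = rss + model.rss.shift <= 0
    t = boxcox_transform(np.array([rss]), model.rss.shift, model.rss.exponent)[0]
    z = (t - model.rss.mean) / model.rss.sd
    zeta = float(zeta_transform(z))
    return TaskScore(value=zeta, impaired=zeta > IMPAIRMENT_THRESHOLD, at_domain_edge=edge)


def score_observations(observations: pd.DataFrame, model: NormativeModel) -> pd.DataFrame:
    """Vectorised scoring of many assessments.

    ``observations`` uses the same layout as :func:`fit_normative_model`
    (``subject`` optional).  Returns a copy with added columns ``z_<param>``
    for each parameter, ``rss``, ``task_score`` and ``impaired``.
    """
    obs = observations.reset_index(drop=True)
    age = obs["age"].to_numpy(dtype=float)
    sex = (obs["sex"].astype(str) == "female").to_numpy()
    hand = (obs["handedness"].astype(str) == "left").to_numpy()
    X = _design_matrix(age, sex, hand)
    out = obs.copy()
    folded = np.empty((len(obs), len(PARAMETER_NAMES)))
    for j, name in enumerate(PARAMETER_NAMES):
        p = model.params[name]
        t = boxcox_transform(obs[name].to_numpy(dtype=float), p.shift, p.exponent)
        z = (t - X @ p.coef) / p.resid_sd
        out[f"z_{name}"] = z
        folded[:, j] = one_sided_transform(z, p.direction)
    rss = np.sqrt((folded**2).sum(axis=1))
    t = boxcox_transform(rss, model.rss.shift, model.rss.exponent)
    z_rss = (t - model.rss.mean) / model.rss.sd
    out["rss"] = rss
    out["task_score"] = zeta_transform(z_rss)
    out["impaired"] = out["task_score"] > IMPAIRMENT_THRESHOLD
    return out
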