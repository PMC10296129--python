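"""Univariate association battery and group comparisons.

Mirrors the classical two-stage screen used in outcome studies: first,
each candidate two-week feature is related to the continuous six-month
Task Score (OLS for continuous features, Spearman for the ordinal TLT,
two-sample t for binary demographics); second, participants are split
into impaired / unimpaired at six months and each feature is compared
between groups with Mann-Whitney U tests under a Bonferroni-adjusted
critical alpha (0.05 / 14 comparisons = 0.00357).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as st

from .apm import PARAMETER_NAMES

__all__ = [
    "AssociationResult",
    "linear_assoc",
    "spearman_assoc",
    "two_sample_t",
    "mann_whitney",
    "bonferroni_alpha",
    "neglect_flag",
    "association_battery",
    "group_difference_battery",
    "BATTERY_FEATURES",
]

#: The 14 features of the impaired-vs-unimpaired Mann-Whitney battery:
#: age, the three clinical scores, the two lesion features and the eight
#: robotic parameters.  Sex and affected arm are categorical and excluded.
BATTERY_FEATURES = ("age", "tlt", "bit", "fim", "lesion_volume", "vlsm_mean_z") + tuple(
    f"z_{name}" for name in PARAMETER_NAMES
)


@dataclass(frozen=True)
class AssociationResult:
    """One feature-outcome test: statistic, effect size, p, significance."""

    feature: str
    method: str  # linear_regression | spearman | t_test | mann_whitney
    statistic: float
    effect: float | None  # R^2 or rho where applicable
    p: float
    significant: bool
    effect_adjusted: float | None = None  # adjusted R^2 (linear regression only)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p must lie in [0, 1]")


def _finite(*arrays: np.ndarray) -> list[np.ndarray]:
    out = [np.asarray(a, dtype=float) for a in arrays]
    for a in out:
        if not np.all(np.isfinite(a)):
            raise ValueError("inputs must be finite")
    return out


def linear_assoc(x: np.ndarray, y: np.ndarray, feature: str = "", alpha: float = 0.05) -> AssociationResult:
    """Simple OLS of y on x: slope t-test, plain and adjusted R^2."""
    x, y = _finite(x, y)
    n = len(x)
    if n < 3 or len(y) != n:
        raise ValueError("need n >= 3 paired observations")
    if np.ptp(x) == 0:
        raise ValueError("predictor has zero variance")
    res = st.linregress(x, y)
    r2 = res.rvalue**2
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return AssociationResult(
        feature=feature,
        method="linear_regression",
        statistic=float(res.slope / res.stderr) if res.stderr > 0 else np.inf,
        effect=float(r2),
        effect_adjusted=float(adj),
        p=float(res.pvalue),
        significant=bool(res.pvalue < alpha),
    )


def spearman_assoc(x: np.ndarray, y: np.ndarray, feature: str = "", alpha: float = 0.05) -> AssociationResult:
    """Spearman rank correlation (midrank ties), p via the t approximation."""
    x, y = _finite(x, y)
    if len(x) < 4 or len(y) != len(x):
        raise ValueError("need n >= 4 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input has no rank correlation")
    rho, p = st.spearmanr(x, y)
    return AssociationResult(
        feature=feature,
        method="spearman",
        statistic=float(rho),
        effect=float(rho),
        p=float(p),
        significant=bool(p < alpha),
    )


def two_sample_t(group_a: np.ndarray, group_b: np.ndarray, feature: str = "", alpha: float = 0.05) -> AssociationResult:
    """Student's pooled-variance two-sample t-test, two-sided."""
    a, b = _finite(group_a, group_b)
    if min(len(a), len(b)) < 2:
        raise ValueError("both groups need n >= 2")
    t, p = st.ttest_ind(a, b, equal_var=True)
    return AssociationResult(
        feature=feature,
        method="t_test",
        statistic=float(t),
        effect=None,
        p=float(p),
        significant=bool(p < alpha),
    )


def _mw_exact_p(a: np.ndarray, b: np.ndarray) -> float:
    """Exhaustive-permutation two-sided Mann-Whitney p (tie-aware).

    Counts group assignments whose U deviates from the null mean at least
    as much as the observed one; feasible for small pooled samples.
    """
    import itertools

    pooled = np.concatenate([a, b])
    n1 = len(a)
    ranks = st.rankdata(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    mu = n1 * len(b) / 2.0
    count = total = 0
    for comb in itertools.combinations(range(len(pooled)), n1):
        u = ranks[list(comb)].sum() - n1 * (n1 + 1) / 2.0
        count += abs(u - mu) >= abs(u_obs - mu) - 1e-9
        total += 1
    return count / total


def mann_whitney(group_a: np.ndarray, group_b: np.ndarray, feature: str = "", alpha: float = 0.05) -> AssociationResult:
    """Mann-Whitney U test, two-sided.

    Small pooled samples (n1 + n2 <= 14) use an exhaustive tie-aware
    permutation p-value; larger samples use the normal approximation with
    continuity and tie corrections.
    """
    a, b = _finite(group_a, group_b)
    if min(len(a), len(b)) < 2:
        raise ValueError("both groups need n >= 2")
    n1 = len(a)
    u = float(st.rankdata(np.concatenate([a, b]))[:n1].sum() - n1 * (n1 + 1) / 2.0)
    if len(a) + len(b) <= 14:
        p = _mw_exact_p(a, b)
    else:
        _, p = st.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return AssociationResult(
        feature=feature,
        method="mann_whitney",
        statistic=float(u),
        effect=None,
        p=float(p),
        significant=bool(p < alpha),
    )


def bonferroni_alpha(family_alpha: float, m: int) -> float:
    """Bonferroni-adjusted critical alpha: family alpha / number of comparisons."""
    if m < 1:
        raise ValueError("number of comparisons must be >= 1")
    return family_alpha / m


def neglect_flag(bit_score: float) -> bool:
    """Hemispatial-neglect screen: BIT scores below 130 are flagged."""
    if not 0 <= bit_score <= 146:
        raise ValueError("BIT score must lie in [0, 146]")
    return bit_score < 130


def association_battery(table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Feature-by-feature association with the six-month Task Score.

    ``table`` needs a ``task_score_6mo`` column plus the feature columns;
    OLS for continuous features, Spearman for ``tlt``, pooled t-tests for
    ``sex`` and ``affected_arm`` (coded 0/1).  Returns a tidy results table.
    """
    y = table["task_score_6mo"].to_numpy(dtype=float)
    results: list[AssociationResult] = []
    for feat in BATTERY_FEATURES:
        if feat not in table.columns:
            continue
        x = table[feat].to_numpy(dtype=float)
        if feat == "tlt":
            results.append(spearman_assoc(x, y, feature=feat, alpha=alpha))
        else:
            results.append(linear_assoc(x, y, feature=feat, alpha=alpha))
    for feat in ("sex", "affected_arm"):
        if feat in table.columns:
            g = table[feat].to_numpy(dtype=float)
            results.append(two_sample_t(y[g == 1], y[g == 0], feature=feat, alpha=alpha))
    return _to_frame(results, alpha)


def group_difference_battery(table: pd.DataFrame, family_alpha: float = 0.05) -> pd.DataFrame:
    """The 14-comparison impaired-vs-unimpaired Mann-Whitney battery.

    Significance is judged at the Bonferroni-adjusted critical alpha
    (family alpha divided by the number of comparisons actually run).
    """
    label = table["impaired_6mo"].to_numpy(dtype=int)
    feats = [f for f in BATTERY_FEATURES if f in table.columns]
    alpha = bonferroni_alpha(family_alpha, len(feats))
    results = [
        mann_whitney(
            table.loc[label == 1, f].to_numpy(dtype=float),
            table.loc[label == 0, f].to_numpy(dtype=float),
            feature=f,
            alpha=alpha,
        )
        for f in feats
    ]
    return _to_frame(results, alpha)


def _to_frame(results: list[AssociationResult], alpha: float) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "feature": [r.feature for r in results],
            "method": [r.method for r in results],
            "statistic": [r.statistic for r in results],
            "effect": [r.effect for r in results],
            "effect_adjusted": [r.effect_adjusted for r in results],
            "p": [r.p for r in results],
            "significant": [r.significant for r in results],
            "critical_alpha": alpha,
        }
    )
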