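"""Arm-position-matching (APM) task representation and performance parameters.

The APM task is a proprioceptive assessment performed in a bilateral
exoskeleton robot: the robot moves one arm (the affected arm, post-stroke)
to each of nine planar targets laid out on a 20 cm x 20 cm square (eight
outer targets around a centre target), and the participant mirror-matches
the position with the opposite arm.  Each target is visited once per block,
in pseudorandom order, for six blocks: 54 trials per session.

Performance is summarised by four parameters, each computed separately in
the x and y directions after reflecting the matched hand across the body
midline onto the robot-moved workspace:

* **Absolute Error** -- mean absolute mismatch between the mirrored matched
  position and the robot position (metres).
* **Variability** -- trial-to-trial standard deviation of the mirrored
  matched position per target, averaged over the nine targets (metres).
* **Contraction/Expansion** -- ratio of the spatial range spanned by the
  mean matched positions of the eight outer targets to the range spanned by
  the corresponding robot targets (1 = veridical, <1 contracted workspace,
  >1 expanded).
* **Shift** -- mean signed mismatch (metres); a systematic translation of
  the perceived workspace.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "N_TARGETS",
    "N_BLOCKS",
    "N_TRIALS",
    "PARAMETER_NAMES",
    "WORKSPACE_SIDE",
    "target_layout",
    "APMSession",
    "APMParameters",
    "mirror_match",
    "absolute_error",
    "variability",
    "contraction_expansion",
    "shift",
    "session_parameters",
    "parameters_tidy",
    "sessions_to_frame",
    "sessions_from_frame",
]

N_TARGETS = 9
N_BLOCKS = 6
N_TRIALS = N_TARGETS * N_BLOCKS

#: Side length of the square on which the nine targets are laid out (metres).
WORKSPACE_SIDE = 0.20

#: Canonical order of the eight performance parameters.
PARAMETER_NAMES = (
    "abs_error_x",
    "abs_error_y",
    "variability_x",
    "variability_y",
    "contract_expand_x",
    "contract_expand_y",
    "shift_x",
    "shift_y",
)


def target_layout(center: tuple[float, float] = (0.0, 0.0)) -> np.ndarray:
    """Planar positions of the nine targets, metres, indexed by target id 1..9.

    Targets form a 3x3 grid spanning ``WORKSPACE_SIDE`` in x and y around
    ``center``; target 5 is the centre target.
    """
    half = WORKSPACE_SIDE / 2.0
    offsets = np.array([-half, 0.0, half])
    grid = np.array([(dx, dy) for dy in offsets[::-1] for dx in offsets])
    return grid + np.asarray(center, dtype=float)


def mirror_match(match_pos: np.ndarray, midline_x: float) -> np.ndarray:
    """Reflect matched-hand positions across the body midline.

    Only the x coordinate is reflected (about ``midline_x``); y is unchanged.
    Accepts a single (x, y) pair or an (n, 2) array.
    """
    pos = np.asarray(match_pos, dtype=float)
    if not np.all(np.isfinite(pos)):
        raise ValueError("positions must be finite")
    out = pos.copy()
    out[..., 0] = 2.0 * midline_x - out[..., 0]
    return out


@dataclass
class APMSession:
    """One APM assessment: robot-moved and participant-matched positions.

    Coordinates are in metres, in a common frame whose x axis crosses the
    body midline at ``midline_x``.  ``robot_pos`` holds the affected
    (robot-moved) hand positions, ``match_pos`` the opposite-arm matched
    positions in the matching arm's own workspace (i.e. *not* yet
    reflected).

    With ``strict=True`` (the default) the full task protocol is enforced:
    54 trials, each target appearing exactly once per block.  ``strict=False``
    admits partial sessions (useful for toy analyses and QC of aborted
    runs); parameter functions still require whatever structure they need.
    """

    participant: str
    arm_assessed: str  # "left" | "right": the robot-moved (affected) arm
    timepoint_weeks: float
    block: np.ndarray  # (n,) int, 1..6
    target: np.ndarray  # (n,) int, 1..9
    robot_pos: np.ndarray  # (n, 2) metres
    match_pos: np.ndarray  # (n, 2) metres
    midline_x: float = 0.0
    strict: bool = field(default=True, repr=False)

    def __post_init__(self) -> None:
        self.block = np.asarray(self.block, dtype=int)
        self.target = np.asarray(self.target, dtype=int)
        self.robot_pos = np.asarray(self.robot_pos, dtype=float)
        self.match_pos = np.asarray(self.match_pos, dtype=float)
        n = len(self.block)
        if not (len(self.target) == self.robot_pos.shape[0] == self.match_pos.shape[0] == n):
            raise ValueError("trial arrays must have equal length")
        if self.robot_pos.shape[1:] != (2,) or self.match_pos.shape[1:] != (2,):
            raise ValueError("positions must be (n, 2)")
        if not (np.isfinite(self.robot_pos).all() and np.isfinite(self.match_pos).all()):
            raise ValueError("positions must be finite")
        if self.arm_assessed not in ("left", "right"):
            raise ValueError("arm_assessed must be 'left' or 'right'")
        if self.strict:
            if n != N_TRIALS:
                raise ValueError(f"a complete APM session has {N_TRIALS} trials, got {n}")
            if self.block.min() < 1 or self.block.max() > N_BLOCKS:
                raise ValueError("block ids must lie in 1..6")
            if self.target.min() < 1 or self.target.max() > N_TARGETS:
                raise ValueError("target ids must lie in 1..9")
            for b in range(1, N_BLOCKS + 1):
                targets_in_block = np.sort(self.target[self.block == b])
                if not np.array_equal(targets_in_block, np.arange(1, N_TARGETS + 1)):
                    raise ValueError(f"block {b}: each target must appear exactly once")

    @property
    def n_trials(self) -> int:
        return len(self.block)

    def mirrored_match(self) -> np.ndarray:
        """Matched positions reflected across the midline onto the robot workspace."""
        return mirror_match(self.match_pos, self.midline_x)


def _mirrored_errors(session: APMSession) -> np.ndarray:
    return session.mirrored_match() - session.robot_pos


def absolute_error(session: APMSession) -> tuple[float, float]:
    """Mean absolute mirrored-match error per axis (metres)."""
    if session.n_trials == 0:
        raise ValueError("session has no trials")
    err = np.abs(_mirrored_errors(session)).mean(axis=0)
    return float(err[0]), float(err[1])


def shift(session: APMSession) -> tuple[float, float]:
    """Mean signed mirrored-match error per axis (metres)."""
    if session.n_trials == 0:
        raise ValueError("session has no trials")
    err = _mirrored_errors(session).mean(axis=0)
    return float(err[0]), float(err[1])


def variability(session: APMSession) -> tuple[float, float]:
    """Trial-to-trial SD of the mirrored match per target, averaged over targets.

    Uses the sample (n-1) standard deviation across each target's
    repetitions; every target present must have at least two repetitions.
    """
    mirrored = session.mirrored_match()
    sds = []
    for t in np.unique(session.target):
        sel = session.target == t
        if sel.sum() < 2:
            raise ValueError(f"target {t} has fewer than 2 repetitions")
        sds.append(mirrored[sel].std(axis=0, ddof=1))
    sd = np.mean(sds, axis=0)
    return float(sd[0]), float(sd[1])


def contraction_expansion(session: APMSession) -> tuple[float, float]:
    """Matched-to-robot workspace range ratio per axis over the outer targets.

    The centre target (the one nearest the centroid of the per-target robot
    positions) is excluded; the ratio is the range of per-target mean
    mirrored matched positions over the eight outer targets divided by the
    range of the corresponding robot target positions.
    """
    mirrored = session.mirrored_match()
    targets = np.unique(session.target)
    robot_means = np.array([session.robot_pos[session.target == t].mean(axis=0) for t in targets])
    match_means = np.array([mirrored[session.target == t].mean(axis=0) for t in targets])
    centroid = robot_means.mean(axis=0)
    center_idx = np.argmin(np.linalg.norm(robot_means - centroid, axis=1))
    outer = np.arange(len(targets)) != center_idx
    ratios = []
    for ax in range(2):
        robot_range = np.ptp(robot_means[outer, ax])
        if robot_range <= 0:
            raise ValueError("robot target range is degenerate (zero extent)")
        ratios.append(np.ptp(match_means[outer, ax]) / robot_range)
    return float(ratios[0]), float(ratios[1])


@dataclass(frozen=True)
class APMParameters:
    """The eight APM performance parameters for one session."""

    abs_error_x: float
    abs_error_y: float
    variability_x: float
    variability_y: float
    contract_expand_x: float
    contract_expand_y: float
    shift_x: float
    shift_y: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in PARAMETER_NAMES])

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in PARAMETER_NAMES}


def session_parameters(session: APMSession) -> APMParameters:
    """Compute all eight performance parameters for a session."""
    ae = absolute_error(session)
    var = variability(session)
    ce = contraction_expansion(session)
    sh = shift(session)
    return APMParameters(ae[0], ae[1], var[0], var[1], ce[0], ce[1], sh[0], sh[1])


def parameters_tidy(sessions: list[APMSession]) -> pd.DataFrame:
    """Tidy long-format parameter table: participant, timepoint, parameter, axis, value."""
    rows = []
    for s in sessions:
        for name, value in session_parameters(s).as_dict().items():
            base, axis = name.rsplit("_", 1)
            rows.append(
                {
                    "participant": s.participant,
                    "timepoint": s.timepoint_weeks,
                    "parameter": base,
                    "axis": axis,
                    "value": value,
                }
            )
    return pd.DataFrame(rows)


def sessions_to_frame(sessions: list[APMSession]) -> pd.DataFrame:
    """Serialise sessions to the tidy trial-level table (one row per trial).

    Columns: participant, timepoint, arm_assessed, midline_x, block, target,
    robot_x, robot_y, match_x, match_y; coordinates in metres.
    """
    frames = []
    for s in sessions:
        frames.append(
            pd.DataFrame(
                {
                    "participant": s.participant,
                    "timepoint": s.timepoint_weeks,
                    "arm_assessed": s.arm_assessed,
                    "midline_x": s.midline_x,
                    "block": s.block,
                    "target": s.target,
                    "robot_x": s.robot_pos[:, 0],
                    "robot_y": s.robot_pos[:, 1],
                    "match_x": s.match_pos[:, 0],
                    "match_y": s.match_pos[:, 1],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def sessions_from_frame(df: pd.DataFrame, strict: bool = True) -> list[APMSession]:
    """Rebuild sessions from the tidy trial-level table."""
    sessions = []
    for (pid, tp), grp in df.groupby(["participant", "timepoint"], sort=True):
        sessions.append(
            APMSession(
                participant=str(pid),
                arm_assessed=str(grp["arm_assessed"].iloc[0]),
                timepoint_weeks=float(tp),
                block=grp["block"].to_numpy(),
                target=grp["target"].to_numpy(),
                robot_pos=grp[["robot_x", "robot_y"]].to_numpy(),
                match_pos=grp[["match_x", "match_y"]].to_numpy(),
                midline_x=float(grp["midline_x"].iloc[0]),
                strict=strict,
            )
        )
    return sessions
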