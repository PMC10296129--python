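"""APM session structure and the four performance parameters."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from propriokit.apm import (
    APMSession,
    N_TRIALS,
    absolute_error,
    contraction_expansion,
    mirror_match,
    session_parameters,
    sessions_from_frame,
    sessions_to_frame,
    shift,
    target_layout,
    variability,
)
from propriokit.synthetic import SyntheticConfig, generate_control_cohort

finite_coord = st.floats(-1.0, 1.0, allow_nan=False)


def make_session(offset=(0.0, 0.0), scale=1.0, noise=None, n_blocks=6, midline_x=0.0):
    """Session whose mirrored matches equal robot targets distorted by
    ``scale`` (about the target centroid), ``offset`` and optional per-trial noise."""
    targets = target_layout(center=(0.2, 0.3))
    block = np.repeat(np.arange(1, n_blocks + 1), 9)
    target = np.tile(np.arange(1, 10), n_blocks)
    robot = targets[target - 1]
    centroid = targets.mean(axis=0)
    mirrored = centroid + scale * (robot - centroid) + np.asarray(offset)
    if noise is not None:
        mirrored = mirrored + noise
    match = mirror_match(mirrored, midline_x)  # involution: un-mirror into the matching workspace
    return APMSession(
        participant="T",
        arm_assessed="right",
        timepoint_weeks=2.0,
        block=block,
        target=target,
        robot_pos=robot,
        match_pos=match,
        midline_x=midline_x,
        strict=(n_blocks == 6),
    )


class TestMirror:
    def test_point_on_axis_is_fixed(self):
        assert np.allclose(mirror_match(np.array([0.5, 0.1]), midline_x=0.5), [0.5, 0.1])

    def test_reflection_about_zero(self):
        assert np.allclose(mirror_match(np.array([-0.15, 0.30]), midline_x=0.0), [0.15, 0.30])

    @given(x=finite_coord, y=finite_coord, mid=finite_coord)
    @settings(max_examples=50, deadline=None)
    def test_involution(self, x, y, mid):
        p = np.array([x, y])
        assert np.allclose(mirror_match(mirror_match(p, mid), mid), p, atol=1e-12)

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            mirror_match(np.array([np.nan, 0.0]), 0.0)


class TestSessionStructure:
    def test_complete_session_accepted(self):
        assert make_session().n_trials == N_TRIALS

    def test_wrong_trial_count_rejected(self):
        s = make_session()
        with pytest.raises(ValueError, match="54 trials"):
            APMSession(
                participant="T", arm_assessed="right", timepoint_weeks=2.0,
                block=s.block[:-1], target=s.target[:-1],
                robot_pos=s.robot_pos[:-1], match_pos=s.match_pos[:-1],
            )

    def test_duplicate_target_in_block_rejected(self):
        s = make_session()
        target = s.target.copy()
        target[1] = target[0]
        with pytest.raises(ValueError, match="once"):
            APMSession(
                participant="T", arm_assessed="right", timepoint_weeks=2.0,
                block=s.block, target=target, robot_pos=s.robot_pos, match_pos=s.match_pos,
            )

    def test_csv_roundtrip(self):
        sessions = [make_session(offset=(0.01, -0.02))]
        back = sessions_from_frame(sessions_to_frame(sessions))
        assert len(back) == 1
        assert np.allclose(back[0].match_pos, sessions[0].match_pos)
        assert np.array_equal(back[0].target, sessions[0].target)


class TestParameters:
    def test_perfect_mirroring_is_veridical(self):
        s = make_session()
        assert absolute_error(s) == pytest.approx((0.0, 0.0), abs=1e-12)
        assert shift(s) == pytest.approx((0.0, 0.0), abs=1e-12)
        assert variability(s) == pytest.approx((0.0, 0.0), abs=1e-12)
        assert contraction_expansion(s) == pytest.approx((1.0, 1.0))

    def test_constant_offset(self):
        s = make_session(offset=(0.02, -0.03))
        assert absolute_error(s) == pytest.approx((0.02, 0.03))
        assert shift(s) == pytest.approx((0.02, -0.03))
        assert variability(s) == pytest.approx((0.0, 0.0))
        assert contraction_expansion(s) == pytest.approx((1.0, 1.0))

    @pytest.mark.parametrize("scale", [0.5, 1.3])
    def test_pure_scaling_sets_contraction_ratio(self, scale):
        s = make_session(scale=scale)
        assert contraction_expansion(s) == pytest.approx((scale, scale))

    def test_toy_session_hand_computed_means(self):
        # 3 listed trials (relaxed protocol): mirrored errors x: +0.01, -0.02, +0.04; y: 0, +0.03, -0.03
        robot = np.array([[0.1, 0.3], [0.2, 0.3], [0.1, 0.4]])
        mirrored = robot + np.array([[0.01, 0.0], [-0.02, 0.03], [0.04, -0.03]])
        s = APMSession(
            participant="T", arm_assessed="right", timepoint_weeks=2.0,
            block=np.array([1, 1, 1]), target=np.array([1, 2, 3]),
            robot_pos=robot, match_pos=mirror_match(mirrored, 0.0),
            strict=False,
        )
        assert absolute_error(s) == pytest.approx((np.mean([0.01, 0.02, 0.04]), np.mean([0.0, 0.03, 0.03])))
        assert shift(s) == pytest.approx((np.mean([0.01, -0.02, 0.04]), np.mean([0.0, 0.03, -0.03])))

    def test_single_target_spread_sets_variability(self):
        # target 1's x matches are displaced +0.02 in half the blocks; all else perfect
        s = make_session()
        mirrored = s.mirrored_match()
        sel = np.flatnonzero(s.target == 1)
        mirrored[sel[::2], 0] += 0.02
        s2 = APMSession(
            participant="T", arm_assessed="right", timepoint_weeks=2.0,
            block=s.block, target=s.target, robot_pos=s.robot_pos,
            match_pos=mirror_match(mirrored, 0.0),
        )
        expected_target_sd = np.std([0.02, 0.0, 0.02, 0.0, 0.02, 0.0], ddof=1)
        assert variability(s2)[0] == pytest.approx(expected_target_sd / 9)
        assert variability(s2)[1] == pytest.approx(0.0, abs=1e-12)

    def test_contraction_derived_ratio(self):
        # robot outer span 0.20 m; matched x span scaled to 0.26 -> ratio 1.3
        s = make_session(scale=1.0)
        mirrored = s.mirrored_match()
        centroid = s.robot_pos.mean(axis=0)
        mirrored[:, 0] = centroid[0] + 1.3 * (mirrored[:, 0] - centroid[0])
        s2 = APMSession(
            participant="T", arm_assessed="right", timepoint_weeks=2.0,
            block=s.block, target=s.target, robot_pos=s.robot_pos,
            match_pos=mirror_match(mirrored, 0.0),
        )
        assert contraction_expansion(s2)[0] == pytest.approx(1.3)
        assert contraction_expansion(s2)[1] == pytest.approx(1.0)

    def test_variability_rejects_single_repetition(self):
        robot = np.array([[0.1, 0.3], [0.2, 0.3]])
        s = APMSession(
            participant="T", arm_assessed="right", timepoint_weeks=2.0,
            block=np.array([1, 1]), target=np.array([1, 2]),
            robot_pos=robot, match_pos=robot * [-1, 1], strict=False,
        )
        with pytest.raises(ValueError, match="repetitions"):
            variability(s)

    def test_variability_estimates_noise_sd(self):
        # mean of many per-target sample SDs approaches sigma (times the c4
        # small-sample factor for n=6, ~0.952)
        rng = np.random.default_rng(5)
        sigma = 0.01
        estimates = [
            variability(make_session(noise=rng.normal(0, sigma, (54, 2))))[0] for _ in range(300)
        ]
        import math

        c4 = np.sqrt(2 / 5) * math.gamma(3.0) / math.gamma(2.5)
        assert np.mean(estimates) == pytest.approx(sigma * c4, rel=0.03)


@pytest.fixture(scope="module")
def noisy_session():
    cohort = generate_control_cohort(SyntheticConfig(n_controls=1, seed=3))
    return cohort.sessions[0]


class TestInvariants:

    def test_abs_error_dominates_shift(self, noisy_session):
        ae, sh = absolute_error(noisy_session), shift(noisy_session)
        assert ae[0] >= abs(sh[0]) and ae[1] >= abs(sh[1])

    def test_trial_order_invariance(self, noisy_session):
        s = noisy_session
        perm = np.random.default_rng(0).permutation(s.n_trials)
        shuffled = APMSession(
            participant=s.participant, arm_assessed=s.arm_assessed, timepoint_weeks=s.timepoint_weeks,
            block=s.block[perm], target=s.target[perm],
            robot_pos=s.robot_pos[perm], match_pos=s.match_pos[perm], midline_x=s.midline_x,
        )
        assert session_parameters(shuffled).as_array() == pytest.approx(
            session_parameters(s).as_array()
        )

    def test_translation_moves_shift_not_variability(self, noisy_session):
        s = noisy_session
        translated = APMSession(
            participant=s.participant, arm_assessed=s.arm_assessed, timepoint_weeks=s.timepoint_weeks,
            block=s.block, target=s.target, robot_pos=s.robot_pos,
            match_pos=s.match_pos + np.array([-0.05, 0.04]), midline_x=s.midline_x,
        )
        base, moved = session_parameters(s), session_parameters(translated)
        assert moved.shift_x != pytest.approx(base.shift_x, abs=1e-4)
        assert moved.variability_x == pytest.approx(base.variability_x)
        assert moved.variability_y == pytest.approx(base.variability_y)
        assert moved.contract_expand_x == pytest.approx(base.contract_expand_x)
        assert moved.contract_expand_y == pytest.approx(base.contract_expand_y)
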