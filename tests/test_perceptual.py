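"""Belief filters: exact recursions, invariants, source handling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from predcontrol import (
    DesignSpec,
    HGFParams,
    KFParams,
    RWParams,
    TrialSequence,
    build_item_trajectories,
    combine_beliefs,
    combine_sources,
    compute_pe,
    generate_design,
    model_trajectory,
    simulate_hgf2,
    simulate_kf,
    simulate_rw,
)
from predcontrol.perceptual import ParameterError, theta_builder


def _seq(y, items=None):
    y = np.asarray(y, int)
    items = np.zeros(y.size, int) if items is None else np.asarray(items)
    return TrialSequence(item_id=items, session=np.zeros(y.size, int),
                         outcomes=y)


binary_seqs = st.lists(st.integers(0, 1), min_size=2, max_size=60)


class TestRescorlaWagner:
    def test_exact_recursion_oracle(self):
        # direct recursion: y=[1,1,0], alpha=.5, V0=.5 -> V=[.75,.875,.4375]
        traj = simulate_rw(_seq([1, 1, 0]), RWParams(alpha=0.5))
        v = traj.mu1_hat[1:]  # predictions for trials 2,3 = posteriors 1,2
        assert np.allclose(v, [0.75, 0.875])
        # final posterior via the prediction it would make next
        y = np.array([1, 1, 0.0])
        v_full = [0.5]
        for t in range(3):
            v_full.append(v_full[-1] + 0.5 * (y[t] - v_full[-1]))
        assert np.allclose(v_full[-1], 0.4375)
        assert np.allclose(traj.mu1_hat, v_full[:3])

    def test_full_update_predicts_previous_outcome(self):
        y = [1, 0, 0, 1, 1]
        traj = simulate_rw(_seq(y), RWParams(alpha=1.0))
        assert np.allclose(traj.mu1_hat[1:], y[:-1])

    def test_zero_learning_rate_is_constant(self):
        traj = simulate_rw(_seq([1, 0, 1, 1]), RWParams(alpha=0.0, v0=0.5))
        assert np.allclose(traj.mu1_hat, 0.5)

    def test_alpha_domain_checked(self):
        with pytest.raises(ParameterError):
            RWParams(alpha=1.5)


class TestKalmanFilter:
    def test_gain_fixed_point(self):
        # K = (K + c)/(K + c + 1) with c = pi*omega = 2 has fixed point
        # (-2 + sqrt(12))/2
        traj = simulate_kf(_seq([1, 0] * 40), KFParams(pi=2.0, omega=1.0))
        kstar = (-2 + np.sqrt(12)) / 2
        assert abs(traj.gain[-1] - kstar) < 1e-10

    def test_vanishing_process_noise_kills_learning(self):
        traj = simulate_kf(_seq([1] * 50), KFParams(pi=1e-12, omega=1e-12))
        assert np.all(np.diff(traj.gain) < 0)
        assert traj.gain[-1] < 0.02

    def test_constant_outcomes_monotone_beliefs(self):
        traj = simulate_kf(_seq([1] * 30), KFParams(pi=1.0, omega=1.0))
        assert np.all(np.diff(traj.mu1_hat) >= 0)
        assert traj.mu1_hat[-1] > 0.95

    def test_reduces_to_rw_at_constant_gain(self):
        # start the gain at its fixed point: the KF then IS a fixed-rate
        # delta rule with alpha = K*
        kstar = (-2 + np.sqrt(12)) / 2
        y = [1, 0, 0, 1, 1, 0, 1]
        kf = simulate_kf(_seq(y), KFParams(pi=2.0, omega=1.0, k0=kstar))
        rw = simulate_rw(_seq(y), RWParams(alpha=kstar))
        assert np.allclose(kf.mu1_hat, rw.mu1_hat)

    def test_parameter_domain(self):
        with pytest.raises(ParameterError):
            KFParams(pi=-1.0, omega=1.0)


class TestHGF2:
    def test_zero_second_level_mean_gives_half(self):
        traj = simulate_hgf2(_seq([1, 0]), HGFParams(omega=-3.0))
        assert traj.mu1_hat[0] == 0.5

    def test_worked_pe_example(self):
        assert compute_pe(0.3, 1) == pytest.approx(0.7)

    def test_intrusion_raises_second_level_mean(self):
        traj = simulate_hgf2(_seq([1, 1, 1]), HGFParams(omega=-2.0))
        assert np.all(np.diff(np.concatenate([[0.0], traj.mu2])) > 0)

    def test_uncertainty_weights_update_magnitude(self):
        lo = simulate_hgf2(_seq([1]), HGFParams(omega=-3.0, sigma2_0=0.5))
        hi = simulate_hgf2(_seq([1]), HGFParams(omega=-3.0, sigma2_0=4.0))
        assert hi.mu2[0] > lo.mu2[0] > 0

    def test_psi_is_inverse_posterior_precision(self):
        traj = simulate_hgf2(_seq([1, 0, 1, 1, 0]), HGFParams(omega=-1.0))
        assert np.allclose(traj.psi, traj.sigma2)

    @settings(max_examples=50, deadline=None)
    @given(y=binary_seqs, omega=st.floats(-12, 4))
    def test_beliefs_bounded_variance_positive(self, y, omega):
        traj = simulate_hgf2(_seq(y), HGFParams(omega=omega))
        assert np.all((traj.mu1_hat > 0) & (traj.mu1_hat < 1))
        assert np.all(traj.sigma2 > 0)
        assert np.all(np.abs(traj.pe) < 1)


class TestItemSource:
    def test_concatenation_matches_per_item_runs(self, default_skeleton):
        rng = np.random.default_rng(0)
        y = (rng.random(144) < 0.5).astype(int)
        seq = TrialSequence(item_id=default_skeleton.item_id,
                            session=default_skeleton.session, outcomes=y)
        traj = build_item_trajectories(seq, "hgf2", HGFParams(omega=-2.0))
        # chronological reassembly: item 0's k-th trial equals the k-th
        # step of a standalone run on item 0's outcomes
        idx = np.flatnonzero(seq.item_id == seq.item_id[0])
        solo = simulate_hgf2(_seq(y[idx]), HGFParams(omega=-2.0))
        assert np.allclose(traj.mu1_hat[idx], solo.mu1_hat)
        assert traj.valid.all()

    def test_single_item_equals_state(self):
        y = [1, 0, 1, 1, 0, 0]
        seq = _seq(y)
        item = build_item_trajectories(seq, "rw", RWParams(alpha=0.3))
        state = simulate_rw(seq, RWParams(alpha=0.3))
        assert np.allclose(item.mu1_hat, state.mu1_hat)

    def test_items_below_two_reps_are_flagged(self):
        seq = _seq([1, 0, 1], items=[0, 0, 1])
        with pytest.warns(UserWarning, match="repetition"):
            traj = build_item_trajectories(seq, "rw", RWParams(alpha=0.3))
        assert not traj.valid[2]
        assert traj.valid[:2].all()


class TestCombinedSource:
    def test_equal_precision_is_midpoint(self):
        assert combine_beliefs(0.3, 0.7) == pytest.approx(0.5)

    def test_explicit_precision_example(self):
        # (0.2*2 + 0.6*6) / (2 + 6) = 0.5
        assert combine_beliefs(0.2, 0.6, 2.0, 6.0) == pytest.approx(0.5)

    def test_dominant_precision_wins(self):
        assert combine_beliefs(0.2, 0.6, 1e-9, 1e9) == pytest.approx(0.6)

    def test_first_repetition_carries_state_belief(self, default_skeleton):
        rng = np.random.default_rng(3)
        y = (rng.random(144) < 0.4).astype(int)
        seq = TrialSequence(item_id=default_skeleton.item_id,
                            session=default_skeleton.session, outcomes=y)
        params = HGFParams(omega=-2.5)
        state = simulate_hgf2(seq, params)
        item = build_item_trajectories(seq, "hgf2", params)
        comb = combine_sources(state, item, seq)
        first = seq.repetition_index() == 0
        assert np.allclose(comb.mu1_hat[first], state.mu1_hat[first])

    def test_combined_lies_between_sources(self, default_skeleton):
        rng = np.random.default_rng(4)
        y = (rng.random(144) < 0.5).astype(int)
        seq = TrialSequence(item_id=default_skeleton.item_id,
                            session=default_skeleton.session, outcomes=y)
        params = HGFParams(omega=-2.0)
        state = simulate_hgf2(seq, params)
        item = build_item_trajectories(seq, "hgf2", params)
        comb = combine_sources(state, item, seq)
        lo = np.minimum(state.mu1_hat, item.mu1_hat) - 1e-12
        hi = np.maximum(state.mu1_hat, item.mu1_hat) + 1e-12
        assert np.all((comb.mu1_hat >= lo) & (comb.mu1_hat <= hi))


def test_theta_builder_matches_trajectories(binary_sequence):
    for model_id, params in [
        ("rw-item", RWParams(alpha=0.4)),
        ("kf-combined", KFParams(pi=1.0, omega=0.5)),
        ("hgf2-combined", HGFParams(omega=-2.0)),
    ]:
        build, valid = theta_builder(binary_sequence, model_id)
        traj = model_trajectory(binary_sequence, model_id, params)
        assert np.allclose(build(params), traj.mu1_hat)
        assert (valid == traj.valid).all() or valid.all()


def test_pe_masks_nonintrusions():
    mu = np.array([0.3, 0.5, 0.8])
    y = np.array([1, 0, 1])
    pe = compute_pe(mu, y)
    assert pe == pytest.approx([0.7, -0.5, 0.2])
    pe_plus = pe[y == 1]
    assert np.all(pe_plus > 0)
    assert pe_plus.size == 2
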