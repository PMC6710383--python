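"""Unit and property tests of the oscillator dynamics."""

from math import pi

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from oscseq import stimuli
from oscseq.core import (
    TWO_PI,
    EnsembleState,
    ErrorTrace,
    ModelParams,
    OscState,
    TargetMap,
    advance_phases,
    classify_state,
    decide_congruence,
    init_ensemble,
    match_update,
    mismatch_update,
    signed_phase_diff,
    step,
)
from conftest import drive_single


class TestInit:
    def test_same_seed_same_state(self, default_params):
        a = init_ensemble(default_params)
        b = init_ensemble(default_params)
        np.testing.assert_array_equal(a.phases, b.phases)
        np.testing.assert_array_equal(a.freqs, b.freqs)
        assert a.t == 0 and (a.last_reset == 0).all()

    @pytest.mark.parametrize("factory,lo,hi", [
        (ModelParams.visual, 0.01, 1.0),
        (ModelParams.auditory, 5.0, 6.0),
    ])
    def test_init_frequency_bands(self, factory, lo, hi):
        st = init_ensemble(factory(seed=3))
        assert st.freqs.min() >= lo and st.freqs.max() <= hi
        assert st.phases.min() >= 0 and st.phases.max() < TWO_PI

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            ModelParams(theta_locked=1.0, theta_locking=0.5)
        with pytest.raises(ValueError):
            ModelParams(freq_init_low=0.5, freq_init_high=0.1)
        with pytest.raises(ValueError):
            ModelParams(noise_std=-1.0)
        with pytest.raises(ValueError):
            ModelParams(mismatch_variant="c")


class TestAdvance:
    @pytest.mark.parametrize("phase,freq,expected", [
        (0.0, 0.0, 0.0),              # no motion
        (0.0, 0.5, pi),               # half a cycle per step
        (3 * pi / 2, 0.5, pi / 2),    # wraps through 2*pi
    ])
    def test_advance_noise_free(self, phase, freq, expected, quiet_params):
        st = EnsembleState(phases=np.array([phase]), freqs=np.array([freq]),
                           last_reset=np.zeros(1, dtype=int))
        advance_phases(st, quiet_params, np.random.default_rng(0))
        assert st.phases[0] == pytest.approx(expected, abs=1e-12)
        assert st.freqs[0] == freq and st.t == 1


class TestClassify:
    def test_at_target_is_locked(self, unimodal_targets, default_params):
        states, nearest = classify_state(
            np.array([pi / 2]), unimodal_targets, default_params)
        assert states[0] == OscState.LOCKED
        assert unimodal_targets.symbols[nearest[0]] == stimuli.BLACK

    def test_between_thresholds_is_locking(self, unimodal_targets,
                                           default_params):
        states, nearest = classify_state(
            np.array([pi / 2 + pi / 12]), unimodal_targets, default_params)
        assert states[0] == OscState.LOCKING
        assert unimodal_targets.symbols[nearest[0]] == stimuli.BLACK

    def test_far_phase_in_transit_tie_to_first(self, unimodal_targets,
                                               default_params):
        # pi is equidistant from both targets; tie goes to the first entry
        states, nearest = classify_state(
            np.array([pi]), unimodal_targets, default_params)
        assert states[0] == OscState.IN_TRANSIT
        assert nearest[0] == 0

    def test_empty_target_map_rejected(self):
        with pytest.raises(ValueError):
            TargetMap(symbols=(), target_phases=())


class TestMatchUpdate:
    def test_zero_error_keeps_frequency(self):
        ph, fr = match_update(pi / 2, 0.31, pi / 2, 4)
        assert ph == pi / 2 and fr == 0.31

    def test_match_frequency_substitution(self):
        # phase error pi/12 spread over 2*pi*2 steps
        ph, fr = match_update(pi / 2 + pi / 12, 0.5, pi / 2, 2)
        assert ph == pi / 2
        assert fr == pytest.approx(0.5 - 1.0 / 48, abs=1e-15)

    def test_circular_error_at_seam(self):
        # phase just below 2*pi, target just above 0: error is small
        ph, fr = match_update(TWO_PI - 0.1, 0.5, 0.05, 1)
        assert fr == pytest.approx(0.5 + 0.15 / TWO_PI, abs=1e-12)

    @pytest.mark.parametrize("period,f0", [(2, 0.37), (5, 0.23), (4, 0.21)])
    def test_frequency_recovery_fixed_point(self, period, f0):
        """Repeated match updates converge to one cycle per period.

        Closed-form oracle: the update projects f onto the nearest
        multiple of 1/period, so any start within 1/(2*period) of
        1/period ends exactly there.
        """
        phase, freq = 0.25, f0  # arbitrary target phase
        target = 0.25
        for _ in range(10):
            phase = np.mod(phase + TWO_PI * freq * period, TWO_PI)
            phase, freq = match_update(phase, freq, target, period)
        assert freq == pytest.approx(1.0 / period, abs=1e-6)


class TestMismatchUpdate:
    @pytest.mark.parametrize("target,expected", [
        (pi / 2, 3 * pi / 2), (3 * pi / 2, pi / 2)])
    def test_phase_inversion(self, target, expected):
        ph, _ = mismatch_update(target, 0.3, target, 5)
        assert ph == pytest.approx(expected, abs=1e-12)

    def test_documented_frequency_rule(self):
        # lagging tie at the target: period lengthened by 0.9 parts in 5
        _, fr = mismatch_update(pi / 2, 0.2, pi / 2, 5)
        assert fr == 0.2 * (1 - 0.9 / 5)
        # leading phase: period shortened
        _, fr = mismatch_update(pi / 2 + 0.01, 0.2, pi / 2, 5)
        assert fr == 0.2 * (1 + 0.9 / 5)

    def test_printed_variant_groupings(self):
        # hand-computed values of the two printed readings at
        # phi = phi_hat (E term = 2*pi exactly)
        _, fa = mismatch_update(pi / 2, 0.2, pi / 2, 5, variant="a")
        assert fa == pytest.approx(0.2 + (0.2 - 1.0 / 5) / 5, abs=1e-15)
        _, fb = mismatch_update(pi / 2, 0.2, pi / 2, 5, variant="b")
        assert fb == pytest.approx(0.2 + 0.2 / 5 - 1.0 / 5, abs=1e-15)

    def test_period_shifts_by_about_one_interval_fraction(self):
        """Free-run cross-check of the retune direction and size.

        For an oscillator at the reset cadence (f = 1/dt), the lagging
        branch lengthens the period so the target phase is reached
        about one stimulus slot later per cycle; the leading branch
        shortens it symmetrically.
        """
        dt = 10
        f = 1.0 / dt
        _, f_later = mismatch_update(3 * pi / 2, f, 3 * pi / 2, dt)
        _, f_earlier = mismatch_update(3 * pi / 2 + 0.01, f, 3 * pi / 2, dt)
        slip_later = 1.0 / f_later - 1.0 / f
        slip_earlier = 1.0 / f - 1.0 / f_earlier
        assert 0.5 < slip_later < 1.5
        assert 0.5 < slip_earlier < 1.5


class TestStep:
    def _three_oscillator_state(self):
        # ages dt = [7, 3, 4] at t = 11 after the advance
        return EnsembleState(
            phases=np.array([pi / 2 + pi / 12, pi, 3 * pi / 2 + pi / 12]),
            freqs=np.zeros(3),
            last_reset=np.array([4, 8, 7]),
            t=10,
        )

    def test_error_is_age_weighted_reset_count(self, unimodal_targets):
        params = ModelParams(n_oscillators=3, noise_std=0.0)
        st = self._three_oscillator_state()
        st, res = step(st, stimuli.WHITE, unimodal_targets, params,
                       np.random.default_rng(0))
        # osc0 locking toward black -> mismatch (dt=7); osc1 in transit;
        # osc2 locking toward white -> match (dt=4)
        np.testing.assert_array_equal(res.resets, [True, False, True])
        assert res.error == 11.0
        np.testing.assert_array_equal(st.last_reset, [11, 8, 11])

    def test_blank_slot_is_inert(self, unimodal_targets, default_params):
        rng = np.random.default_rng(0)
        st = init_ensemble(default_params, rng=rng)
        st, res = step(st, 0, unimodal_targets, default_params, rng)
        assert res.error == 0.0 and not res.resets.any()

    def test_unknown_symbol_rejected(self, unimodal_targets, default_params):
        rng = np.random.default_rng(0)
        st = init_ensemble(default_params, rng=rng)
        with pytest.raises(ValueError):
            step(st, 9, unimodal_targets, default_params, rng)

    def test_stable_stream_converges(self, unimodal_targets, default_params):
        """Resets die out after ~10 repetitions of a constant stream."""
        stream = [0, stimuli.WHITE] * 100
        _, _, resets, _ = drive_single(stream, default_params,
                                       unimodal_targets, seed=1)
        assert resets[-40:].mean() < 1.0
        assert resets[:10].mean() > 5.0


class TestDecide:
    @pytest.mark.parametrize("history,err,expected", [
        ([50, 12, 3], 20, False),
        ([50, 12, 3], 60, True),
        ([], 5, False),
    ])
    def test_decision_rule(self, history, err, expected):
        trace = ErrorTrace(errors=list(history))
        assert decide_congruence(trace, err) is expected


class TestInvariants:
    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=hst.integers(0, 2 ** 16),
           syms=hst.lists(hst.sampled_from([0, 1, 2]), min_size=1,
                          max_size=30),
           noise=hst.sampled_from([0.0, 1e-10, 0.3]))
    def test_phases_stay_on_circle(self, seed, syms, noise):
        params = ModelParams(n_oscillators=16, noise_std=noise)
        targets = TargetMap.unimodal()
        rng = np.random.default_rng(seed)
        st = init_ensemble(params, rng=rng)
        for s in syms:
            st, res = step(st, s, targets, params, rng)
            assert np.all((st.phases >= 0) & (st.phases < TWO_PI))
            assert np.all(np.asarray(res.error) >= 0)
            assert np.all(st.last_reset <= st.t)

    def test_error_zero_on_every_blank_slot(self, unimodal_targets,
                                            default_params):
        stream = ([0, stimuli.BLACK] + [0, stimuli.WHITE] * 4) * 5
        _, errors, _, _ = drive_single(stream, default_params,
                                       unimodal_targets, seed=0)
        assert np.all(errors[::2] == 0.0)

    def test_trajectories_bit_identical_under_seed(self, unimodal_targets,
                                                   default_params):
        stream = ([0, stimuli.BLACK] + [0, stimuli.WHITE] * 4) * 6
        s1, e1, _, _ = drive_single(stream, default_params,
                                    unimodal_targets, seed=7)
        s2, e2, _, _ = drive_single(stream, default_params,
                                    unimodal_targets, seed=7)
        np.testing.assert_array_equal(s1.phases, s2.phases)
        np.testing.assert_array_equal(s1.freqs, s2.freqs)
        np.testing.assert_array_equal(e1, e2)

    def test_locked_count_trend_under_congruent_stream(self,
                                                       unimodal_targets):
        """Attunement accumulates locked oscillators.

        The per-repetition mean locked count rises steeply and never
        falls by more than a single boundary oscillator.
        """
        params = ModelParams(noise_std=0.0)
        stream = [0, stimuli.WHITE] * 100
        _, _, _, states = drive_single(stream, params, unimodal_targets,
                                       seed=2)
        locked = np.array([(s == OscState.LOCKED).sum()
                           for s in states[1::2]])
        per_block = locked.reshape(-1, 10).mean(axis=1)
        assert np.all(np.diff(per_block) >= -1.0)
        assert per_block[-1] > 3 * per_block[0]

    def test_perturbation_spikes_error_after_attunement(self,
                                                        unimodal_targets,
                                                        default_params):
        """A flipped item on an attuned ensemble stands out of the
        recent error history (Fig-3E-style spike)."""
        base = ([0, stimuli.BLACK] + [0, stimuli.WHITE] * 4) * 16
        hits = 0
        for seed in range(20):
            stream = base + [0, stimuli.WHITE]  # black was due: flipped
            _, errors, _, _ = drive_single(stream, default_params,
                                           unimodal_targets, seed=seed)
            stim_errors = errors[1::2]
            hits += stim_errors[-1] > np.median(stim_errors[-11:-1])
        assert hits >= 18

    def test_signed_phase_diff_range(self):
        a = np.linspace(0, TWO_PI, 37)
        b = np.linspace(0, TWO_PI, 37)[::-1]
        d = signed_phase_diff(a, b)
        assert np.all((d > -pi) & (d <= pi))
        assert np.allclose(np.mod(a - b, TWO_PI), np.mod(d, TWO_PI))
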