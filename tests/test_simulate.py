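"""Master-equation propagation and current synthesis."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from gabakin.params import ModelVariant, RateParameters
from gabakin.scheme import build_scheme
from gabakin.simulate import (
    AgonistProtocol,
    CurrentTrace,
    current_from_occupancy,
    propagate,
    sample_channel_noise,
)
from gabakin.states import SubunitID

PARAMS = RateParameters()
PARAMS_III = RateParameters(gamma_coupling=100.0, epsilon_coupling=10.0)


def quiet_propagate(scheme, protocol):
    with pytest.warns(UserWarning, match="fastest relaxation"):
        return propagate(scheme, protocol)


class TestPropagation:
    def test_three_state_steady_state_closed_form(self):
        """No desensitizable subunits: the open occupancy settles at the
        closed-form value k_on[A] beta / (k_on[A] beta + k_on[A] alpha
        + k_off alpha)."""
        scheme = build_scheme(ModelVariant.I, PARAMS, desensitizable=[])
        traj = quiet_propagate(scheme, AgonistProtocol(segments=((5.0, 0.01),)))
        kon_a = PARAMS.k_on * 0.01
        expected = kon_a * PARAMS.beta / (
            kon_a * PARAMS.beta + kon_a * PARAMS.alpha + PARAMS.k_off * PARAMS.alpha
        )
        assert abs(traj.state("AO")[-1] - expected) < 1e-6

    def test_two_state_relaxation_time(self):
        """With one desensitizable subunit and effectively instantaneous
        activation the gated pair is an isolated two-state system relaxing
        with time constant 1/(delta+ + delta-)."""
        params = PARAMS.evolve(delta_plus=0.8, delta_minus=1.2,
                               beta=2.0e5, alpha=2.0)
        scheme = build_scheme(
            ModelVariant.I, params, desensitizable=[SubunitID.SU4]
        )
        traj = quiet_propagate(scheme, AgonistProtocol(segments=((6.0, 0.01),)))
        ao = traj.state("AO")
        # fit a single exponential to the relaxation towards equilibrium,
        # over the window where the transient is well above round-off
        t = traj.times
        sel = (t > 0.05) & (t < 2.0)
        eq = ao[-1]
        decay = ao[sel] - eq
        slope = np.polyfit(t[sel][decay > 1e-8], np.log(decay[decay > 1e-8]), 1)[0]
        tau_expected = 1.0 / (0.8 + 1.2)
        assert -1.0 / slope == pytest.approx(tau_expected, rel=0.01)

    def test_no_desensitization_monotone_open(self):
        params = PARAMS.evolve(
            delta_plus=1e-12, delta3_plus=1e-12, delta_minus=1.0, delta3_minus=1.0
        )
        scheme = build_scheme(ModelVariant.I, params)
        traj = quiet_propagate(scheme, AgonistProtocol(segments=((10.0, 0.01),)))
        ao = traj.state("AO")
        peak = int(np.argmax(ao))
        assert np.all(np.diff(ao[peak:]) > -1e-9)

    def test_probability_conservation(self):
        scheme = build_scheme(ModelVariant.III, PARAMS_III)
        traj = quiet_propagate(scheme, AgonistProtocol())
        sums = traj.probabilities.sum(axis=1)
        assert np.abs(sums - 1.0).max() < 1e-8
        assert traj.probabilities.min() >= 0.0

    def test_expm_matches_stiff_integrator(self):
        """Matrix-exponential stepping against an adaptive stiff solver."""
        scheme = build_scheme(ModelVariant.III, PARAMS_III)
        q = scheme.generator
        p0 = np.zeros(scheme.n_states)
        p0[scheme.state_index("R")] = 1.0
        t_eval = np.linspace(0.0, 60.0, 121)
        sol = solve_ivp(
            lambda t, p: p @ q, (0.0, 60.0), p0, method="Radau",
            t_eval=t_eval, rtol=1e-10, atol=1e-12,
        )
        traj = quiet_propagate(scheme, AgonistProtocol(dt=0.5))
        ours = traj.probabilities[:: 1][np.searchsorted(traj.times, t_eval)]
        assert np.abs(ours - sol.y.T).max() < 1e-6

    def test_dt_halving_invariance(self):
        """expm stepping is exact for the ideal step: halving dt leaves the
        final occupancies unchanged."""
        scheme = build_scheme(ModelVariant.III, PARAMS_III)
        a = quiet_propagate(scheme, AgonistProtocol(dt=0.004))
        b = quiet_propagate(scheme, AgonistProtocol(dt=0.002))
        assert np.abs(a.probabilities[-1] - b.probabilities[-1]).max() < 1e-8

    def test_multi_segment_washout(self):
        scheme = build_scheme(ModelVariant.I, PARAMS)
        protocol = AgonistProtocol(segments=((5.0, 0.01), (5.0, 0.0)))
        traj = quiet_propagate(scheme, protocol)
        ao = traj.state("AO")
        i_end_app = int(np.searchsorted(traj.times, 5.0))
        assert ao[-1] < 0.01 * ao[: i_end_app].max()


class TestCurrent:
    def test_resting_occupancy_zero_current(self):
        scheme = build_scheme(ModelVariant.I, PARAMS)
        traj = quiet_propagate(scheme, AgonistProtocol(segments=((0.1, 0.0),)))
        trace = current_from_occupancy(traj, scheme)
        assert np.abs(trace.current).max() == 0.0

    def test_zero_channels_zero_trace(self):
        scheme = build_scheme(ModelVariant.I, PARAMS)
        traj = quiet_propagate(scheme, AgonistProtocol(segments=((1.0, 0.01),)))
        trace = current_from_occupancy(traj, scheme, n_channels=0)
        assert np.abs(trace.current).max() == 0.0

    def test_model_II_current_dominates_model_I(self):
        """Model II's conducting set contains model I's, so on the same
        occupancies its current magnitude is pointwise at least as large."""
        s1 = build_scheme(ModelVariant.I, PARAMS)
        s2 = build_scheme(ModelVariant.II, PARAMS)
        traj = quiet_propagate(s1, AgonistProtocol(segments=((30.0, 0.01),)))
        i1 = np.abs(current_from_occupancy(traj, s1).current)
        i2 = np.abs(current_from_occupancy(traj, s2).current)
        assert np.all(i2 >= i1 - 1e-12)


@pytest.fixture(scope="module")
def traj_scheme():
    scheme = build_scheme(ModelVariant.III, PARAMS_III)
    with pytest.warns(UserWarning):
        traj = propagate(scheme, AgonistProtocol(segments=((10.0, 0.01),)))
    return traj, scheme


class TestChannelNoise:
    def test_seed_determinism(self, traj_scheme):
        traj, scheme = traj_scheme
        a = sample_channel_noise(traj, scheme, seed=7)
        b = sample_channel_noise(traj, scheme, seed=7)
        np.testing.assert_array_equal(a.current, b.current)
        c = sample_channel_noise(traj, scheme, seed=8)
        assert not np.array_equal(a.current, c.current)

    def test_mean_peak_matches_deterministic(self, traj_scheme):
        traj, scheme = traj_scheme
        det = current_from_occupancy(traj, scheme, n_channels=20_000)
        det_peak = np.abs(det.current).max()
        i_pk = int(np.argmax(np.abs(det.current)))
        p_pk = np.abs(det.current[i_pk]) / 20_000
        draws = [
            np.abs(sample_channel_noise(traj, scheme, seed=s).current[i_pk])
            for s in range(100)
        ]
        se = np.sqrt(p_pk * (1 - p_pk) * 20_000) / np.sqrt(100)
        assert abs(np.mean(draws) - det_peak) < 3 * se + 1e-9

    def test_zero_probability_zero_variance(self, traj_scheme):
        traj, scheme = traj_scheme
        zeroed = traj.probabilities.copy()
        zeroed[:, scheme.conducting_mask] = 0.0
        zeroed /= zeroed.sum(axis=1, keepdims=True)
        from gabakin.simulate import OccupancyTrajectory

        flat = OccupancyTrajectory(traj.times, zeroed, traj.labels)
        trace = sample_channel_noise(flat, scheme, seed=3)
        assert np.abs(trace.current).max() == 0.0


def test_trace_length_mismatch_rejected():
    with pytest.raises(ValueError):
        CurrentTrace(times=np.arange(5.0), current=np.arange(4.0))


def test_protocol_validation():
    with pytest.raises(ValueError):
        AgonistProtocol(segments=())
    with pytest.raises(ValueError):
        AgonistProtocol(segments=((0.0, 0.01),))
    with pytest.raises(ValueError):
        AgonistProtocol(dt=-1.0)
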