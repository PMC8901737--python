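import dataclasses

import numpy as np
import pytest

import pelvimon as pm
from pelvimon.errors import DomainError, NormalizationError, ValidationError
from pelvimon.stimulation import ProtocolPhase
from pelvimon.trace_analysis import flag_artifacts, physiological_slope_limit, with_artifact_mask


def _trace(u_volts: np.ndarray, rate: float = 100.0) -> pm.ImpedanceTrace:
    t = np.arange(len(u_volts)) / rate
    return pm.ImpedanceTrace(time_s=t, U_v=u_volts, version="v2", config=pm.ChainConfig())


def _norm(u: np.ndarray, sigma: float = 1e-3, rate: float = 100.0):
    from pelvimon.trace_analysis import NormalizedTrace
    t = np.arange(len(u)) / rate
    return NormalizedTrace(time_s=t, u=u, baseline_window_s=(0.0, 5.0),
                           U0_v=4.0, noise_sigma=sigma)


class TestNormalize:
    def test_constant_trace_normalizes_to_one(self):
        tr = _trace(np.full(2000, 4.2))
        norm = pm.normalize(tr, (1.0, 5.0))
        assert np.allclose(norm.u, 1.0)
        assert norm.U0_v == pytest.approx(4.2)

    def test_gain_invariance(self):
        """u is unchanged when every U sample is rescaled (e.g. 2x dc_gain)."""
        rng = np.random.default_rng(0)
        u_v = 4.0 + 0.001 * rng.standard_normal(3000)
        n1 = pm.normalize(_trace(u_v), (1.0, 5.0))
        n2 = pm.normalize(_trace(2.0 * u_v), (1.0, 5.0))
        assert np.allclose(n1.u, n2.u, rtol=0, atol=1e-15)

    def test_baseline_below_noise_floor_rejected(self):
        rng = np.random.default_rng(1)
        tr = _trace(0.001 + 0.01 * rng.standard_normal(2000))
        with pytest.raises(NormalizationError):
            pm.normalize(tr, (1.0, 5.0))

    def test_window_inside_settling_rejected(self):
        tr = _trace(np.full(2000, 4.0))
        with pytest.raises(ValidationError):
            pm.normalize(tr, (0.1, 5.0))   # settling is 3/5 Hz = 0.6 s


class TestManometry:
    def test_filled_bladder_tracks_contraction(self, reference_result):
        res = reference_result
        mano = res.manometry
        assert mano.fill_volume_ml == 150.0
        m = mano.time_s >= 2.0
        u = np.interp(mano.time_s[m], res.norm.time_s, res.norm.u)
        assert np.corrcoef(u, mano.p_norm[m])[0, 1] > 0.95

    def test_empty_bladder_shows_nothing_while_impedance_does(self, reference_result):
        state = reference_result.state
        mano = pm.manometry_model(state, fill_volume_ml=0.0, noise_rms=0.003, seed=2)
        assert np.std(mano.p_norm) == pytest.approx(0.003, rel=0.1)  # noise only
        assert abs(np.mean(mano.p_norm) - 1.0) < 1e-3
        assert reference_result.norm.u.max() > 1.02   # impedance channel responds

    def test_no_contraction_gives_flat_pressure(self):
        rest = pm.StimulationProtocol((ProtocolPhase("rest", 20.0),))
        state = pm.simulate_contraction(rest, seed=0)
        mano = pm.manometry_model(state, fill_volume_ml=150.0, noise_rms=0.0, seed=0)
        assert np.all(mano.p_norm == 1.0)

    def test_negative_volume_rejected(self, reference_result):
        with pytest.raises(DomainError):
            pm.manometry_model(reference_result.state, fill_volume_ml=-1.0)


class TestPhaseMetrics:
    def test_flat_trace_has_zero_delta(self):
        proto = pm.default_protocol(n_cycles=2, stim_s=2.0, rest_s=3.0)
        norm = _norm(np.ones(1100))
        summary = pm.phase_metrics(norm, proto)
        assert [p.delta_u for p in summary.phases] == [0.0, 0.0]
        assert summary.frequency_hz == 30.0

    def test_trace_shorter_than_protocol_rejected(self):
        proto = pm.default_protocol()
        with pytest.raises(ValidationError):
            pm.phase_metrics(_norm(np.ones(100)), proto)


class TestConditionStats:
    def test_single_value(self):
        s = pm.condition_stats([2.5])
        assert s.n == 1
        assert s.mean == s.median == 2.5
        assert s.q3 - s.q1 == 0.0

    def test_linear_interpolation_quartiles(self):
        """{1,2,3,4}: median 2.5, q1 1.75, q3 3.25 (hand-computed)."""
        s = pm.condition_stats([1.0, 2.0, 3.0, 4.0])
        assert s.median == pytest.approx(2.5)
        assert s.q1 == pytest.approx(1.75)
        assert s.q3 == pytest.approx(3.25)

    def test_tukey_whiskers_and_outliers(self):
        s = pm.condition_stats([1.0, 2.0, 3.0, 4.0, 100.0])
        assert s.outliers == (100.0,)
        assert s.whisker_high == 4.0     # clamped to observed data
        assert s.whisker_low == 1.0

    def test_empty_rejected(self):
        with pytest.raises(DomainError):
            pm.condition_stats([])


class TestDetection:
    def test_flat_noisy_trace_has_no_events(self):
        rng = np.random.default_rng(3)
        u = 1.0 + 1e-3 * rng.standard_normal(45000)
        assert pm.detect_contraction(_norm(u, sigma=1e-3)) == []

    def test_single_sustained_bump_detected(self):
        u = np.ones(6000)
        u[2000:3000] += 0.03    # 10 s bump at 100 Hz
        events = pm.detect_contraction(_norm(u, sigma=1e-3))
        assert len(events) == 1
        assert events[0].start_s == pytest.approx(20.0, abs=0.1)
        assert events[0].peak_u == pytest.approx(1.03)

    def test_brief_flicker_ignored(self):
        u = np.ones(6000)
        u[2000:2100] += 0.03    # 1 s < min_duration
        assert pm.detect_contraction(_norm(u, sigma=1e-3)) == []

    def test_noise_dip_does_not_split_event(self):
        u = np.ones(6000)
        u[2000:4000] += 0.03
        u[2950:3000] = 1.0 + 0.0025   # dip to 2.5 sigma, above release level
        events = pm.detect_contraction(_norm(u, sigma=1e-3))
        assert len(events) == 1

    def test_min_delta_suppresses_self_activity_band(self):
        u = np.ones(6000)
        u[2000:4000] += 0.004   # below a 0.006 floor but above 5 sigma
        assert pm.detect_contraction(_norm(u, sigma=1e-4), min_delta=0.006) == []


class TestArtifacts:
    def test_clean_simulation_unflagged_after_settling(self, reference_result):
        mask = reference_result.trace.artifact_mask
        settled = reference_result.trace.time_s > 1.0
        assert not np.any(mask[settled])

    def test_injected_step_flagged_locally(self, reference_result):
        tr = reference_result.trace
        u = tr.U_v.copy()
        i_step = np.searchsorted(tr.time_s, 100.0)   # during rest
        u[i_step:] += 0.5                             # electrode bump
        stepped = dataclasses.replace(tr, U_v=u, artifact_mask=None)
        limit = physiological_slope_limit(reference_result.norm.U0_v)
        mask = flag_artifacts(stepped, limit)
        assert mask[i_step]
        assert not mask[i_step - 200]                 # 2 s earlier untouched
        assert not np.any(mask[np.searchsorted(tr.time_s, 160.0):])

    def test_rest_step_does_not_corrupt_peak_metrics(self, reference_result):
        """A flagged artifact during rest leaves stimulation metrics intact."""
        res = reference_result
        tr = res.trace
        u = tr.U_v.copy()
        i0 = np.searchsorted(tr.time_s, 100.0)
        i1 = np.searchsorted(tr.time_s, 101.0)
        u[i0:i1] += 0.5                               # transient bump in rest
        stepped = dataclasses.replace(tr, U_v=u, artifact_mask=None)
        limit = physiological_slope_limit(res.norm.U0_v)
        stepped = with_artifact_mask(stepped, flag_artifacts(stepped, limit))
        norm = pm.normalize(stepped, res.norm.baseline_window_s)
        summary = pm.phase_metrics(norm, res.protocol)
        clean = [p.peak_u for p in res.summary.phases]
        dirty = [p.peak_u for p in summary.phases]
        assert dirty == pytest.approx(clean, rel=1e-9)
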