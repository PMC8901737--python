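import dataclasses

import numpy as np
import pytest

import pelvimon as pm
from pelvimon.errors import DomainError
from pelvimon.stimulation import ProtocolPhase


class TestRecruitment:
    def test_subthreshold_is_zero(self):
        assert pm.recruitment_fraction(3.0, 30.0) == 0.0
        assert pm.recruitment_fraction(5.0, 30.0) == 0.0   # at threshold

    def test_frequency_ordering_matches_observed(self):
        """30 Hz recruits best, 10 Hz second, 50 Hz worst."""
        r30 = pm.recruitment_fraction(15.0, 30.0)
        r10 = pm.recruitment_fraction(15.0, 10.0)
        r50 = pm.recruitment_fraction(15.0, 50.0)
        assert r30 > r10 > r50 > 0.0

    def test_unimodal_tuning_single_maximum(self):
        f = np.arange(5.0, 101.0, 1.0)
        r = np.array([pm.recruitment_fraction(15.0, fi) for fi in f])
        d = np.sign(np.diff(r))
        # exactly one sign change + -> -: one interior local maximum
        changes = np.sum((d[:-1] > 0) & (d[1:] < 0))
        assert changes == 1
        assert f[np.argmax(r)] == 30.0

    def test_monotone_in_amplitude(self):
        amps = np.linspace(0.0, 60.0, 121)
        r = np.array([pm.recruitment_fraction(a, 30.0) for a in amps])
        assert np.all(np.diff(r) >= 0)
        assert r.max() <= 1.0

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            pm.recruitment_fraction(-1.0, 30.0)
        with pytest.raises(DomainError):
            pm.recruitment_fraction(15.0, 0.0)


class TestContractionDynamics:
    def test_full_rest_restores_peaks_within_two_percent(self):
        state = pm.simulate_contraction(pm.default_protocol(), seed=1)
        peaks = _phase_peaks(state, pm.default_protocol())
        assert all(abs(p / peaks[0] - 1.0) < 0.02 for p in peaks)

    def test_short_rest_reduces_successive_peaks(self):
        proto = pm.default_protocol(rest_s=30.0)
        peaks = _phase_peaks(pm.simulate_contraction(proto, seed=1), proto)
        assert peaks[1] / peaks[0] < 0.95
        assert peaks[2] < peaks[1]

    def test_cut_nerve_abolishes_bladder_response(self):
        cfg = pm.ContractionConfig(nerve_intact=False, organ="bladder")
        state = pm.simulate_contraction(pm.default_protocol(), config=cfg, seed=1)
        assert np.all(state.c == 0.0)

    def test_vecuronium_bit_identical(self):
        """A skeletal relaxant does not touch smooth-muscle dynamics."""
        proto = pm.default_protocol()
        a = pm.simulate_contraction(proto, config=pm.ContractionConfig(vecuronium=False),
                                    seed=5)
        b = pm.simulate_contraction(proto, config=pm.ContractionConfig(vecuronium=True),
                                    seed=5)
        assert np.array_equal(a.c, b.c)
        assert np.array_equal(a.q, b.q)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_state_bounds_and_zero_start(self, seed):
        cfg = pm.ContractionConfig(organ="rectum")
        state = pm.simulate_contraction(pm.default_protocol(), config=cfg, seed=seed)
        assert state.c[0] == 0.0
        assert np.all((state.c >= 0) & (state.c <= 1))
        assert np.all((state.q >= 0) & (state.q <= 1))

    def test_rectal_self_activity_bounded_without_stimulation(self):
        rest_only = pm.StimulationProtocol((ProtocolPhase("rest", 60.0),))
        cfg = pm.ContractionConfig(organ="rectum", self_activity_amplitude=0.07)
        state = pm.simulate_contraction(rest_only, config=cfg, seed=3)
        assert np.max(state.c) <= 0.07 + 1e-12
        assert np.min(state.c) >= 0.0


class TestTissueImpedance:
    def test_baseline_matches_closed_form_exactly(self):
        model = pm.TissueElectricalModel()
        omega = 2 * np.pi * 1007.0
        zp = model.membrane_resistance_ohm / (
            1 + 1j * omega * model.membrane_resistance_ohm * model.membrane_capacitance_f
        )
        expected = model.baseline_resistance_ohm + zp
        assert model.impedance(1007.0, 0.0) == pytest.approx(expected, rel=1e-15)

    def test_relaxed_state_gives_constant_baseline_trace(self):
        rest = pm.StimulationProtocol((ProtocolPhase("rest", 10.0),))
        state = pm.simulate_contraction(rest, seed=0)
        tr = pm.impedance_trace(state, pm.TissueElectricalModel(),
                                pm.SETUP_REGISTRY["bladder_setup2"], 1007.0)
        assert np.all(tr.z == tr.z[0])

    def test_zero_coverage_hides_contraction(self):
        """The muscle contracts but the electrodes do not see it."""
        state = pm.simulate_contraction(pm.default_protocol(), seed=1)
        assert state.c.max() > 0.2
        setup = dataclasses.replace(pm.SETUP_REGISTRY["bladder_setup2"], coverage=0.0)
        tr = pm.impedance_trace(state, pm.TissueElectricalModel(), setup, 1007.0)
        assert np.ptp(tr.magnitude) == 0.0

    def test_magnitude_nondecreasing_in_activation(self):
        model = pm.TissueElectricalModel()
        c = np.linspace(0, 1, 101)
        mag = np.abs(model.impedance(1007.0, c))
        assert np.all(np.diff(mag) >= 0)

    def test_phase_stays_capacitive(self):
        model = pm.TissueElectricalModel()
        c = np.linspace(0, 1, 11)
        ph = np.degrees(np.angle(model.impedance(1007.0, c)))
        assert np.all(ph > -90) and np.all(ph <= 0)

    def test_equal_couplings_scale_impedance_exactly(self):
        """With equal resistive/capacitive couplings k the whole circuit
        scales by (1 + k*g*c): doubling k doubles the relative change."""
        m1 = pm.TissueElectricalModel(coupling_resistive=0.1, coupling_capacitive=0.1)
        m2 = pm.TissueElectricalModel(coupling_resistive=0.2, coupling_capacitive=0.2)
        z0 = abs(m1.impedance(1007.0, 0.0))
        d1 = abs(m1.impedance(1007.0, 1.0)) / z0 - 1.0
        d2 = abs(m2.impedance(1007.0, 1.0)) / z0 - 1.0
        assert d1 == pytest.approx(0.1, rel=1e-12)
        assert d2 == pytest.approx(2 * d1, rel=1e-12)

    def test_bipolar_adds_contact_impedance(self):
        state = pm.simulate_contraction(
            pm.StimulationProtocol((ProtocolPhase("rest", 5.0),)), seed=0)
        model = pm.TissueElectricalModel()
        four = pm.ElectrodeSetup(version="four_electrode", contact_impedance_ohm=100.0)
        two = pm.ElectrodeSetup(version="two_electrode", contact_impedance_ohm=100.0)
        z4 = pm.impedance_trace(state, model, four, 1007.0).z[0]
        z2 = pm.impedance_trace(state, model, two, 1007.0).z[0]
        assert z2 == pytest.approx(z4 + 200.0)


def _phase_peaks(state: pm.ContractionState, proto: pm.StimulationProtocol):
    peaks = []
    for start, end, _ in proto.stim_windows():
        m = (state.time_s >= start) & (state.time_s <= end + 5.0)
        peaks.append(state.c[m].max())
    return peaks
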