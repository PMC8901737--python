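"""Smooth-muscle contraction dynamics and the tissue equivalent circuit.

Autonomic efferents recruited by a stimulation pulse train drive a slow,
seconds-scale contraction of the visceral smooth muscle (the "slow wave"
response, as opposed to the millisecond CMAP of skeletal muscle).  The
contraction changes the geometry of the tissue between the measurement
electrodes — fluid spaces narrow, the layered structure of dense bodies and
connective tissue compresses — which alters both the resistive and the
capacitive properties of the tissue.  The organ is modelled electrically as
a Fricke-type equivalent circuit (series resistance plus a parallel RC
membrane branch) whose elements are modulated by the activation state, so
contraction raises the impedance magnitude seen at the carrier frequency.

Activation dynamics
-------------------
Activation ``c(t)`` in [0, 1] follows first-order kinetics: during
stimulation it relaxes exponentially toward the drive ``r * q`` with time
constant ``tau_act``; during rest it decays with ``tau_rel``.  ``r`` is the
recruitment fraction of the pulse train and ``q`` in [0, 1] a recovery pool
(contractile capability) that depletes while the muscle is contracted and is
replenished, at rate proportional to how relaxed the muscle is, with time
constant ``tau_recover``.  The pool reproduces the observed memory effect:
after a full two-minute rest the next contraction reaches the previous peak,
whereas restimulation before complete relaxation falls measurably short.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .errors import DomainError, ValidationError
from .stimulation import StimulationProtocol

ORGANS = ("bladder", "rectum")


# ---------------------------------------------------------------------------
# recruitment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RecruitmentParams:
    """Amplitude/frequency tuning of nerve-fiber recruitment.

    The recruited fraction is zero below ``threshold_current_ma``, grows
    linearly to 1 at ``saturation_current_ma``, and is modulated by a
    unimodal frequency tuning centred at ``freq_peak_hz``.  The tuning is a
    two-sided Gaussian whose high-frequency side is narrower (width
    ``freq_bandwidth_hz * high_side_ratio``): autonomic fibers follow
    moderate pulse rates well but fail to sustain transmission at high
    rates, so efficacy falls off faster above the peak than below it.
    With the defaults, 30 Hz recruits more than 10 Hz, which recruits more
    than 50 Hz.
    """

    threshold_current_ma: float = 5.0
    saturation_current_ma: float = 30.0
    freq_peak_hz: float = 30.0
    freq_bandwidth_hz: float = 20.0
    high_side_ratio: float = 0.5

    def __post_init__(self) -> None:
        if self.threshold_current_ma < 0:
            raise DomainError("threshold current must be >= 0")
        if self.saturation_current_ma <= self.threshold_current_ma:
            raise DomainError("saturation current must exceed the threshold")
        if self.freq_peak_hz <= 0 or self.freq_bandwidth_hz <= 0:
            raise DomainError("frequency tuning parameters must be positive")
        if not 0 < self.high_side_ratio <= 1:
            raise DomainError("high_side_ratio must be in (0, 1]")


def recruitment_fraction(
    amplitude_ma: float, frequency_hz: float, params: RecruitmentParams | None = None
) -> float:
    """Fraction of excitable fibers activated by a pulse train.

    Zero below the excitation threshold, monotone non-decreasing in
    amplitude up to saturation, unimodal in frequency with its maximum at
    ``params.freq_peak_hz``.
    """
    params = params or RecruitmentParams()
    if amplitude_ma < 0:
        raise DomainError("stimulation amplitude must be >= 0 mA")
    if frequency_hz <= 0:
        raise DomainError("stimulation frequency must be > 0 Hz")
    if amplitude_ma <= params.threshold_current_ma:
        return 0.0
    amp = min(
        (amplitude_ma - params.threshold_current_ma)
        / (params.saturation_current_ma - params.threshold_current_ma),
        1.0,
    )
    df = frequency_hz - params.freq_peak_hz
    sigma = params.freq_bandwidth_hz
    if df > 0:
        sigma *= params.high_side_ratio
    tune = float(np.exp(-0.5 * (df / sigma) ** 2))
    return amp * tune


# ---------------------------------------------------------------------------
# contraction simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContractionConfig:
    """Kinetic parameters and flags of the contraction simulator.

    Time constants (seconds): ``tau_act`` activation rise, ``tau_rel``
    passive relaxation, ``tau_recover`` recovery-pool replenishment (gated
    by relaxation), ``tau_deplete`` pool depletion while contracted.  The
    defaults are set so that a 120 s rest restores at least 98% of the
    previous peak while a 30 s rest leaves the next peak below 95% of it.

    ``self_activity_amplitude`` adds a bounded sinusoidal spontaneous
    activity (rectum only; the bladder shows none), with seeded random
    phase.  ``nerve_intact=False`` models a transected nerve: the
    stimulated component of ``c`` is identically zero.  ``vecuronium`` is a
    skeletal-muscle relaxant flag carried for protocol bookkeeping; smooth
    muscle is unaffected, so it changes nothing in the dynamics.
    """

    tau_act_s: float = 10.0
    tau_rel_s: float = 30.0
    tau_recover_s: float = 40.0
    tau_deplete_s: float = 70.0
    organ: str = "bladder"
    self_activity_amplitude: float = 0.07
    self_activity_freq_hz: float = 0.1
    nerve_intact: bool = True
    vecuronium: bool = False

    def __post_init__(self) -> None:
        for name in ("tau_act_s", "tau_rel_s", "tau_recover_s", "tau_deplete_s"):
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be positive")
        if self.organ not in ORGANS:
            raise ValidationError(f"organ must be one of {ORGANS}")
        if not 0 <= self.self_activity_amplitude < 1:
            raise DomainError("self-activity amplitude must be in [0, 1)")
        if self.self_activity_freq_hz <= 0:
            raise DomainError("self-activity frequency must be positive")


@dataclass(frozen=True)
class ContractionState:
    """Simulated activation trajectory.

    ``c`` is the total activation (stimulated component plus, for the
    rectum, spontaneous self-activity), ``q`` the recovery pool, both in
    [0, 1] on ``time_s``.
    """

    time_s: np.ndarray
    c: np.ndarray
    q: np.ndarray
    config: ContractionConfig

    @property
    def organ(self) -> str:
        return self.config.organ


def simulate_contraction(
    protocol: StimulationProtocol,
    recruit: RecruitmentParams | None = None,
    config: ContractionConfig | None = None,
    control_rate_hz: float = 100.0,
    seed: int = 0,
) -> ContractionState:
    """Integrate the activation dynamics over a stimulation protocol.

    Exact exponential updates on a fixed control grid (default 100 Hz); the
    system is piecewise first-order, so the update is stiff-free and
    deterministic.  Randomness (the self-activity phase) is drawn from
    ``seed`` regardless of organ so that traces for different organs at the
    same seed stay stream-aligned.
    """
    recruit = recruit or RecruitmentParams()
    config = config or ContractionConfig()
    if control_rate_hz < 10.0:
        raise DomainError("control rate must be >= 10 Hz")
    protocol.validate()

    dt = 1.0 / control_rate_hz
    n = int(round(protocol.total_duration_s * control_rate_hz))
    t = np.arange(n) / control_rate_hz

    # per-sample drive r for the active train (0 in rest / cut nerve)
    drive = np.zeros(n)
    if config.nerve_intact:
        for start, end, train in protocol.stim_windows():
            r = recruitment_fraction(train.amplitude_ma, train.frequency_hz, recruit)
            r *= train.site_multiplier
            i0, i1 = int(round(start * control_rate_hz)), int(round(end * control_rate_hz))
            drive[i0:i1] = r
    stim_on = np.zeros(n, dtype=bool)
    for start, end, _ in protocol.stim_windows():
        stim_on[int(round(start * control_rate_hz)) : int(round(end * control_rate_hz))] = True

    ea = np.exp(-dt / config.tau_act_s)
    er = np.exp(-dt / config.tau_rel_s)
    c = np.empty(n)
    q = np.empty(n)
    ci, qi = 0.0, 1.0
    inv_dep = dt / config.tau_deplete_s
    inv_rec = dt / config.tau_recover_s
    for i in range(n):
        c[i], q[i] = ci, qi
        if stim_on[i]:
            target = drive[i] * qi
            ci = target + (ci - target) * ea
        else:
            ci = ci * er
        qi = qi * np.exp(-ci * inv_dep)
        qi = qi + (1.0 - qi) * (1.0 - np.exp(-(1.0 - ci) * inv_rec))

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    phase = rng.uniform(0.0, 2.0 * np.pi)  # drawn for every organ (stream stability)
    if config.organ == "rectum" and config.self_activity_amplitude > 0:
        sa = 0.5 * config.self_activity_amplitude * (
            1.0 - np.cos(2.0 * np.pi * config.self_activity_freq_hz * t + phase)
        )
        # soft start over half a self-activity period: the pre-recording
        # reference state is exactly baseline (c(0) = 0) for every seed
        ramp_tau = 0.5 / config.self_activity_freq_hz
        sa *= -np.expm1(-t / ramp_tau)
        c = np.clip(c + sa, 0.0, 1.0)

    return ContractionState(time_s=t, c=c, q=q, config=config)


# ---------------------------------------------------------------------------
# tissue electrical model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TissueElectricalModel:
    """Fricke-type equivalent circuit of the organ between the electrodes.

    A series (extracellular) resistance ``baseline_resistance_ohm`` in
    series with a parallel branch of ``membrane_resistance_ohm`` and
    ``membrane_capacitance_f`` (cell membranes).  Contraction scales the
    resistive elements by ``(1 + coupling_resistive * g * c)`` and the
    capacitive reactance by ``(1 + coupling_capacitive * g * c)`` (i.e. the
    capacitance shrinks), where ``g`` is the electrode coverage fraction.
    With equal couplings the whole impedance scales by that factor, so the
    default couplings of 0.1 give a +10% magnitude change at full
    contraction under full coverage.
    """

    baseline_resistance_ohm: float = 150.0
    membrane_resistance_ohm: float = 200.0
    membrane_capacitance_f: float = 0.5e-6
    coupling_resistive: float = 0.10
    coupling_capacitive: float = 0.10
    organ: str = "bladder"

    def __post_init__(self) -> None:
        if self.baseline_resistance_ohm <= 0 or self.membrane_resistance_ohm <= 0:
            raise DomainError("circuit resistances must be positive")
        if self.membrane_capacitance_f <= 0:
            raise DomainError("membrane capacitance must be positive")
        if self.coupling_resistive < 0 or self.coupling_capacitive < 0:
            raise DomainError("couplings must be >= 0 (contraction raises impedance)")
        if self.organ not in ORGANS:
            raise ValidationError(f"organ must be one of {ORGANS}")

    def impedance(self, carrier_freq_hz: float, c: np.ndarray | float = 0.0,
                  coverage: float = 1.0) -> np.ndarray:
        """Complex impedance at the carrier for activation ``c`` (vectorized)."""
        if carrier_freq_hz <= 0:
            raise DomainError("carrier frequency must be positive")
        c = np.asarray(c, dtype=float)
        fr = 1.0 + self.coupling_resistive * coverage * c
        fc = 1.0 + self.coupling_capacitive * coverage * c
        rs = self.baseline_resistance_ohm * fr
        rm = self.membrane_resistance_ohm * fr
        cm = self.membrane_capacitance_f / fc
        omega = 2.0 * np.pi * carrier_freq_hz
        zp = rm / (1.0 + 1j * omega * rm * cm)
        return rs + zp


@dataclass(frozen=True)
class ElectrodeSetup:
    """Electrode configuration for impedance measurement on one organ.

    ``four_electrode`` (tetrapolar, hardware version one) separates current
    injection from voltage sensing, so electrode contact impedance cancels;
    ``two_electrode`` (bipolar, version two) shares electrodes between both
    roles and the measured impedance includes twice the contact impedance
    as a contraction-independent series term.  ``coverage`` is the fraction
    of the contractile muscle lying between the measurement electrodes:
    the observable impedance change scales linearly with it, and zero
    coverage hides the contraction entirely even though the muscle
    contracts.  ``coverage_cv`` is the inter-individual variability of the
    effective coverage used by cohort simulations (placement differs
    between animals).
    """

    organ: str = "bladder"
    version: str = "four_electrode"
    setup_id: str = "bladder_setup2"
    coverage: float = 0.9
    contact_impedance_ohm: float = 100.0
    coverage_cv: float = 0.10

    def __post_init__(self) -> None:
        if self.organ not in ORGANS:
            raise ValidationError(f"organ must be one of {ORGANS}")
        if self.version not in ("four_electrode", "two_electrode"):
            raise ValidationError("version must be 'four_electrode' or 'two_electrode'")
        if not 0.0 <= self.coverage <= 1.0:
            raise DomainError("coverage must be in [0, 1]")
        if self.contact_impedance_ohm < 0:
            raise DomainError("contact impedance must be >= 0")
        if self.coverage_cv < 0:
            raise DomainError("coverage_cv must be >= 0")


#: The five electrode positioning setups evaluated in the porcine study.
#: Coverage and its spread are qualitative emulation choices: needle-only
#: placements are steadier (low spread) than mixed surface/needle ones.
SETUP_REGISTRY: dict[str, ElectrodeSetup] = {
    "bladder_setup1": ElectrodeSetup("bladder", "four_electrode", "bladder_setup1",
                                     coverage=0.95, coverage_cv=0.35),
    "bladder_setup2": ElectrodeSetup("bladder", "four_electrode", "bladder_setup2",
                                     coverage=0.90, coverage_cv=0.10),
    "rectum_setup1": ElectrodeSetup("rectum", "four_electrode", "rectum_setup1",
                                    coverage=0.85, coverage_cv=0.15),
    "rectum_setup2": ElectrodeSetup("rectum", "four_electrode", "rectum_setup2",
                                    coverage=0.90, coverage_cv=0.30),
    "rectum_setup3": ElectrodeSetup("rectum", "four_electrode", "rectum_setup3",
                                    coverage=0.80, coverage_cv=0.15),
}


@dataclass(frozen=True)
class TissueImpedanceTrace:
    """Complex tissue impedance per sample on the contraction control grid."""

    time_s: np.ndarray
    z: np.ndarray  # complex ohms

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.z)

    @property
    def phase_deg(self) -> np.ndarray:
        return np.degrees(np.angle(self.z))


def impedance_trace(
    state: ContractionState,
    model: TissueElectricalModel,
    setup: ElectrodeSetup,
    carrier_freq_hz: float,
) -> TissueImpedanceTrace:
    """Map a contraction trajectory to the measured complex impedance.

    Bipolar (two-electrode) measurements add twice the contact impedance as
    a purely resistive, contraction-independent series term.
    """
    z = model.impedance(carrier_freq_hz, state.c, setup.coverage)
    if setup.version == "two_electrode":
        z = z + 2.0 * setup.contact_impedance_ohm
    return TissueImpedanceTrace(time_s=state.time_s, z=np.asarray(z))
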