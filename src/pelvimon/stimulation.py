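"""Constant-current nerve stimulator: pulse trains, sites, and timed protocols.

The stimulator delivers monophasic rectangular current pulses (10-50 mA,
1000 us, 10-50 Hz in routine use; 100 mA compliance limit).  Stimulation is
applied either at fixed anatomical landmarks close to the target organ
(vesicouterine ligament for the bladder, paraproctium for the rectum, via a
permanently placed Saxophone electrode) or with a handheld probe on the
hypogastric plexus.  A protocol is an ordered sequence of stimulation and
rest phases; the reference protocol is three repetitions of 30 s stimulation
followed by 120 s relaxation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import DomainError, ResolutionError, ValidationError

#: Relative recruitment efficacy of each stimulation site.  Fixed Saxophone
#: sites and direct organ stimulation give steady, full-efficacy conditions;
#: the handheld plexus probe is position-dependent (configurable in (0, 1]);
#: the wound margin contains no efferent fibers and is the negative control.
SITE_MULTIPLIERS: dict[str, float] = {
    "vesicouterine_ligament": 1.0,
    "paraproctium": 1.0,
    "hypogastric_plexus": 0.8,
    "detrusor_direct": 1.0,
    "rectum_direct": 1.0,
    "wound_margin": 0.0,
}

STIMULATION_SITES = tuple(SITE_MULTIPLIERS)

#: Stimulator compliance limit (mA).
MAX_AMPLITUDE_MA = 100.0


@dataclass(frozen=True)
class StimulusTrain:
    """A monophasic rectangular pulse train.

    Parameters
    ----------
    amplitude_ma : float
        Pulse current in mA, 0 < amplitude <= 100 (stimulator compliance).
    pulse_width_us : float
        Pulse width in microseconds (default 1000).
    frequency_hz : float
        Pulse repetition rate in Hz.
    duration_s : float
        Train duration in seconds.
    site : str
        Stimulation site label, one of :data:`STIMULATION_SITES`.
    """

    amplitude_ma: float
    pulse_width_us: float = 1000.0
    frequency_hz: float = 30.0
    duration_s: float = 30.0
    site: str = "vesicouterine_ligament"

    def __post_init__(self) -> None:
        if not 0.0 <= self.amplitude_ma <= MAX_AMPLITUDE_MA:
            raise DomainError(
                f"amplitude must be in [0, {MAX_AMPLITUDE_MA}] mA (0 = stimulator off), "
                f"got {self.amplitude_ma}"
            )
        if self.pulse_width_us <= 0:
            raise DomainError("pulse width must be positive")
        if self.frequency_hz <= 0:
            raise DomainError("pulse frequency must be positive")
        if self.duration_s <= 0:
            raise DomainError("train duration must be positive")
        # pulses must not overlap: period (us) must exceed the pulse width
        if self.frequency_hz * self.pulse_width_us >= 1e6:
            raise ValidationError(
                "pulse width times frequency exceeds one period: pulses overlap"
            )
        if self.site not in SITE_MULTIPLIERS:
            raise ValidationError(
                f"unknown site {self.site!r}; expected one of {STIMULATION_SITES}"
            )

    @property
    def duty_cycle(self) -> float:
        """Fraction of each period the current is on."""
        return self.frequency_hz * self.pulse_width_us * 1e-6

    @property
    def charge_per_pulse_nc(self) -> float:
        """Charge delivered per pulse in nanocoulombs (mA * us = nC)."""
        return self.amplitude_ma * self.pulse_width_us

    @property
    def site_multiplier(self) -> float:
        return SITE_MULTIPLIERS[self.site]


@dataclass(frozen=True)
class ProtocolPhase:
    kind: str  # "stim" | "rest"
    duration_s: float
    train: Optional[StimulusTrain] = None

    def __post_init__(self) -> None:
        if self.kind not in ("stim", "rest"):
            raise ValidationError(f"phase kind must be 'stim' or 'rest', got {self.kind!r}")
        if self.duration_s <= 0:
            raise ValidationError("phase duration must be positive")
        if self.kind == "stim" and self.train is None:
            raise ValidationError("stimulation phase requires a StimulusTrain")
        if self.kind == "rest" and self.train is not None:
            raise ValidationError("rest phase must not carry a StimulusTrain")
        if self.train is not None and abs(self.train.duration_s - self.duration_s) > 1e-9:
            raise ValidationError("train duration must match the phase duration")


@dataclass(frozen=True)
class StimulationProtocol:
    """Contiguous, non-overlapping sequence of stimulation and rest phases."""

    phases: tuple[ProtocolPhase, ...]

    def __post_init__(self) -> None:
        if not self.phases:
            raise ValidationError("protocol must contain at least one phase")
        object.__setattr__(self, "phases", tuple(self.phases))

    @property
    def total_duration_s(self) -> float:
        return float(sum(p.duration_s for p in self.phases))

    def phase_boundaries(self) -> list[tuple[str, float, float]]:
        """Return (kind, start_s, end_s) for each phase, contiguous from t=0."""
        out, t = [], 0.0
        for p in self.phases:
            out.append((p.kind, t, t + p.duration_s))
            t += p.duration_s
        return out

    def stim_windows(self) -> list[tuple[float, float, StimulusTrain]]:
        """Start/end times and train of every stimulation phase."""
        return [
            (a, b, p.train)
            for p, (_, a, b) in zip(self.phases, self.phase_boundaries())
            if p.kind == "stim"
        ]

    def validate(self) -> None:
        """Re-run structural validation (phases are validated on construction)."""
        for p in self.phases:
            ProtocolPhase(p.kind, p.duration_s, p.train)


def default_protocol(
    amplitude_ma: float = 15.0,
    frequency_hz: float = 30.0,
    pulse_width_us: float = 1000.0,
    n_cycles: int = 3,
    stim_s: float = 30.0,
    rest_s: float = 120.0,
    site: str = "vesicouterine_ligament",
) -> StimulationProtocol:
    """Reference protocol: three cycles of 30 s stimulation / 120 s relaxation.

    Defaults reproduce the standard test condition: 15 mA, 1000 us pulse
    width, 30 Hz at the vesicouterine ligament.
    """
    phases: list[ProtocolPhase] = []
    for _ in range(n_cycles):
        train = StimulusTrain(
            amplitude_ma=amplitude_ma,
            pulse_width_us=pulse_width_us,
            frequency_hz=frequency_hz,
            duration_s=stim_s,
            site=site,
        )
        phases.append(ProtocolPhase("stim", stim_s, train))
        phases.append(ProtocolPhase("rest", rest_s))
    return StimulationProtocol(tuple(phases))


def pulse_waveform(train: StimulusTrain, sample_rate: float) -> np.ndarray:
    """Sample a pulse train as a current waveform in mA.

    Pulse onsets are placed at multiples of the period (rounded to the sample
    grid) and each pulse is exactly ``round(width * fs)`` samples long, so
    charge per pulse is invariant to the sample rate within one sample's
    quantization.  The inter-pulse baseline is 0 mA (monophasic pulses, no
    charge balancing).
    """
    width_s = train.pulse_width_us * 1e-6
    if sample_rate < 10.0 / width_s:
        raise ResolutionError(
            f"sample rate {sample_rate} Hz gives fewer than 10 samples per "
            f"{train.pulse_width_us} us pulse"
        )
    n = int(round(train.duration_s * sample_rate))
    w = np.zeros(n)
    width_samples = int(round(width_s * sample_rate))
    period = sample_rate / train.frequency_hz
    n_pulses = int(np.floor(train.duration_s * train.frequency_hz))
    for k in range(n_pulses):
        start = int(round(k * period))
        if start >= n:
            break
        w[start : min(start + width_samples, n)] = train.amplitude_ma
    return w


def protocol_waveform(protocol: StimulationProtocol, sample_rate: float) -> np.ndarray:
    """Sampled stimulation current (mA) over the whole protocol, zeros in rest."""
    n_total = int(round(protocol.total_duration_s * sample_rate))
    w = np.zeros(n_total)
    offset = 0
    for p in protocol.phases:
        n = int(round(p.duration_s * sample_rate))
        if p.kind == "stim":
            w[offset : offset + n] = pulse_waveform(p.train, sample_rate)
        offset += n
    return w
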