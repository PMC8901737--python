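"""Measurement-chain front end: carrier synthesis, amplification, filtering.

A sine test current of 50 uA is driven through the tissue; the voltage drop
(the "measurement signal") is picked up differentially, amplified (gain 50)
and high-pass filtered (160 Hz) before lock-in demodulation.  This module
synthesizes the raw sampled voltage at the ADC-facing node of that chain
from a simulated impedance trajectory, including stimulation crosstalk and
seeded white measurement noise, and designs the chain's Butterworth filters.

The carrier frequency is not a physiological quantity; the default of
1007 Hz sits well above the 160 Hz high-pass cutoff, far above the 5 Hz
post-demodulation low-pass, and — being prime — off the harmonic grid of
the 10-50 Hz stimulation pulse trains.  The impedance varies on a seconds
scale, orders of magnitude slower than the carrier, so the synthesis uses
the quasi-static envelope ``v(t) = i_test * |Z(t)| * sin(w t + theta(t))``.

Filters are applied causally (forward only), matching analog hardware;
their settling transients are part of the signal and are excluded from
baseline windows downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import signal

from .errors import DomainError, FilterDesignError, ValidationError
from .tissue_sim import TissueImpedanceTrace


@dataclass(frozen=True)
class ChainConfig:
    """Parameters of the impedance measurement chain.

    Values stated on the hardware: 50 uA test current, preamp gain 50,
    160 Hz high-pass, 3rd-order 5 Hz low-pass after demodulation, DC gain
    11 into the ADC.  Carrier frequency, sample rate, ADC depth/range, the
    high-pass order, noise and crosstalk levels are instrument-typical
    documented defaults.
    """

    test_current_a: float = 50e-6
    carrier_freq_hz: float = 1007.0
    preamp_gain: float = 50.0
    hpf_cutoff_hz: float = 160.0
    hpf_order: int = 2
    lpf_cutoff_hz: float = 5.0
    lpf_order: int = 3
    dc_gain: float = 11.0
    sample_rate_hz: float = 20000.0
    adc_bits: int = 16
    adc_range_v: float = 5.0
    noise_rms_v: float = 0.15e-3
    crosstalk_coupling: float = 1e-4
    output_rate_hz: float = 100.0

    def __post_init__(self) -> None:
        if self.test_current_a <= 0:
            raise DomainError("test current must be positive")
        if self.carrier_freq_hz <= self.hpf_cutoff_hz:
            raise ValidationError("carrier must lie above the high-pass cutoff")
        if self.lpf_cutoff_hz >= self.carrier_freq_hz / 10.0:
            raise ValidationError("low-pass cutoff must be < carrier/10")
        if self.sample_rate_hz <= 10.0 * self.carrier_freq_hz:
            raise ValidationError("sample rate must exceed 10x the carrier frequency")
        if self.adc_bits < 2 or self.adc_range_v <= 0:
            raise DomainError("invalid ADC configuration")
        if self.noise_rms_v < 0 or self.crosstalk_coupling < 0:
            raise DomainError("noise and crosstalk levels must be >= 0")
        if self.output_rate_hz <= 2 * self.lpf_cutoff_hz * 2:
            raise ValidationError("output rate must comfortably exceed twice the LPF cutoff")

    @property
    def adc_lsb_v(self) -> float:
        return 2.0 * self.adc_range_v / (2 ** self.adc_bits)


def design_filters(config: ChainConfig) -> dict[str, np.ndarray]:
    """Butterworth designs of the chain filters as second-order sections.

    Returns ``{"hpf": sos, "lpf": sos}``; magnitude at each cutoff is -3 dB
    by construction of the Butterworth prototype.
    """
    nyq = config.sample_rate_hz / 2.0
    if config.hpf_cutoff_hz >= nyq or config.lpf_cutoff_hz >= nyq:
        raise FilterDesignError("filter cutoff at or above Nyquist")
    hpf = signal.butter(config.hpf_order, config.hpf_cutoff_hz,
                        btype="highpass", fs=config.sample_rate_hz, output="sos")
    lpf = signal.butter(config.lpf_order, config.lpf_cutoff_hz,
                        btype="lowpass", fs=config.sample_rate_hz, output="sos")
    return {"hpf": hpf, "lpf": lpf}


def filter_response(sos: np.ndarray, freq_hz: float, sample_rate_hz: float) -> complex:
    """Complex response of a SOS filter at a single frequency."""
    _, h = signal.sosfreqz(sos, worN=[freq_hz], fs=sample_rate_hz)
    return complex(h[0])


def chain_carrier_phase_deg(config: ChainConfig) -> float:
    """Phase added to the carrier by the high-pass filter (degrees).

    The causal 160 Hz high-pass leads the carrier slightly; the lock-in
    compensates this known, design-determined phase so that reported
    phases refer to the tissue.
    """
    hpf = design_filters(config)["hpf"]
    h = filter_response(hpf, config.carrier_freq_hz, config.sample_rate_hz)
    return float(np.degrees(np.angle(h)))


@dataclass(frozen=True)
class RawRecording:
    """Sampled voltage at the amplifier/high-pass output (lock-in input).

    ``chain_filtered`` records whether the samples passed through the
    preamp + high-pass chain (and therefore carry its known carrier phase
    shift) or are a bare synthetic carrier.
    """

    samples_v: np.ndarray
    sample_rate_hz: float
    t0_s: float = 0.0
    channel: str = "bladder"
    config: Optional[ChainConfig] = None
    seed: Optional[int] = None
    chain_filtered: bool = True

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.samples_v)):
            raise ValidationError("raw recording contains non-finite samples")

    @property
    def duration_s(self) -> float:
        return len(self.samples_v) / self.sample_rate_hz

    @property
    def time_s(self) -> np.ndarray:
        cached = getattr(self, "_time_s", None)
        if cached is None or len(cached) != len(self.samples_v):
            cached = self.t0_s + np.arange(len(self.samples_v)) / self.sample_rate_hz
            object.__setattr__(self, "_time_s", cached)
        return cached


def synthesize_raw(
    z_trace: TissueImpedanceTrace,
    config: ChainConfig,
    stim_waveform_ma: Optional[np.ndarray] = None,
    seed: int = 0,
    channel: str = "bladder",
) -> RawRecording:
    """Synthesize the raw lock-in input voltage from an impedance trajectory.

    The impedance trace (on its slow control grid) is interpolated to the
    chain sample rate; the input voltage is the quasi-static carrier plus
    optional stimulation crosstalk and seeded white Gaussian noise, then
    amplified and causally high-pass filtered:

    ``v = gain * HPF[ i_test * |Z(t)| * sin(w t + theta(t)) + leak + noise ]``

    Crosstalk couples the stimulation current into the input as
    ``crosstalk_coupling`` volts per mA.  ``stim_waveform_ma`` must be
    sampled at ``config.sample_rate_hz`` over the same duration as the
    impedance trace.
    """
    fs = config.sample_rate_hz
    n = int(round((z_trace.time_s[-1] + (z_trace.time_s[1] - z_trace.time_s[0])) * fs))
    t = np.arange(n) / fs
    zmag = np.interp(t, z_trace.time_s, z_trace.magnitude)

    if stim_waveform_ma is not None and len(stim_waveform_ma) != n:
        raise ValidationError(
            f"stimulation waveform length {len(stim_waveform_ma)} does not match "
            f"the {n}-sample raw grid at {fs} Hz"
        )
    # carrier with quasi-static envelope, built in place (long arrays)
    v_in = t * (2.0 * np.pi * config.carrier_freq_hz)
    v_in += np.interp(t, z_trace.time_s, np.angle(z_trace.z))
    np.sin(v_in, out=v_in)
    v_in *= zmag
    v_in *= config.test_current_a
    if stim_waveform_ma is not None and config.crosstalk_coupling > 0:
        v_in += config.crosstalk_coupling * stim_waveform_ma
    if config.noise_rms_v > 0:
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        v_in += config.noise_rms_v * rng.standard_normal(n)

    hpf = design_filters(config)["hpf"]
    v_out = config.preamp_gain * signal.sosfilt(hpf, v_in)
    return RawRecording(
        samples_v=v_out,
        sample_rate_hz=fs,
        channel=channel,
        config=config,
        seed=seed,
        chain_filtered=True,
    )


def synthetic_carrier(
    amplitude_v: float,
    phase_deg: float,
    config: ChainConfig,
    duration_s: float = 2.0,
    noise_rms_v: float = 0.0,
    seed: int = 0,
    channel: str = "bladder",
) -> RawRecording:
    """A bare sinusoidal carrier ``A sin(w t + theta)`` for bench tests.

    Bypasses the preamp/high-pass chain (``chain_filtered=False``), so the
    lock-in closed forms hold exactly.
    """
    n = int(round(duration_s * config.sample_rate_hz))
    t = np.arange(n) / config.sample_rate_hz
    v = amplitude_v * np.sin(
        2.0 * np.pi * config.carrier_freq_hz * t + np.radians(phase_deg)
    )
    if noise_rms_v > 0:
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        v = v + noise_rms_v * rng.standard_normal(n)
    return RawRecording(
        samples_v=v,
        sample_rate_hz=config.sample_rate_hz,
        channel=channel,
        config=config,
        seed=seed,
        chain_filtered=False,
    )
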