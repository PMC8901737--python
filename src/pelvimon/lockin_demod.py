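"""Lock-in demodulation, versions one and two.

Version one multiplies the measurement signal by a single sine reference
whose phase is adjusted (in hardware, a potentiometer; here, a grid-search
calibration) until measurement and reference are in phase, then integrates
through the 3rd-order 5 Hz low-pass and amplifies by the DC gain of 11.
Its displayed output is the in-phase component: for a carrier of amplitude
``A`` and phase ``theta``, steady state gives
``U = dc_gain * (A/2) * cos(theta - reference_phase)``.

Version two multiplies by a sine and a 90-degree-shifted cosine reference
(in hardware, alternating; here, continuous dual-branch by default, with an
optional chopped mode), demodulates and digitizes each branch, and adds the
two ADC outputs vectorially: ``U = dc_gain * A / 2`` independent of theta,
with the tissue phase recovered as ``phase_est = -theta`` (tissue phase is
negative/capacitive; the display convention reports the lag as positive).

For recordings that passed through the analog chain the demodulator offsets
its references by the chain's known carrier phase (the causal high-pass
adds a small design-determined lead), so reported phases refer to the
tissue.  Bare synthetic carriers are demodulated as-is and satisfy the
closed forms exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import signal

from .analog_frontend import ChainConfig, RawRecording, chain_carrier_phase_deg, design_filters
from .errors import CalibrationError

#: Settling time of the demodulation low-pass, as a multiple of 1/cutoff.
SETTLING_FACTOR = 3.0


@dataclass(frozen=True)
class ImpedanceTrace:
    """Demodulated, digitized neuromonitor output U(t), decimated for storage.

    ``U_v`` is proportional to the tissue impedance magnitude (v2) or its
    in-phase component (v1).  ``phase_deg`` (v2 only) is the estimated
    tissue phase lag, with ``phase_valid`` False where the magnitude is too
    small for the phase to mean anything.  ``artifact_mask``, if set, marks
    samples excluded from metrics.
    """

    time_s: np.ndarray
    U_v: np.ndarray
    version: str
    config: ChainConfig
    phase_deg: Optional[np.ndarray] = None
    phase_valid: Optional[np.ndarray] = None
    artifact_mask: Optional[np.ndarray] = None

    @property
    def sample_rate_hz(self) -> float:
        return 1.0 / (self.time_s[1] - self.time_s[0])

    @property
    def settling_time_s(self) -> float:
        return SETTLING_FACTOR / self.config.lpf_cutoff_hz


def _quantize(x: np.ndarray, config: ChainConfig) -> np.ndarray:
    lsb = config.adc_lsb_v
    r = config.adc_range_v
    return np.clip(np.round(x / lsb) * lsb, -r, r - lsb)


def _decimate(t: np.ndarray, x: np.ndarray, fs: float, out_rate: float):
    """Pick every fs/out_rate-th sample.  Post-LPF bandwidth (5 Hz) is far
    below the output Nyquist (50 Hz at the default 100 Hz), so plain
    subsampling does not alias."""
    step = max(int(round(fs / out_rate)), 1)
    return t[::step], x[::step]


def _reference_products(raw: RawRecording, config: ChainConfig,
                        extra_phase_deg: float, mode: str, chop_rate_hz: float,
                        need_q: bool = True):
    """Mixer products raw*sin (and raw*cos) with the chain phase folded in."""
    t = raw.time_s
    comp = chain_carrier_phase_deg(config) if raw.chain_filtered else 0.0
    ph = 2.0 * np.pi * config.carrier_freq_hz * t + np.radians(extra_phase_deg + comp)
    ref_sin = np.sin(ph)
    ref_cos = np.cos(ph) if need_q else None
    if mode == "chopped":
        # hardware-style alternation: each reference is active on alternate
        # chop half-periods; the factor 2 restores the duty-cycle loss.
        sel = (np.floor(t * chop_rate_hz).astype(np.int64) % 2) == 0
        ref_sin = np.where(sel, 2.0 * ref_sin, 0.0)
        if need_q:
            ref_cos = np.where(sel, 0.0, 2.0 * ref_cos)
    elif mode != "continuous":
        raise ValueError(f"unknown demodulation mode {mode!r}")
    prod_i = raw.samples_v * ref_sin
    prod_q = raw.samples_v * ref_cos if need_q else None
    return prod_i, prod_q


def demodulate_v1(
    raw: RawRecording,
    config: ChainConfig,
    reference_phase_deg: float = 0.0,
    adc: bool = True,
) -> ImpedanceTrace:
    """Single-reference lock-in with manual phase adjustment (version one).

    ``U(t) = ADC[ dc_gain * LPF( raw(t) * sin(w t + reference_phase) ) ]``.
    ``adc=False`` skips quantization/clipping, exposing the pre-ADC value.
    """
    lpf = design_filters(config)["lpf"]
    prod, _ = _reference_products(raw, config, reference_phase_deg % 360.0,
                                  "continuous", 0.0, need_q=False)
    # pointwise gain/quantization commute with subsampling, so decimate first
    t_dec, u_dec = _decimate(raw.time_s, signal.sosfilt(lpf, prod),
                             raw.sample_rate_hz, config.output_rate_hz)
    u_dec = config.dc_gain * u_dec
    if adc:
        u_dec = _quantize(u_dec, config)
    return ImpedanceTrace(time_s=t_dec, U_v=u_dec, version="v1", config=config)


def demodulate_v2(
    raw: RawRecording,
    config: ChainConfig,
    adc: bool = True,
    mode: str = "continuous",
    chop_rate_hz: float = 1000.0,
) -> ImpedanceTrace:
    """Quadrature lock-in with vectorial resultant (version two).

    ``I = dc_gain * LPF(raw * sin(wt))``, ``Q = dc_gain * LPF(raw * cos(wt))``;
    each branch is digitized and the resultant ``U = sqrt(I^2 + Q^2)`` is
    formed from the ADC outputs.  The tissue phase is reported as
    ``phase_est = -atan2(Q, I)`` (a capacitive tissue lag appears positive).
    ``mode="chopped"`` emulates the hardware's alternating reference input
    with a zero-order-hold equivalent at ``chop_rate_hz``.
    """
    lpf = design_filters(config)["lpf"]
    prod_i, prod_q = _reference_products(raw, config, 0.0, mode, chop_rate_hz)
    # filtering must run at the full rate (carrier rejection); the pointwise
    # gain, ADC and vector sum commute with subsampling, so decimate first
    t_dec, i_br = _decimate(raw.time_s, signal.sosfilt(lpf, prod_i),
                            raw.sample_rate_hz, config.output_rate_hz)
    _, q_br = _decimate(raw.time_s, signal.sosfilt(lpf, prod_q),
                        raw.sample_rate_hz, config.output_rate_hz)
    i_br = config.dc_gain * i_br
    q_br = config.dc_gain * q_br
    if adc:
        i_br = _quantize(i_br, config)
        q_br = _quantize(q_br, config)
    u = np.hypot(i_br, q_br)
    phase = -np.degrees(np.arctan2(q_br, i_br))
    valid = u > max(10.0 * config.adc_lsb_v, 1e-12)
    phase = np.where(valid, phase, 0.0)
    return ImpedanceTrace(time_s=t_dec, U_v=u, version="v2", config=config,
                          phase_deg=phase, phase_valid=valid)


def calibrate_phase_v1(
    raw: RawRecording,
    config: ChainConfig,
    baseline_s: Optional[tuple[float, float]] = None,
) -> float:
    """Recover the tissue phase by maximizing the baseline v1 output.

    Emulates the potentiometer adjustment: the reference phase is swept on
    a 1-degree grid and refined to 0.1 degree around the maximum of the
    steady baseline output.  Because the v1 output is an exact cosine in
    the reference phase, the sweep is evaluated as
    ``U(ref) = I0 cos(ref) + Q0 sin(ref)`` from one I/Q demodulation of the
    baseline.  Returns the tissue phase in degrees, wrapped to (-180, 180];
    for chain-filtered recordings the chain's known carrier phase has
    already been compensated by the demodulator.

    Raises :class:`CalibrationError` when no carrier is detectable (carrier
    amplitude below 10x the noise floor of the quadrature residual).
    """
    if baseline_s is None:
        start = SETTLING_FACTOR / config.lpf_cutoff_hz
        baseline_s = (start, raw.duration_s)
    if baseline_s[1] - baseline_s[0] < 1.0:
        raise CalibrationError("calibration needs at least 1 s of steady baseline")

    tr = demodulate_v2(raw, config, adc=False)
    m = (tr.time_s >= baseline_s[0]) & (tr.time_s < baseline_s[1])
    u = tr.U_v[m]
    amp = float(np.mean(u))
    noise = float(np.std(u))
    if amp < 10.0 * max(noise, 1e-12):
        raise CalibrationError(
            f"no detectable carrier: baseline amplitude {amp:.3g} V below 10x "
            f"noise floor {noise:.3g} V"
        )
    # mean I/Q over the baseline: U(ref) = I0*cos(ref) + Q0*sin(ref)
    ph = np.radians(-tr.phase_deg[m])  # atan2(Q, I)
    i0 = float(np.mean(u * np.cos(ph)))
    q0 = float(np.mean(u * np.sin(ph)))

    def u_of(ref_deg: np.ndarray) -> np.ndarray:
        r = np.radians(ref_deg)
        return i0 * np.cos(r) + q0 * np.sin(r)

    coarse = np.arange(0.0, 360.0, 1.0)
    best = coarse[int(np.argmax(u_of(coarse)))]
    fine = best + np.arange(-1.0, 1.0001, 0.1)
    best = float(fine[int(np.argmax(u_of(fine)))])
    return ((best + 180.0) % 360.0) - 180.0
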