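"""Trace normalization, per-phase metrics, manometry reference, statistics.

The neuromonitor readout is evaluated qualitatively: the absolute impedance
value depends on electrode placement and contact and is irrelevant, so the
demodulated output is normalized to its pre-contraction baseline, giving the
dimensionless trace ``u(t) = U(t)/U(0)``.  The same convention applies to
the cystomanometry reference channel, ``p(t)/p(0)``, which — unlike the
impedance channel — requires the bladder to be filled before any pressure
response is detectable.

Across-trial comparisons (per stimulation frequency, amplitude or electrode
setup) are summarized with arithmetic mean, median and box-plot dispersion
(linearly interpolated quartiles, 1.5 IQR Tukey whiskers).  High mean and
median are read as a strong response, high dispersion as poor test-condition
stability.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .errors import DomainError, NormalizationError, ValidationError
from .lockin_demod import ImpedanceTrace
from .stimulation import StimulationProtocol
from .tissue_sim import ContractionState


@dataclass(frozen=True)
class NormalizedTrace:
    """Dimensionless neuromonitor trace u(t) = U(t)/U(0)."""

    time_s: np.ndarray
    u: np.ndarray
    baseline_window_s: tuple[float, float]
    U0_v: float
    noise_sigma: float  # std of u within the baseline window
    artifact_mask: Optional[np.ndarray] = None

    @property
    def sample_rate_hz(self) -> float:
        return 1.0 / (self.time_s[1] - self.time_s[0])


@dataclass(frozen=True)
class ManometryTrace:
    """Normalized bladder pressure p(t)/p(0) from cystomanometry."""

    time_s: np.ndarray
    p_norm: np.ndarray
    fill_volume_ml: float


@dataclass(frozen=True)
class PhaseMetrics:
    """Response metrics of one stimulation phase."""

    phase_index: int
    start_s: float
    end_s: float
    peak_u: float
    delta_u: float
    time_to_peak_s: float
    recovery_residual: float


@dataclass(frozen=True)
class TrialSummary:
    """Per-phase metrics of one trial plus its condition labels."""

    phases: tuple[PhaseMetrics, ...]
    frequency_hz: Optional[float] = None
    amplitude_ma: Optional[float] = None
    setup_id: Optional[str] = None
    site: Optional[str] = None

    def metric(self, name: str) -> list[float]:
        return [getattr(p, name) for p in self.phases]


@dataclass(frozen=True)
class ConditionStats:
    """Box-plot summary of one metric under one condition."""

    n: int
    mean: float
    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: tuple[float, ...]


# ---------------------------------------------------------------------------


def normalize(
    trace: ImpedanceTrace,
    baseline_window_s: tuple[float, float],
) -> NormalizedTrace:
    """Normalize a demodulated trace to its pre-contraction baseline.

    ``U0`` is the mean over the baseline window, which must start after the
    low-pass settling time and precede the first stimulation.  Raises
    :class:`NormalizationError` when ``U0`` is below 10x the baseline noise
    floor — the signature of a lost electrode contact.
    """
    a, b = baseline_window_s
    if b <= a:
        raise ValidationError("baseline window must have positive length")
    if a < trace.settling_time_s:
        raise ValidationError(
            f"baseline window starts at {a} s, inside the {trace.settling_time_s:.2f} s "
            "filter settling transient"
        )
    m = (trace.time_s >= a) & (trace.time_s < b)
    if not np.any(m):
        raise ValidationError("baseline window contains no samples")
    u0 = float(np.mean(trace.U_v[m]))
    sigma_v = float(np.std(trace.U_v[m]))
    if u0 <= 10.0 * max(sigma_v, 1e-12):
        raise NormalizationError(
            f"baseline level {u0:.3g} V below 10x noise floor {sigma_v:.3g} V "
            "(bad electrode contact?)"
        )
    u = trace.U_v / u0
    return NormalizedTrace(
        time_s=trace.time_s,
        u=u,
        baseline_window_s=(a, b),
        U0_v=u0,
        noise_sigma=sigma_v / u0,
        artifact_mask=trace.artifact_mask,
    )


def manometry_model(
    state: ContractionState,
    fill_volume_ml: float = 150.0,
    gain: float = 0.3,
    noise_rms: float = 0.003,
    seed: int = 0,
    fill_threshold_ml: float = 50.0,
) -> ManometryTrace:
    """Normalized cystomanometry channel driven by the contraction state.

    ``p(t)/p(0) = 1 + gain * c(t)`` when the bladder holds at least
    ``fill_threshold_ml`` of fluid, plus seeded white noise.  An empty (or
    under-filled) bladder transmits no pressure: ``p_norm`` stays at 1
    regardless of contraction — the reason manometry requires the 150 ml
    Ringer's fill that the impedance channel does not.
    """
    if fill_volume_ml < 0:
        raise DomainError("fill volume must be >= 0 ml")
    filled = fill_volume_ml >= fill_threshold_ml
    p = 1.0 + (gain * state.c if filled else np.zeros_like(state.c))
    if noise_rms > 0:
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        p = p + noise_rms * rng.standard_normal(len(p))
    return ManometryTrace(time_s=state.time_s, p_norm=p, fill_volume_ml=fill_volume_ml)


def phase_metrics(
    norm: NormalizedTrace,
    protocol: StimulationProtocol,
    peak_grace_s: float = 10.0,
) -> TrialSummary:
    """Per-stimulation-phase response metrics.

    The peak is searched within each stimulation phase plus a short grace
    period (the low-pass delays the displayed peak slightly past the end of
    stimulation); the recovery residual is |u - 1| at the end of the
    following rest phase.  Samples flagged as artifacts are excluded.
    """
    if norm.time_s[-1] + 1.0 / norm.sample_rate_hz < protocol.total_duration_s - 1e-6:
        raise ValidationError(
            f"trace ({norm.time_s[-1]:.1f} s) shorter than protocol "
            f"({protocol.total_duration_s:.1f} s)"
        )
    good = np.ones(len(norm.u), dtype=bool)
    if norm.artifact_mask is not None:
        good &= ~norm.artifact_mask

    bounds = protocol.phase_boundaries()
    metrics: list[PhaseMetrics] = []
    freq = amp = site = None
    idx = 0
    for k, (kind, a, b) in enumerate(bounds):
        if kind != "stim":
            continue
        train = protocol.phases[k].train
        freq, amp, site = train.frequency_hz, train.amplitude_ma, train.site
        m = (norm.time_s >= a) & (norm.time_s < b + peak_grace_s) & good
        if not np.any(m):
            raise ValidationError(f"no unflagged samples in stimulation phase {idx}")
        seg_t, seg_u = norm.time_s[m], norm.u[m]
        i_peak = int(np.argmax(seg_u))
        peak_u = float(seg_u[i_peak])
        # recovery residual at the end of the following rest phase (if any)
        residual = np.nan
        if k + 1 < len(bounds) and bounds[k + 1][0] == "rest":
            rest_end = bounds[k + 1][2]
            mrest = (norm.time_s <= rest_end) & good
            if np.any(mrest):
                residual = float(abs(norm.u[mrest][-1] - 1.0))
        metrics.append(
            PhaseMetrics(
                phase_index=idx,
                start_s=a,
                end_s=b,
                peak_u=peak_u,
                delta_u=peak_u - 1.0,
                time_to_peak_s=float(seg_t[i_peak] - a),
                recovery_residual=residual,
            )
        )
        idx += 1
    return TrialSummary(phases=tuple(metrics), frequency_hz=freq, amplitude_ma=amp,
                        site=site)


def condition_stats(
    summaries: Sequence[TrialSummary] | Sequence[float],
    metric: str = "delta_u",
) -> ConditionStats:
    """Box-plot summary (mean, median, quartiles, Tukey whiskers) of a metric.

    Accepts either trial summaries (all phases of all trials pooled) or a
    bare sequence of values.  Quartiles use linear interpolation; whiskers
    are clamped to the most extreme observations within 1.5 IQR of the box.
    """
    if len(summaries) == 0:
        raise DomainError("condition_stats requires at least one trial")
    if isinstance(summaries[0], TrialSummary):
        values = np.array(
            [v for s in summaries for v in s.metric(metric)], dtype=float
        )
    else:
        values = np.asarray(summaries, dtype=float)
    values = values[np.isfinite(values)]
    if len(values) == 0:
        raise DomainError("no finite values to summarize")
    q1, med, q3 = np.percentile(values, [25.0, 50.0, 75.0])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = values[(values >= lo_fence) & (values <= hi_fence)]
    outliers = tuple(float(v) for v in np.sort(values[(values < lo_fence) | (values > hi_fence)]))
    return ConditionStats(
        n=len(values),
        mean=float(np.mean(values)),
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        whisker_low=float(np.min(inside)),
        whisker_high=float(np.max(inside)),
        outliers=outliers,
    )


@dataclass(frozen=True)
class ContractionEvent:
    start_s: float
    end_s: float
    peak_u: float


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open index spans of contiguous True runs."""
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2], edges[1::2]))


def detect_contraction(
    norm: NormalizedTrace,
    noise_sigma: Optional[float] = None,
    k: float = 5.0,
    min_duration_s: float = 2.0,
    merge_gap_s: float = 1.0,
    min_delta: float = 0.0,
    k_end: float = 2.0,
) -> list[ContractionEvent]:
    """Detect sustained contraction responses in a normalized trace.

    Schmitt-trigger detection with two thresholds: an event requires
    ``u - 1`` to exceed the onset threshold ``max(k * noise_sigma,
    min_delta)`` continuously for at least ``min_duration_s``, and then
    extends over the surrounding span where ``u - 1`` stays above the
    release threshold ``k_end * noise_sigma``.  The hysteresis keeps the
    slowly relaxing tail of a contraction — which hovers near the onset
    threshold for many seconds — inside its event instead of shedding
    noise-driven fragments.  Sub-duration crossings never seed an event,
    and events separated by less than ``merge_gap_s`` are merged.

    ``noise_sigma`` defaults to the baseline estimate stored in the trace.
    ``min_delta`` lets the caller keep the onset threshold above known
    spontaneous activity (rectal self-activity is not subtracted from u
    and will otherwise register).
    """
    sigma = norm.noise_sigma if noise_sigma is None else noise_sigma
    if sigma <= 0:
        raise DomainError("noise sigma must be positive")
    if k_end > k:
        raise DomainError("release threshold k_end must not exceed onset k")
    thr_hi = max(k * sigma, min_delta)
    thr_lo = min(k_end * sigma, thr_hi)
    excess = norm.u - 1.0
    good = np.ones(len(excess), dtype=bool)
    if norm.artifact_mask is not None:
        good = ~norm.artifact_mask
    dt = 1.0 / norm.sample_rate_hz

    hi_runs = [(s, e) for s, e in _runs((excess > thr_hi) & good)
               if (e - s) * dt >= min_duration_s]
    if not hi_runs:
        return []
    lo_runs = _runs((excess > thr_lo) & good)

    # each event: start at a sustained onset run, end where the release-
    # level run containing that onset ends; onsets inside an open event
    # (or within merge_gap of its end) extend it instead of starting anew
    events: list[list[int]] = []
    for hs, _ in hi_runs:
        le = next(e for s, e in lo_runs if s <= hs < e)
        if events and (hs - events[-1][1]) * dt < merge_gap_s:
            events[-1][1] = max(events[-1][1], le)
        else:
            events.append([hs, le])

    return [
        ContractionEvent(
            start_s=float(norm.time_s[s]),
            end_s=float(norm.time_s[e - 1]),
            peak_u=float(np.max(norm.u[s:e])),
        )
        for s, e in events
    ]


def flag_artifacts(trace: ImpedanceTrace, slope_limit_v_per_s: float,
                   pad_s: float = 0.1) -> np.ndarray:
    """Flag samples whose slope exceeds the physiological limit.

    Mechanical manipulation produces step-like jumps far steeper than any
    contraction (whose rise time is set by the activation time constant);
    samples where ``|dU/dt|`` exceeds ``slope_limit_v_per_s`` are flagged,
    with ``pad_s`` of padding on each side, and excluded from metrics
    downstream.  Returns a boolean mask aligned with the trace.
    """
    if slope_limit_v_per_s <= 0:
        raise DomainError("slope limit must be positive")
    dt = 1.0 / trace.sample_rate_hz
    slope = np.abs(np.gradient(trace.U_v, dt))
    mask = slope > slope_limit_v_per_s
    if np.any(mask) and pad_s > 0:
        w = int(round(pad_s / dt))
        idx = np.flatnonzero(mask)
        for i in idx:
            mask[max(0, i - w) : i + w + 1] = True
    return mask


def with_artifact_mask(trace: ImpedanceTrace, mask: np.ndarray) -> ImpedanceTrace:
    """Attach an artifact mask to a trace (returns a copy)."""
    return replace(trace, artifact_mask=np.asarray(mask, dtype=bool))


def physiological_slope_limit(
    u0_v: float,
    coupling: float = 0.1,
    coverage: float = 0.9,
    tau_act_s: float = 10.0,
    factor: float = 10.0,
) -> float:
    """Default artifact slope limit: ``factor`` times the steepest slope a
    contraction can produce, ``U0 * coupling * coverage / tau_act``."""
    return factor * u0_v * coupling * coverage / tau_act_s
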