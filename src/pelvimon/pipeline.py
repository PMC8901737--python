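"""End-to-end pipeline: simulate -> synthesize -> demodulate -> analyze.

All randomness flows from the single global seed through named sub-streams
("contraction", "noise", "manometry", per-trial cohort streams), so adding
a new noise source never perturbs existing streams and identical
config+seed pairs give bit-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .analog_frontend import RawRecording, synthesize_raw
from .config import RunConfig, config_to_dict
from .lockin_demod import ImpedanceTrace, calibrate_phase_v1, demodulate_v1, demodulate_v2
from .stimulation import StimulationProtocol, protocol_waveform
from .timeseries_io import export_contraction_csv, write_timeseries_csv
from .tissue_sim import (
    ContractionState,
    TissueImpedanceTrace,
    impedance_trace,
    simulate_contraction,
)
from .trace_analysis import (
    ContractionEvent,
    ManometryTrace,
    NormalizedTrace,
    TrialSummary,
    detect_contraction,
    flag_artifacts,
    manometry_model,
    normalize,
    phase_metrics,
    physiological_slope_limit,
    with_artifact_mask,
)


def stream_seed(seed: int, name: str) -> int:
    """Derive a stable per-stream integer seed from the global seed.

    Streams are keyed by name through CRC32, so the mapping is stable
    across sessions and insensitive to the order in which streams are
    drawn.
    """
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(name.encode())])
    return int(ss.generate_state(1)[0])


@dataclass
class PipelineResult:
    """Artifact bundle of one pipeline run."""

    config: RunConfig
    protocol: StimulationProtocol
    state: ContractionState
    z_trace: TissueImpedanceTrace
    trace: ImpedanceTrace
    norm: NormalizedTrace
    summary: TrialSummary
    events: list[ContractionEvent]
    manometry: Optional[ManometryTrace]
    calibrated_phase_deg: Optional[float]
    raw: Optional[RawRecording]
    timings_s: dict[str, float]

    def summary_dict(self) -> dict:
        return {
            "config_hash": config_hash(self.config),
            "seed": self.config.seed,
            "calibrated_phase_deg": self.calibrated_phase_deg,
            "U0_v": self.norm.U0_v,
            "noise_sigma_u": self.norm.noise_sigma,
            "n_events": len(self.events),
            "events": [dataclasses.asdict(e) for e in self.events],
            "phases": [dataclasses.asdict(p) for p in self.summary.phases],
            "timings_s": self.timings_s,
        }


def config_hash(config: RunConfig) -> str:
    blob = json.dumps(config_to_dict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def baseline_window(config: RunConfig, protocol: StimulationProtocol) -> tuple[float, float]:
    """Baseline window: the ``analysis.baseline_s`` seconds immediately
    preceding the first stimulation, clipped past the filter settling time."""
    first_stim = protocol.stim_windows()[0][0]
    settle = 3.0 / config.chain.lpf_cutoff_hz
    start = max(first_stim - config.analysis.baseline_s, settle)
    if start >= first_stim:
        raise ValueError(
            "no usable baseline: first stimulation starts inside the filter "
            "settling transient"
        )
    return (start, first_stim)


def lead_in_protocol(config: RunConfig) -> StimulationProtocol:
    """The configured protocol preceded by a rest lead-in long enough to
    hold the settling transient plus the baseline window."""
    from .stimulation import ProtocolPhase

    settle = 3.0 / config.chain.lpf_cutoff_hz
    lead = float(np.ceil(settle + config.analysis.baseline_s + 1.0))
    base = config.protocol.build()
    return StimulationProtocol((ProtocolPhase("rest", lead),) + base.phases)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run the full simulate/synthesize/demodulate/analyze pipeline."""
    timings: dict[str, float] = {}
    t0 = time.perf_counter()

    protocol = lead_in_protocol(config)
    state = simulate_contraction(
        protocol,
        config.recruitment,
        config.contraction,
        control_rate_hz=config.control_rate_hz,
        seed=stream_seed(config.seed, "contraction"),
    )
    z_tr = impedance_trace(state, config.tissue, config.setup, config.chain.carrier_freq_hz)
    timings["simulate"] = time.perf_counter() - t0

    t1 = time.perf_counter()
    stim_wave = None
    if config.chain.crosstalk_coupling > 0:
        stim_wave = protocol_waveform(protocol, config.chain.sample_rate_hz)
    raw = synthesize_raw(
        z_tr,
        config.chain,
        stim_waveform_ma=stim_wave,
        seed=stream_seed(config.seed, "noise"),
        channel=config.setup.organ,
    )
    timings["synthesize"] = time.perf_counter() - t1

    t2 = time.perf_counter()
    window = baseline_window(config, protocol)
    cal_phase = None
    if config.analysis.demod_version == "v1":
        cal_phase = calibrate_phase_v1(raw, config.chain, baseline_s=window)
        trace = demodulate_v1(raw, config.chain, reference_phase_deg=cal_phase)
    else:
        trace = demodulate_v2(raw, config.chain)
    timings["demodulate"] = time.perf_counter() - t2

    t3 = time.perf_counter()
    norm0 = normalize(trace, window)
    slope_limit = physiological_slope_limit(
        norm0.U0_v,
        coupling=max(config.tissue.coupling_resistive, config.tissue.coupling_capacitive),
        coverage=max(config.setup.coverage, 0.1),
        tau_act_s=config.contraction.tau_act_s,
        factor=config.analysis.artifact_slope_factor,
    )
    # an artifact below the noise floor of the slope is undetectable: keep
    # the limit above the extreme slope white noise alone produces
    wm = (trace.time_s >= window[0]) & (trace.time_s < window[1])
    noise_slope = float(np.std(np.gradient(trace.U_v[wm], 1.0 / config.chain.output_rate_hz)))
    slope_limit = max(slope_limit, 8.0 * noise_slope)
    mask = flag_artifacts(trace, slope_limit)
    trace = with_artifact_mask(trace, mask)
    norm = normalize(trace, window)

    summary = phase_metrics(norm, protocol)
    summary = dataclasses.replace(summary, setup_id=config.setup.setup_id)
    # keep the detection threshold above configured rectal self-activity
    min_delta = 0.0
    if config.contraction.organ == "rectum":
        min_delta = (
            1.5
            * config.contraction.self_activity_amplitude
            * max(config.tissue.coupling_resistive, config.tissue.coupling_capacitive)
            * config.setup.coverage
        )
    events = detect_contraction(
        norm,
        k=config.analysis.detection_k,
        min_duration_s=config.analysis.min_event_s,
        merge_gap_s=config.analysis.merge_gap_s,
        min_delta=min_delta,
    )

    mano = None
    if config.setup.organ == "bladder":
        mano = manometry_model(
            state,
            fill_volume_ml=config.analysis.manometry_fill_ml,
            gain=config.analysis.manometry_gain,
            noise_rms=config.analysis.manometry_noise_rms,
            seed=stream_seed(config.seed, "manometry"),
        )
    timings["analyze"] = time.perf_counter() - t3

    result = PipelineResult(
        config=config,
        protocol=protocol,
        state=state,
        z_trace=z_tr,
        trace=trace,
        norm=norm,
        summary=summary,
        events=events,
        manometry=mano,
        calibrated_phase_deg=cal_phase,
        raw=raw if config.analysis.store_raw else None,
        timings_s=timings,
    )
    if config.outdir:
        write_bundle(result, Path(config.outdir))
    return result


def write_bundle(result: PipelineResult, outdir: Path) -> None:
    """Write the artifact bundle (CSV traces, summary JSON, log)."""
    outdir.mkdir(parents=True, exist_ok=True)
    export_contraction_csv(result.state, result.z_trace, outdir / "contraction.csv")
    write_timeseries_csv(result.trace, outdir / "impedance.csv")
    write_timeseries_csv(result.norm, outdir / "normalized.csv")
    if result.raw is not None:
        write_timeseries_csv(result.raw, outdir / "raw.csv")
    (outdir / "summary.json").write_text(json.dumps(result.summary_dict(), indent=2))
    (outdir / "config.json").write_text(
        json.dumps(config_to_dict(result.config), indent=2, default=str)
    )
    log = [
        f"config_hash={config_hash(result.config)}",
        f"seed={result.config.seed}",
    ] + [f"timing.{k}={v:.3f}s" for k, v in result.timings_s.items()]
    (outdir / "run.log").write_text("\n".join(log) + "\n")


def run_cohort(
    base: RunConfig,
    n_trials: int = 20,
    seed: int = 1,
    vary_coverage: bool = True,
) -> list[TrialSummary]:
    """Simulate a cohort of independent trials under one condition.

    Each trial draws its own noise/self-activity streams and, when
    ``vary_coverage`` is set, an individual effective electrode coverage
    from a lognormal distribution with the setup's coefficient of variation
    (electrode placement differs between individuals; the paper-level
    dispersion of U(t)/U(0) comes mostly from this).
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, zlib.crc32(b"cohort")]))
    summaries = []
    cv = base.setup.coverage_cv
    for i in range(n_trials):
        cfg = dataclasses.replace(base, seed=stream_seed(seed, f"trial{i}") & 0x7FFFFFFF)
        if vary_coverage and cv > 0:
            sigma = np.sqrt(np.log1p(cv * cv))
            mult = float(np.exp(rng.normal(-0.5 * sigma * sigma, sigma)))
            cov = float(np.clip(base.setup.coverage * mult, 0.05, 1.0))
            cfg = dataclasses.replace(
                cfg, setup=dataclasses.replace(base.setup, coverage=cov)
            )
        summaries.append(run_pipeline(cfg).summary)
    return summaries


def reference_run(seed: int = 1, outdir: Optional[str] = None) -> PipelineResult:
    """The reference bladder run: default tissue/chain, 3 x (30 s stim at
    15 mA / 1000 us / 30 Hz + 120 s rest), quadrature demodulation."""
    return run_pipeline(dataclasses.replace(RunConfig(), seed=seed, outdir=outdir))
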