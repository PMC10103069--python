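"""Run configuration and the simulate -> track -> analyze pipeline.

A ``RunConfig`` is fully serializable; a run report embeds the resolved
config and the package version so identical config + seed reproduce an
identical comparable payload (timestamps live under ``meta`` and are
excluded from the comparison).
"""
from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from . import __version__
from .types import Calibration, ConfigError, LightingEpoch
from . import aliasing, binocular, kinematics, receptive_field, synthetic, tracker

log = logging.getLogger("pseudopupil")

KNOWN_STAGES = ("tracking", "okr", "gap", "rf_shift", "aliasing")


@dataclass
class RunConfig:
    """Serializable description of one pipeline run."""

    seed: int = 0
    sample_rate: float = synthetic.DEFAULT_SAMPLE_RATE
    deg_per_spacing: float = 5.0
    stages: list[str] = field(default_factory=lambda: ["okr"])
    params: dict[str, dict[str, Any]] = field(default_factory=dict)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)


def _stage_tracking(cfg: RunConfig, p: dict[str, Any]) -> dict[str, Any]:
    n_frames = int(p.get("n_frames", 200))
    amp = float(p.get("amplitude_deg", 2.0))
    dt = 1.0 / cfg.sample_rate
    times = np.arange(n_frames) * dt
    x = amp * np.sin(2 * np.pi * 0.5 * times)
    gt = synthetic.TrajectoryGT(times=times, x=x, y=np.zeros_like(x),
                                smooth_x=x, smooth_y=np.zeros_like(x))
    scene = synthetic.SceneParams(seed=cfg.seed)
    stack, px_gt = synthetic.gen_frames(gt, scene, cfg.deg_per_spacing)
    res = tracker.track_stack(stack)
    calib = Calibration(tracker.estimate_spacing(res.dots), cfg.deg_per_spacing)
    trace = tracker.to_degrees(res, calib)
    rms = float(np.sqrt(np.mean((trace.x - (x - x.mean())) ** 2)))
    return {"n_frames": n_frames, "px_per_spacing": calib.px_per_spacing,
            "rms_error_deg": rms,
            "peak_to_peak_deg": float(np.ptp(trace.x))}


def _stage_okr(cfg: RunConfig, p: dict[str, Any]) -> dict[str, Any]:
    params = synthetic.OkrParams(seed=cfg.seed, sample_rate=cfg.sample_rate,
                                 **{k: v for k, v in p.items()
                                    if k in ("gain", "stimulus_speed",
                                             "nystagmus_rate",
                                             "noise_sigma_deg")})
    duration = float(p.get("duration", 10.0))
    _, right = synthetic.gen_okr_trace(params, duration)
    trace = right.to_eye_trace()
    sacc = kinematics.detect_saccades(trace)
    iv = kinematics.initial_velocity(trace, 0.0, saccades=sacc)
    gain = kinematics.okr_gain(iv, params.stimulus_speed)
    oi = kinematics.optomotor_index(trace, saccades=sacc)
    return {"initial_velocity_deg_s": iv, "gain": gain.gain,
            "tracking_sign": gain.sign, "n_saccades": len(sacc),
            "optomotor_index": oi.value}


def _stage_gap(cfg: RunConfig, p: dict[str, Any]) -> dict[str, Any]:
    params = synthetic.GapSessionParams(
        seed=cfg.seed, sample_rate=cfg.sample_rate,
        n_crossings=int(p.get("n_crossings", 5)),
        vergence_amplitude=float(p.get("vergence_amplitude", 2.0)))
    session, t_gt = synthetic.gen_gap_session(params)
    threshold = params.gap_offset_deg - 1.0
    events = binocular.detect_crossings(session.times, session.wheel,
                                        threshold, session=session)
    fwd = [e for e in events if e.direction == "forward"]
    avg = binocular.triggered_average(binocular.session_channels(session), fwd)
    deltas = binocular.event_deltas(avg)
    tt = binocular.deltas_ttest(deltas, m_tests=9)
    return {"n_crossings_gt": int(t_gt.size), "n_forward_events": len(fwd),
            "mean_vergence_delta": float(deltas["vergence_delta"].mean()),
            "vergence_significant": bool(tt.loc["vergence_delta",
                                                "significant"])}


def _stage_rf_shift(cfg: RunConfig, p: dict[str, Any]) -> dict[str, Any]:
    shift = float(p.get("shift_deg", 5.7))
    latency = float(p.get("latency_s", 0.1))
    sweeps = synthetic.gen_bar_sweep(shift, latency, seed=cfg.seed,
                                     noise_sigma_mV=float(
                                         p.get("noise_sigma_mV", 1.0)))
    est = receptive_field.combine_directions(sweeps)
    return {"true_shift_deg": shift, "combined_shift_deg": est.shift,
            "per_direction_deg": list(est.per_direction),
            "quality": est.quality}


def _stage_aliasing(cfg: RunConfig, p: dict[str, Any]) -> dict[str, Any]:
    array = aliasing.SamplingArray(delta_phi=float(p.get("delta_phi", 5.0)))
    lo, hi = aliasing.inversion_band(array)
    return {"delta_phi": array.delta_phi, "band_low_deg": lo,
            "band_high_deg": hi,
            "cutoff_ratio": hi / array.delta_phi}


_STAGE_FN = {"tracking": _stage_tracking, "okr": _stage_okr,
             "gap": _stage_gap, "rf_shift": _stage_rf_shift,
             "aliasing": _stage_aliasing}


def run_pipeline(config: RunConfig | dict[str, Any],
                 outdir: str | Path | None = None) -> dict[str, Any]:
    """Execute the configured stages and return (and optionally write) a report.

    The report's ``results`` and ``config`` blocks are deterministic for a
    given config + seed; wall-clock data lives under ``meta`` only.
    Unknown stage names raise ``ConfigError``; a stage failure halts the
    run with the stage name and cause.
    """
    if isinstance(config, dict):
        config = RunConfig.from_dict(config)
    for name in config.stages:
        if name not in _STAGE_FN:
            raise ConfigError(f"unknown stage {name!r}; known: {KNOWN_STAGES}")
    results: dict[str, Any] = {}
    timings: dict[str, float] = {}
    for name in config.stages:
        t0 = time.perf_counter()
        log.info("stage %s ...", name)
        try:
            results[name] = _STAGE_FN[name](config,
                                            config.params.get(name, {}))
        except Exception as exc:  # halt with stage name and cause
            raise ConfigError(f"stage {name!r} failed: {exc}") from exc
        timings[name] = time.perf_counter() - t0
        log.info("stage %s done in %.2fs", name, timings[name])
    report = {"config": config.to_dict(), "version": __version__,
              "results": results,
              "meta": {"timings_s": timings, "timestamp": time.time()}}
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "report.json", "w", encoding="utf-8") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
    return report


def comparable_payload(report: dict[str, Any]) -> dict[str, Any]:
    """The deterministic part of a report (drops ``meta``)."""
    return {k: v for k, v in report.items() if k != "meta"}
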