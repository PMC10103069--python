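"""Eye-trace kinematics: velocities, saccades, main sequence, OKR metrics.

Saccades are detected with a threshold-crossing algorithm on the 2-D speed
computed by a Savitzky-Golay smoothing differentiator, with hysteresis for
onset/offset placement, a refractory merge and median-window amplitude
estimation.  Saccade amplitude vs peak velocity follows a power-law "main
sequence"; the optokinetic response is summarized by the initial
(desaccaded) velocity, its gain relative to stimulus speed, and an
optomotor index in [-1, 1].
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy.signal import savgol_filter
from scipy.stats import pearsonr, theilslopes

from .types import EyeTrace, MainSequenceFit, Saccade, StimulusEpoch


@dataclass(frozen=True)
class VelocityConfig:
    """Savitzky-Golay differentiator parameters (mirror-padded ends)."""

    window: int = 5  # samples, odd
    polyorder: int = 2


@dataclass(frozen=True)
class SaccadeConfig:
    """Threshold-crossing saccade detector parameters.

    Candidate events are intervals where the 2-D speed exceeds
    ``threshold``; onset and offset extend outward to where speed falls
    below ``threshold * hysteresis_ratio``.  Events separated by less than
    ``refractory`` seconds are merged.  Amplitude per axis is the median
    position over ``amp_window`` seconds after offset minus the median
    over the same window before onset.
    """

    threshold: float = 15.0  # deg/s
    hysteresis_ratio: float = 1.0 / 3.0
    refractory: float = 0.1  # s
    amp_window: float = 0.05  # s
    baseline_window: float = 0.5  # s, rolling-median window for smooth velocity
    velocity: VelocityConfig = VelocityConfig()


def differentiate(trace: EyeTrace,
                  cfg: VelocityConfig | None = None
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Velocity (vx, vy) in deg/s via a local polynomial fit."""
    cfg = cfg or VelocityConfig()
    n = trace.times.size
    if cfg.window > n:
        raise ValueError(
            f"window ({cfg.window}) longer than trace ({n} samples)")
    dt = trace.dt
    vx = savgol_filter(trace.x, cfg.window, cfg.polyorder, deriv=1,
                       delta=dt, mode="mirror")
    vy = savgol_filter(trace.y, cfg.window, cfg.polyorder, deriv=1,
                       delta=dt, mode="mirror")
    return vx, vy


def detect_saccades(trace: EyeTrace,
                    cfg: SaccadeConfig | None = None) -> list[Saccade]:
    """Detect saccades on the 2-D speed with hysteresis. Empty list is valid.

    The thresholded quantity is the speed of the velocity *residual* after
    subtracting a rolling-median baseline velocity, so that slow smooth
    tracking (optokinetic drift) of any gain does not trigger or extend
    events; peak velocity is still reported from the raw speed.
    """
    cfg = cfg or SaccadeConfig()
    vx, vy = differentiate(trace, cfg.velocity)
    dt = trace.dt
    n = vx.size
    w = int(round(cfg.baseline_window / dt)) | 1  # odd
    if 1 < w < n:
        from scipy.ndimage import median_filter
        bx = median_filter(vx, size=w, mode="nearest")
        by = median_filter(vy, size=w, mode="nearest")
    else:
        bx = np.zeros_like(vx)
        by = np.zeros_like(vy)
    speed = np.hypot(vx - bx, vy - by)
    raw_speed = np.hypot(vx, vy)
    hi = speed > cfg.threshold
    if not hi.any():
        return []
    low = speed >= cfg.threshold * cfg.hysteresis_ratio

    # contiguous runs above the high threshold
    edges = np.flatnonzero(np.diff(np.r_[0, hi.astype(int), 0]))
    starts, ends = edges[::2], edges[1::2] - 1  # inclusive

    # extend each run outward while above the hysteresis bound
    events: list[tuple[int, int]] = []
    for s, e in zip(starts, ends):
        while s > 0 and low[s - 1]:
            s -= 1
        while e < n - 1 and low[e + 1]:
            e += 1
        events.append((int(s), int(e)))

    # merge events closer than the refractory period
    merged: list[tuple[int, int]] = []
    gap = int(round(cfg.refractory / dt))
    for s, e in events:
        if merged and s - merged[-1][1] <= gap:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))

    w = max(int(round(cfg.amp_window / dt)), 1)
    out: list[Saccade] = []
    for s, e in merged:
        pre = slice(max(s - w, 0), max(s, 1))
        post = slice(min(e + 1, n - 1), min(e + 1 + w, n))
        amp_x = float(np.median(trace.x[post]) - np.median(trace.x[pre]))
        amp_y = float(np.median(trace.y[post]) - np.median(trace.y[pre]))
        pk = float(raw_speed[s:e + 1].max())
        t0 = float(trace.times[s])
        t1 = float(trace.times[min(e + 1, n - 1)])
        if t1 <= t0:
            t1 = t0 + dt
        out.append(Saccade(t0, t1, amp_x, amp_y, pk))
    return out


def main_sequence(saccades: Sequence[Saccade]) -> MainSequenceFit:
    """Least-squares power-law fit of peak velocity vs amplitude.

    Fits a line on (log|A|, log v_peak) over saccades with |A| > 0 and
    returns k = exp(intercept), b = slope and the log-log Pearson r.
    """
    amps = np.array([s.amplitude for s in saccades])
    vels = np.array([s.peak_velocity for s in saccades])
    sel = (amps > 0) & (vels > 0)
    amps, vels = amps[sel], vels[sel]
    if amps.size < 3:
        raise ValueError("need >= 3 saccades with non-zero amplitude")
    la, lv = np.log(amps), np.log(vels)
    if np.ptp(la) == 0:
        raise ValueError("degenerate input: all amplitudes equal")
    b, logk = np.polyfit(la, lv, 1)
    if np.ptp(lv) == 0:
        r = 0.0
    else:
        r = float(pearsonr(la, lv)[0])
    return MainSequenceFit(k=float(np.exp(logk)), b=float(b), r=r,
                           n=int(amps.size))


class OkrGain(NamedTuple):
    """Optokinetic gain with the tracking sign reported separately."""

    gain: float
    sign: int  # sign of the initial velocity (-1 opposes a +1 stimulus)


def initial_velocity(trace: EyeTrace, stim_onset: float,
                     window: float = 0.5,
                     saccades: Sequence[Saccade] | None = None,
                     axis: str = "x") -> float:
    """Initial retinal velocity after stimulus onset, deg/s.

    Robust (Theil-Sen) slope of the desaccaded position over
    ``[stim_onset, stim_onset + window]``.
    """
    if saccades is None:
        saccades = detect_saccades(trace)
    smooth = desaccade(trace, saccades)
    t0, t1 = stim_onset, stim_onset + window
    if t0 < trace.times[0] - 1e-9 or t1 > trace.times[-1] + 1e-9:
        raise ValueError("analysis window outside trace")
    sel = (trace.times >= t0) & (trace.times <= t1)
    pos = smooth.x if axis == "x" else smooth.y
    t = trace.times[sel]
    p = pos[sel]
    if t.size < 2:
        raise ValueError("analysis window contains <2 samples")
    if np.ptp(p) == 0:
        return 0.0
    return float(theilslopes(p, t)[0])


def okr_gain(iv: float, stimulus_speed: float) -> OkrGain:
    """Gain = |initial velocity| / |stimulus speed|, sign reported separately."""
    if stimulus_speed == 0:
        raise ValueError("gain undefined for zero stimulus speed")
    return OkrGain(abs(iv) / abs(stimulus_speed), int(np.sign(iv)))


class OptomotorIndex(NamedTuple):
    value: float
    degenerate: bool  # True when total displacement was zero


def optomotor_index(trace: EyeTrace,
                    epochs: Sequence[StimulusEpoch] | None = None,
                    saccades: Sequence[Saccade] | None = None
                    ) -> OptomotorIndex:
    """Response strength in the expected optokinetic direction, in [-1, 1].

    Per motion epoch, OI = s * (net desaccaded displacement) / (total
    absolute desaccaded displacement) with s = -sign(stimulus direction),
    so that tracking opposite the stimulus scores +1; the epoch values are
    averaged and clipped to [-1, 1].  Zero total displacement yields 0,
    flagged as degenerate.
    """
    eps = [e for e in (epochs if epochs is not None else trace.epochs)
           if e.direction != 0]
    if not eps:
        raise ValueError("need at least one motion epoch")
    if saccades is None:
        saccades = detect_saccades(trace)
    smooth = desaccade(trace, saccades)
    vals: list[float] = []
    any_motion = False
    for ep in eps:
        sel = (trace.times >= ep.start) & (trace.times <= ep.end)
        x = smooth.x[sel]
        if x.size < 2:
            continue
        total = float(np.abs(np.diff(x)).sum())
        if total == 0:
            continue
        any_motion = True
        net = float(x[-1] - x[0])
        vals.append(-np.sign(ep.direction) * net / total)
    if not any_motion:
        return OptomotorIndex(0.0, True)
    return OptomotorIndex(float(np.clip(np.mean(vals), -1.0, 1.0)), False)


def desaccade(trace: EyeTrace,
              saccades: Sequence[Saccade],
              amp_window: float = 0.05) -> EyeTrace:
    """Remove saccade steps, leaving the smooth component.

    Each saccade interval is replaced by linear interpolation between its
    endpoints after subtracting the saccade's step from all subsequent
    samples, so the cumulative saccadic displacement is removed.  The step
    is re-measured as the median-window position change across the event
    minus the expected smooth drift (local pre-onset slope), so that
    optokinetic tracking of any gain passes through unchanged.
    """
    out = trace.copy()
    t = out.times
    dt = out.dt if t.size >= 2 else 0.0
    w = max(int(round(amp_window / dt)), 1) if dt else 1
    kb = max(int(round(0.3 / dt)), 5) if dt else 5
    n = t.size
    for sac in sorted(saccades, key=lambda s: s.onset):
        i0 = int(np.searchsorted(t, sac.onset))
        i1 = int(np.searchsorted(t, sac.offset))
        i1 = min(i1, n - 1)
        if i1 <= i0:
            continue
        pre = slice(max(i0 - w, 0), max(i0, 1))
        post = slice(min(i1 + 1, n - 1), min(i1 + 1 + w, n))
        span = (t[post].mean() - t[pre].mean()) if dt else 0.0
        for arr in (out.x, out.y):
            base = slice(max(i0 - kb, 0), i0)
            if i0 - base.start >= 5 and np.ptp(arr[base]) > 0:
                slope = float(theilslopes(arr[base], t[base])[0])
            else:
                slope = 0.0
            step = (float(np.median(arr[post]) - np.median(arr[pre]))
                    - slope * span)
            arr[i1:] -= step
            arr[i0:i1 + 1] = np.linspace(arr[i0], arr[i1], i1 - i0 + 1)
    return out
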