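"""Synthetic-data generator with recorded ground truth.

Every input the pipeline consumes can be generated here: seven-dot deep
pseudopupil frame stacks translating along a known trajectory, optokinetic
traces with nystagmus counter-saccades, binocular gap-crossing sessions
with vergence events locked to wheel-threshold crossings, bar-sweep tuning
curves, flash-grid receptive-field responses and free-walking gap-crossing
trajectories.  Ground truth is returned alongside each artifact so that
every downstream stage can be tested for parameter recovery without any
recorded data.

Modeling choices (see docs/methods.md for rationale):

* default sample rate 100 Hz; saccades are minimum-jerk steps with a 30 ms
  default rise time, which makes peak velocity 1.875/0.030 = 62.5 x
  amplitude (a main sequence with exponent 1);
* noise is additive Gaussian, on positions (degrees) and on pixel
  intensities;
* a single seeded RNG stream per generated object.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .types import (
    EyeTrace,
    FrameStack,
    GapSession,
    LightingEpoch,
    StimulusEpoch,
    TuningCurve,
)

DEFAULT_SAMPLE_RATE = 100.0  # Hz
DEFAULT_SACCADE_RISE = 0.030  # s, minimum-jerk step duration
#: peak velocity of a minimum-jerk step of unit amplitude and unit duration
MIN_JERK_PEAK = 1.875


# --------------------------------------------------------------------------
# ground-truth containers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SaccadeEventGT:
    """Ground truth for one injected saccade (x axis)."""

    onset: float
    offset: float
    amplitude: float  # signed, degrees

    @property
    def direction(self) -> int:
        return int(np.sign(self.amplitude))


@dataclass
class TrajectoryGT:
    """Ground-truth eye trajectory: smooth component plus saccade steps.

    Invariant: ``x = smooth_x + sum of saccade step waveforms`` at every
    sample (before measurement noise, which is stored separately in the
    noisy ``x_noisy`` view used to build observable traces).
    """

    times: np.ndarray
    x: np.ndarray
    y: np.ndarray
    smooth_x: np.ndarray
    smooth_y: np.ndarray
    saccade_events: tuple[SaccadeEventGT, ...] = ()
    x_noisy: np.ndarray | None = None
    y_noisy: np.ndarray | None = None
    eye: str = "right"
    epochs: tuple[StimulusEpoch, ...] = ()

    def __post_init__(self) -> None:
        if self.times.size >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    def to_eye_trace(self, noisy: bool = True) -> EyeTrace:
        x = self.x_noisy if (noisy and self.x_noisy is not None) else self.x
        y = self.y_noisy if (noisy and self.y_noisy is not None) else self.y
        return EyeTrace(self.times.copy(), np.array(x), np.array(y),
                        eye=self.eye, epochs=self.epochs)


# --------------------------------------------------------------------------
# parameter blocks
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SceneParams:
    """Rendering parameters for synthetic seven-dot pseudopupil frames."""

    frame_size: tuple[int, int] = (128, 128)  # (height, width) px
    dot_spacing_px: float = 12.0
    dot_sigma_px: float = 2.0
    dot_amplitude: float = 150.0
    noise_sigma: float = 2.0
    background: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dot_spacing_px <= 0:
            raise ValueError("dot_spacing_px must be positive")
        if self.dot_sigma_px <= 0:
            raise ValueError("dot_sigma_px must be positive")


@dataclass(frozen=True)
class OkrParams:
    """Parameters of the optokinetic-trace generator.

    ``gain`` is the ratio of smooth tracking speed to stimulus speed; the
    smooth component moves *against* the stimulus direction (the fly lens
    forms an inverted image, so a lone retina must move opposite to the
    visual motion to slow the image down).  Counter-saccades (nystagmus)
    move in the stimulus direction, resetting the accumulated excursion,
    and obey a power-law main sequence v_peak = k*|A|**b realized through
    the waveform duration.
    """

    stimulus_speed: float = 15.0  # deg/s
    gain: float = 0.2
    nystagmus_rate: float = 0.0  # events/s during motion epochs
    k: float = 62.5  # main-sequence coefficient, deg^(1-b)/s
    b: float = 1.0  # main-sequence exponent
    noise_sigma_deg: float = 0.02
    sample_rate: float = DEFAULT_SAMPLE_RATE
    seed: int = 0
    amp_log_mu: float = 0.0  # ln degrees, counter-saccade amplitude draw
    amp_log_sigma: float = 0.5
    amp_range: tuple[float, float] = (0.3, 5.0)
    laterality: str = "bilateral"  # "bilateral" | "left" | "right"

    def __post_init__(self) -> None:
        if self.gain < 0:
            raise ValueError("gain must be non-negative")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.b <= 0:
            raise ValueError("main-sequence exponent b must be positive")


@dataclass(frozen=True)
class GapSessionParams:
    """Parameters of the head-fixed gap-crossing session generator.

    The wheel has two gaps 180 degrees apart; crossing the configured
    threshold in the forward direction marks a gap-crossing event.  At each
    crossing the two eyes execute mirror-symmetric convergent excursions of
    ``vergence_amplitude`` degrees (left eye +a, right eye -a) with a
    raised-cosine time course of ``vergence_timecourse`` seconds.
    """

    n_crossings: int = 5
    duration: float | None = None  # s; default min_interval*(n+1)
    wheel_speed: float = 20.0  # deg/s while advancing
    gap_offset_deg: float = 90.0  # wheel angle of the first gap
    gap_spacing_deg: float = 180.0  # two gaps per revolution
    crossing_times: tuple[float, ...] | None = None  # override event times
    min_interval: float = 20.0  # s between crossings
    vergence_amplitude: float = 2.0  # deg, per-eye excursion
    vergence_timecourse: float = 1.0  # s, full width of the raised cosine
    lighting_epochs: tuple[LightingEpoch, ...] = ()
    noise_sigma_deg: float = 0.02
    # wheel-angle measurement jitter; kept small (encoder-scale) so the
    # noisy trace's first threshold crossing stays within one sample of
    # the construction's crossing time
    wheel_noise: float = 0.02  # deg of wheel angle
    sample_rate: float = DEFAULT_SAMPLE_RATE
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_crossings < 0:
            raise ValueError("n_crossings must be >= 0")


@dataclass(frozen=True)
class GaussianRF:
    """2-D (or 1-D, elevation ignored) Gaussian receptive field."""

    center_az: float = 0.0
    center_el: float = 0.0
    sigma: float = 21.2  # deg; FWHM = 2*sigma*sqrt(2 ln 2) ~ 49.9 deg
    amplitude: float = 10.0  # mV
    baseline: float = -70.0  # mV

    def response(self, az, el=0.0) -> np.ndarray:
        az = np.asarray(az, dtype=float)
        el = np.asarray(el, dtype=float)
        r2 = (az - self.center_az) ** 2 + (el - self.center_el) ** 2
        return self.amplitude * np.exp(-r2 / (2.0 * self.sigma**2))


# --------------------------------------------------------------------------
# waveforms
# --------------------------------------------------------------------------

def minimum_jerk_step(t: np.ndarray, onset: float, duration: float,
                      amplitude: float) -> np.ndarray:
    """Minimum-jerk position step of ``amplitude`` starting at ``onset``.

    s(tau) = 10 tau^3 - 15 tau^4 + 6 tau^5 for tau in [0, 1]; the peak
    velocity is 1.875 * amplitude / duration at tau = 1/2.
    """
    tau = np.clip((np.asarray(t, dtype=float) - onset) / duration, 0.0, 1.0)
    return amplitude * (10 * tau**3 - 15 * tau**4 + 6 * tau**5)


def saccade_duration(amplitude: float, k: float, b: float,
                     min_duration: float = 0.010) -> float:
    """Waveform duration realizing v_peak = k*|A|**b for a minimum-jerk step."""
    a = abs(float(amplitude))
    if a == 0:
        return DEFAULT_SACCADE_RISE
    return max(MIN_JERK_PEAK * a / (k * a**b), min_duration)


# --------------------------------------------------------------------------
# gen_frames
# --------------------------------------------------------------------------

#: unit offsets of the seven pseudopupil dots: hexagon + center
_HEX_ANGLES = np.deg2rad(np.arange(0, 360, 60))
DOT_OFFSETS = np.vstack([[0.0, 0.0],
                         np.c_[np.cos(_HEX_ANGLES), np.sin(_HEX_ANGLES)]])


def gen_frames(traj: TrajectoryGT, scene: SceneParams,
               deg_per_spacing: float = 5.0,
               frame_rate: float | None = None,
               ) -> tuple[FrameStack, np.ndarray]:
    """Render a seven-dot pseudopupil stack following ``traj``.

    The cluster centroid follows the trajectory converted to pixels at
    ``dot_spacing_px / deg_per_spacing`` px/deg, starting from the frame
    center.  Returns the stack and the ground-truth pixel trajectory,
    shape (n_frames, 2) as (x=col, y=row); image y points down, so a
    positive trajectory y (up, head-centered) decreases the row.

    Raises ``ValueError`` naming the first offending sample if any dot
    would leave the frame.
    """
    h, w = scene.frame_size
    px_per_deg = scene.dot_spacing_px / float(deg_per_spacing)
    x = traj.x_noisy if traj.x_noisy is not None else traj.x
    y = traj.y_noisy if traj.y_noisy is not None else traj.y
    cx = (w - 1) / 2.0 + np.asarray(x) * px_per_deg
    cy = (h - 1) / 2.0 - np.asarray(y) * px_per_deg
    margin = scene.dot_spacing_px + 3.0 * scene.dot_sigma_px
    bad = np.nonzero((cx < margin) | (cx > w - 1 - margin)
                     | (cy < margin) | (cy > h - 1 - margin))[0]
    if bad.size:
        i = int(bad[0])
        raise ValueError(
            f"trajectory leaves the frame at sample {i} "
            f"(t={traj.times[i]:.3f}s, center=({cx[i]:.1f},{cy[i]:.1f}) px)")

    rng = np.random.default_rng(scene.seed)
    n = cx.size
    frames = np.full((n, h, w), scene.background, dtype=float)
    half = int(np.ceil(4 * scene.dot_sigma_px))
    patch = np.arange(-half, half + 1)
    for i in range(n):
        for ox, oy in DOT_OFFSETS:
            dx = cx[i] + ox * scene.dot_spacing_px
            dy = cy[i] - oy * scene.dot_spacing_px  # image y points down
            c0, r0 = int(round(dx)), int(round(dy))
            cols = patch + c0
            rows = patch + r0
            gx = np.exp(-((cols - dx) ** 2) / (2 * scene.dot_sigma_px**2))
            gy = np.exp(-((rows - dy) ** 2) / (2 * scene.dot_sigma_px**2))
            frames[i, r0 - half:r0 + half + 1, c0 - half:c0 + half + 1] += (
                scene.dot_amplitude * np.outer(gy, gx))
    if scene.noise_sigma > 0:
        frames += rng.normal(0.0, scene.noise_sigma, size=frames.shape)

    if frame_rate is None:
        if traj.times.size >= 2:
            frame_rate = 1.0 / float(np.median(np.diff(traj.times)))
        else:
            frame_rate = DEFAULT_SAMPLE_RATE
    return FrameStack(frames, frame_rate), np.c_[cx, cy]


# --------------------------------------------------------------------------
# gen_okr_trace
# --------------------------------------------------------------------------

def _default_epochs(duration: float, params: OkrParams,
                    direction: int) -> tuple[StimulusEpoch, ...]:
    return (StimulusEpoch(0.0, duration, direction=direction,
                          speed=params.stimulus_speed,
                          laterality=params.laterality),)


def _one_okr_eye(params: OkrParams, duration: float,
                 epochs: tuple[StimulusEpoch, ...],
                 stimulated: bool, eye: str,
                 rng: np.random.Generator) -> TrajectoryGT:
    dt = 1.0 / params.sample_rate
    times = np.arange(0.0, duration, dt)
    smooth_v = np.zeros_like(times)
    if stimulated:
        for ep in epochs:
            if ep.direction == 0 or ep.speed == 0:
                continue
            sel = (times >= ep.start) & (times < ep.end)
            smooth_v[sel] = -ep.direction * params.gain * ep.speed
    smooth_x = np.concatenate([[0.0], np.cumsum(smooth_v[:-1] * dt)])

    events: list[SaccadeEventGT] = []
    sacc_x = np.zeros_like(times)
    if stimulated and params.nystagmus_rate > 0:
        t = 0.0
        last_end = -np.inf
        while True:
            t += rng.exponential(1.0 / params.nystagmus_rate)
            if t >= duration - 0.5:
                break
            ep = next((e for e in epochs
                       if e.start <= t < e.end and e.direction != 0), None)
            if ep is None or t < last_end + 0.15:
                continue
            amp = float(np.exp(rng.normal(params.amp_log_mu,
                                          params.amp_log_sigma)))
            amp = float(np.clip(amp, *params.amp_range))
            # counter-saccade: opposite to the smooth tracking movement,
            # i.e. in the stimulus direction
            signed = amp * ep.direction
            dur = saccade_duration(amp, params.k, params.b)
            sacc_x += minimum_jerk_step(times, t, dur, signed)
            events.append(SaccadeEventGT(t, t + dur, signed))
            last_end = t + dur

    x = smooth_x + sacc_x
    y = np.zeros_like(times)
    xn = x + rng.normal(0.0, params.noise_sigma_deg, size=times.shape) \
        if params.noise_sigma_deg > 0 else x.copy()
    yn = y + rng.normal(0.0, params.noise_sigma_deg, size=times.shape) \
        if params.noise_sigma_deg > 0 else y.copy()
    return TrajectoryGT(times=times, x=x, y=y, smooth_x=smooth_x,
                        smooth_y=y.copy(), saccade_events=tuple(events),
                        x_noisy=xn, y_noisy=yn, eye=eye, epochs=epochs)


def gen_okr_trace(params: OkrParams, duration: float,
                  direction: int = 1,
                  epochs: Sequence[StimulusEpoch] | None = None,
                  ) -> tuple[TrajectoryGT, TrajectoryGT]:
    """Generate a binocular (left, right) optokinetic trajectory pair.

    The smooth component has velocity ``-direction * gain * stimulus_speed``
    during motion epochs; counter-saccades occur at ``nystagmus_rate`` and
    move with the stimulus (against the tracking).  With unilateral
    ``params.laterality`` the unstimulated eye stays flat (plus noise),
    mirroring single-eye grating stimulation.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    eps = tuple(epochs) if epochs is not None else _default_epochs(
        duration, params, direction)
    rng = np.random.default_rng(params.seed)
    left = _one_okr_eye(params, duration, eps,
                        params.laterality in ("bilateral", "left"),
                        "left", rng)
    right = _one_okr_eye(params, duration, eps,
                         params.laterality in ("bilateral", "right"),
                         "right", rng)
    return left, right


def gen_saccade_train(params: OkrParams, duration: float,
                      rate: float = 0.5,
                      amplitudes: Sequence[float] | None = None,
                      eye: str = "right") -> TrajectoryGT:
    """Spontaneous saccade train on a stationary scene (no smooth drift).

    Saccades occur at ``rate`` events/s (or at evenly spaced times when
    explicit signed ``amplitudes`` are given), with random sign and
    amplitudes drawn from the params' lognormal unless provided.  Peak
    velocity follows the main sequence v_peak = k*|A|**b through the
    waveform duration.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(params.seed)
    dt = 1.0 / params.sample_rate
    times = np.arange(0.0, duration, dt)
    x = np.zeros_like(times)
    events: list[SaccadeEventGT] = []
    if amplitudes is not None:
        amps = list(amplitudes)
        onsets = np.linspace(0.5, duration - 0.5, len(amps))
    else:
        onsets = []
        t = 0.0
        while True:
            t += rng.exponential(1.0 / rate)
            if t >= duration - 0.5:
                break
            if onsets and t < onsets[-1] + 0.3:
                continue
            onsets.append(t)
        amps = [float(np.clip(np.exp(rng.normal(params.amp_log_mu,
                                                params.amp_log_sigma)),
                              *params.amp_range)) * rng.choice([-1, 1])
                for _ in onsets]
    for t0, amp in zip(onsets, amps):
        dur = saccade_duration(amp, params.k, params.b)
        x += minimum_jerk_step(times, float(t0), dur, float(amp))
        events.append(SaccadeEventGT(float(t0), float(t0) + dur, float(amp)))
    y = np.zeros_like(times)
    xn = x + rng.normal(0.0, params.noise_sigma_deg, size=times.shape) \
        if params.noise_sigma_deg > 0 else x.copy()
    yn = y + rng.normal(0.0, params.noise_sigma_deg, size=times.shape) \
        if params.noise_sigma_deg > 0 else y.copy()
    return TrajectoryGT(times=times, x=x, y=y, smooth_x=np.zeros_like(x),
                        smooth_y=y.copy(), saccade_events=tuple(events),
                        x_noisy=xn, y_noisy=yn, eye=eye)


# --------------------------------------------------------------------------
# gen_gap_session
# --------------------------------------------------------------------------

def poisson_crossing_times(epochs: Sequence[LightingEpoch],
                           rates: dict[str, float],
                           rng: np.random.Generator,
                           min_interval: float = 0.0) -> np.ndarray:
    """Draw Poisson-process crossing times with a per-lighting-epoch rate."""
    times: list[float] = []
    for ep in epochs:
        lam = rates.get(ep.label, 0.0)
        if lam <= 0:
            continue
        t = ep.start
        while True:
            t += rng.exponential(1.0 / lam)
            if t >= ep.end:
                break
            if not times or t - times[-1] >= min_interval:
                times.append(t)
    return np.asarray(times)


def gen_gap_session(params: GapSessionParams,
                    ) -> tuple[GapSession, np.ndarray]:
    """Generate a gap-crossing session plus ground-truth crossing times.

    The wheel advances monotonically, passing one gap threshold (levels
    ``gap_offset + k*gap_spacing`` of the unwrapped angle) at each
    configured crossing time; between crossings it dwells below the next
    level.  Eye traces carry a convergent vergence pulse at each crossing.
    """
    rng = np.random.default_rng(params.seed)
    if params.crossing_times is not None:
        t_cross = np.sort(np.asarray(params.crossing_times, dtype=float))
        n = t_cross.size
        duration = params.duration or (float(t_cross[-1]) + params.min_interval
                                       if n else 60.0)
    else:
        n = params.n_crossings
        duration = params.duration or params.min_interval * (n + 1)
        if n > 0:
            if duration < params.min_interval * (n + 0.5):
                raise ValueError(
                    f"duration {duration:.0f}s too short for {n} crossings "
                    f"at min_interval {params.min_interval:.0f}s")
            base = np.linspace(params.min_interval * 0.75,
                               duration - params.min_interval * 0.75, n)
            jit = rng.uniform(-0.1, 0.1, size=n) * params.min_interval
            t_cross = np.sort(base + jit)
        else:
            t_cross = np.empty(0)

    dt = 1.0 / params.sample_rate
    times = np.arange(0.0, duration, dt)

    # wheel: smooth monotone, hitting level k at t_cross[k].  Between
    # crossings the fly advances most of the way early, then creeps up to
    # the threshold; implemented as piecewise-linear interpolation of the
    # unwrapped angle through knots placed below each upcoming level.
    levels = params.gap_offset_deg + params.gap_spacing_deg * np.arange(n)
    knot_t = [0.0]
    knot_a = [levels[0] - params.gap_spacing_deg * 0.75 if n
              else 0.0]
    for k, tc in enumerate(t_cross):
        # steep final approach (wheel_speed deg/s over 0.5 s) so that the
        # threshold crossing is sharp relative to wheel noise
        approach = max(tc - 0.5, knot_t[-1] + dt)
        knot_t += [approach, float(tc)]
        knot_a += [levels[k] - params.wheel_speed * 0.5, levels[k]]
    knot_t.append(duration)
    knot_a.append((levels[-1] + params.gap_spacing_deg * 0.25) if n
                  else params.wheel_speed * 0.05 * duration)
    # enforce strictly increasing knots in both axes
    knot_t = np.maximum.accumulate(np.asarray(knot_t))
    knot_a = np.maximum.accumulate(np.asarray(knot_a))
    wheel = np.interp(times, knot_t, knot_a)
    if params.wheel_noise > 0:
        wheel = wheel + rng.normal(0.0, params.wheel_noise, size=times.shape)

    pulse_l = np.zeros_like(times)
    for tc in t_cross:
        half = params.vergence_timecourse / 2.0
        sel = np.abs(times - tc) <= half
        pulse_l[sel] += params.vergence_amplitude * 0.5 * (
            1 + np.cos(np.pi * (times[sel] - tc) / half))
    # raised cosine peaks at vergence_amplitude; left +, right - (convergent)
    xl = pulse_l + rng.normal(0.0, params.noise_sigma_deg, size=times.shape)
    xr = -pulse_l + rng.normal(0.0, params.noise_sigma_deg, size=times.shape)
    yl = rng.normal(0.0, params.noise_sigma_deg, size=times.shape)
    yr = rng.normal(0.0, params.noise_sigma_deg, size=times.shape)

    lighting = params.lighting_epochs or (LightingEpoch("on", 0.0, duration),)
    session = GapSession(
        times=times, wheel=wheel,
        left=EyeTrace(times.copy(), xl, yl, eye="left"),
        right=EyeTrace(times.copy(), xr, yr, eye="right"),
        lighting=tuple(lighting))
    return session, t_cross


# --------------------------------------------------------------------------
# gen_bar_sweep
# --------------------------------------------------------------------------

def gen_bar_sweep(shift_deg: float, latency_s: float,
                  rf: GaussianRF | None = None,
                  bar_speed: float = 21.0,
                  screen_range: tuple[float, float] = (-60.0, 60.0),
                  grid_step: float = 0.21,
                  n_trials: int = 7,
                  noise_sigma_mV: float = 0.0,
                  seed: int = 0) -> dict[tuple[str, int], TuningCurve]:
    """Generate bar-sweep tuning curves for two retinal positions x two directions.

    Returns a dict keyed by ``(condition, direction)`` with condition in
    {"control", "activated"} and direction +1 (rightward) / -1 (leftward).
    The activated-condition curve is the control curve translated by
    ``shift_deg`` in screen coordinates; a fixed response latency adds a
    direction-signed screen offset of ``bar_speed * latency_s``.

    The default ``grid_step`` of 0.21 degrees corresponds to membrane
    voltage binned at 10 ms during a 21 deg/s sweep (curves are Vm time
    series mapped to screen position via the bar speed); coarser grids
    emulate discrete stimulus positions.
    """
    rf = rf or GaussianRF(sigma=8.0)
    lo, hi = screen_range
    if not (lo < rf.center_az - rf.sigma and hi > rf.center_az + shift_deg + rf.sigma):
        raise ValueError("screen range must cover the receptive field at "
                         "both retinal positions")
    positions = np.arange(lo, hi + 1e-9, grid_step)
    rng = np.random.default_rng(seed)
    out: dict[tuple[str, int], TuningCurve] = {}
    for condition, cond_shift in (("control", 0.0), ("activated", shift_deg)):
        for direction in (+1, -1):
            center = rf.center_az + cond_shift + direction * bar_speed * latency_s
            mean = rf.amplitude * np.exp(
                -((positions - center) ** 2) / (2 * rf.sigma**2))
            trials = np.tile(mean, (n_trials, 1))
            if noise_sigma_mV > 0:
                trials = trials + rng.normal(0.0, noise_sigma_mV, trials.shape)
            out[(condition, direction)] = TuningCurve(
                positions.copy(), trials, direction=direction,
                condition=condition)
    return out


# --------------------------------------------------------------------------
# gen_flash_grid
# --------------------------------------------------------------------------

@dataclass
class FlashGridRecords:
    """Flash-response records plus timing metadata.

    ``records`` is a pandas DataFrame with columns (position_az,
    position_el, trial, time_s, vm_mV); each flash occurs at time 0 and
    lasts ``flash_dur`` seconds; the modeled depolarization lasts
    ``response_dur`` seconds from flash onset.
    """

    records: "object"  # pandas.DataFrame
    flash_onset: float
    flash_dur: float
    response_dur: float


def gen_flash_grid(rf: GaussianRF,
                   grid_az: Sequence[float],
                   grid_el: Sequence[float] = (0.0,),
                   flash_dur: float = 0.1,
                   response_dur: float = 0.2,
                   n_trials: int = 3,
                   sample_rate: float = 1000.0,
                   t_pre: float = 0.1, t_post: float = 0.3,
                   noise_sigma_mV: float = 0.0,
                   seed: int = 0) -> FlashGridRecords:
    """Generate membrane-voltage responses to flashes on a screen grid.

    The response amplitude at each grid position equals the Gaussian RF
    evaluated there (on top of ``rf.baseline``), held for ``response_dur``
    from flash onset.
    """
    import pandas as pd

    grid_az = np.asarray(list(grid_az), dtype=float)
    grid_el = np.asarray(list(grid_el), dtype=float)
    if grid_az.size == 0 or grid_el.size == 0:
        raise ValueError("grid must be non-empty")
    rng = np.random.default_rng(seed)
    t = np.arange(-t_pre, t_post, 1.0 / sample_rate)
    kernel = ((t >= 0) & (t < response_dur)).astype(float)
    rows = []
    for el in grid_el:
        for az in grid_az:
            amp = float(rf.response(az, el))
            for trial in range(n_trials):
                vm = rf.baseline + amp * kernel
                if noise_sigma_mV > 0:
                    vm = vm + rng.normal(0.0, noise_sigma_mV, size=t.shape)
                rows.append(pd.DataFrame({
                    "position_az": az, "position_el": el, "trial": trial,
                    "time_s": t, "vm_mV": vm}))
    records = pd.concat(rows, ignore_index=True)
    return FlashGridRecords(records, 0.0, flash_dur, response_dur)


# --------------------------------------------------------------------------
# gen_crossing_trajectories
# --------------------------------------------------------------------------

@dataclass
class CrossingTrajectories:
    """Free-walking gap-crossing paths for one group of flies.

    ``paths[i]`` is the list of (n, 2) x-y arrays (mm) for fly i;
    ``minima[i]`` the ground-truth minimum y of each of fly i's paths.
    """

    paths: list[list[np.ndarray]]
    minima: list[np.ndarray]


def gen_crossing_trajectories(group_mean_y: float,
                              group_sd: float,
                              n_flies: int = 20,
                              crossings_per_fly: int = 10,
                              gap_length: float = 3.5,
                              n_points: int = 61,
                              seed: int = 0) -> CrossingTrajectories:
    """Generate per-fly x-y gap-crossing paths with group-dependent depth.

    Each cross's minimum y is drawn i.i.d. from N(group_mean_y, group_sd)
    (clipped below the gap rim); each path descends from y=0 to its
    minimum at mid-gap and ascends back across the gap.
    """
    if n_flies < 1:
        raise ValueError("n_flies must be >= 1")
    rng = np.random.default_rng(seed)
    x = np.linspace(0.0, gap_length, n_points)
    # 0 at the walls, exactly 1 at mid-gap (odd n_points puts a sample there)
    shape = np.sin(np.pi * x / gap_length) ** 2
    paths: list[list[np.ndarray]] = []
    minima: list[np.ndarray] = []
    for _ in range(n_flies):
        mins = group_mean_y + group_sd * rng.standard_normal(crossings_per_fly)
        mins = np.minimum(mins, -1e-6)  # paths must dip below the rim
        paths.append([np.c_[x, m * shape] for m in mins])
        minima.append(mins)
    return CrossingTrajectories(paths, minima)
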