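"""Shared containers and exceptions for the pseudopupil pipeline.

Conventions used throughout the package:

* Angular eye/retina positions are in **degrees**, head-centered, with +x
  toward the fly's right and +y up, identical for both eyes.  "Retinal
  shift" means deep-pseudopupil shift in these coordinates.
* Time is in **seconds**; traces are uniformly sampled after ingest.
* Pixel coordinates are image coordinates internally: origin at the
  top-left pixel center, x rightward (column), y downward (row).  The
  y-axis is flipped when converting to the head-centered frame.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np


# --------------------------------------------------------------------------
# errors
# --------------------------------------------------------------------------

class PseudopupilError(Exception):
    """Base class for pipeline errors."""


class NoPupilFound(PseudopupilError):
    """No connected component above threshold in a frame."""


class AmbiguousScene(PseudopupilError):
    """Too many above-threshold components to identify a pseudopupil."""


class TrackingError(PseudopupilError):
    """Tracking failed on every frame of a stack."""


class SchemaError(PseudopupilError):
    """An input table violates the expected schema."""


class ConfigError(PseudopupilError):
    """A run configuration is invalid."""


# --------------------------------------------------------------------------
# stimulus / session metadata
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class StimulusEpoch:
    """One labeled stimulus interval attached to a trace.

    ``direction`` is +1 for rightward (or upward) stimulus motion, -1 for
    the opposite, 0 for a stationary scene.  ``laterality`` is
    ``"bilateral"``, ``"left"`` or ``"right"``.
    """

    start: float
    end: float
    direction: int = 0
    speed: float = 0.0
    laterality: str = "bilateral"
    label: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"epoch end {self.end} must exceed start {self.start}")


@dataclass(frozen=True)
class LightingEpoch:
    """A labeled lighting interval (e.g. ``on`` / ``dark``) of a session."""

    label: str
    start: float
    end: float


# --------------------------------------------------------------------------
# traces and stacks
# --------------------------------------------------------------------------

@dataclass
class EyeTrace:
    """Time-stamped 2-D retinal (pseudopupil) position, in degrees, for one eye."""

    times: np.ndarray
    x: np.ndarray
    y: np.ndarray
    eye: str = "right"
    epochs: tuple[StimulusEpoch, ...] = ()

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (self.times.shape == self.x.shape == self.y.shape):
            raise ValueError("times, x and y must have identical shapes")
        if self.times.size >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    @property
    def sample_rate(self) -> float:
        if self.times.size < 2:
            raise ValueError("sample rate undefined for <2 samples")
        return 1.0 / float(np.median(np.diff(self.times)))

    @property
    def dt(self) -> float:
        return 1.0 / self.sample_rate

    def copy(self) -> "EyeTrace":
        return EyeTrace(self.times.copy(), self.x.copy(), self.y.copy(),
                        self.eye, self.epochs)


@dataclass
class FrameStack:
    """Ordered grayscale frames with acquisition rate.

    ``frames`` has shape (n_frames, height, width); all frames share one
    shape by construction.
    """

    frames: np.ndarray
    frame_rate: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n, h, w) array")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate


@dataclass(frozen=True)
class Calibration:
    """Pixel-to-degree calibration through the inter-photoreceptor spacing.

    ``px_per_spacing`` is measured from the dot pattern of the deep
    pseudopupil; ``deg_per_spacing`` defaults to the inter-ommatidial angle
    Δϕ = 5° and is shared with the aliasing model.
    """

    px_per_spacing: float
    deg_per_spacing: float = 5.0

    def __post_init__(self) -> None:
        if self.px_per_spacing <= 0 or self.deg_per_spacing <= 0:
            raise ValueError("calibration factors must be strictly positive")


@dataclass
class DotSet:
    """Sub-pixel centroids of the bright pseudopupil dots in one frame.

    ``centroids`` is (k, 2) in image (x=col, y=row) pixel coordinates,
    1 <= k <= 7; ``centroid`` is the intensity-weighted center of mass over
    all member pixels of the retained components.
    """

    centroids: np.ndarray
    intensities: np.ndarray
    centroid: np.ndarray

    @property
    def n_dots(self) -> int:
        return int(self.centroids.shape[0])


# --------------------------------------------------------------------------
# events and fits
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Saccade:
    """A detected rapid eye-movement event.

    Amplitudes are signed, per axis, in degrees; ``peak_velocity`` is the
    maximum 2-D speed within the event, in deg/s.
    """

    onset: float
    offset: float
    amp_x: float
    amp_y: float
    peak_velocity: float

    def __post_init__(self) -> None:
        if self.offset <= self.onset:
            raise ValueError("saccade offset must exceed onset")

    @property
    def amplitude(self) -> float:
        """Unsigned 2-D amplitude in degrees."""
        return float(np.hypot(self.amp_x, self.amp_y))

    @property
    def direction(self) -> np.ndarray:
        """Unit vector of the displacement (zero vector if amplitude 0)."""
        a = self.amplitude
        if a == 0:
            return np.zeros(2)
        return np.array([self.amp_x, self.amp_y]) / a


@dataclass(frozen=True)
class MainSequenceFit:
    """Power-law fit v_peak = k * |A|**b on log-log axes."""

    k: float
    b: float
    r: float
    n: int


# --------------------------------------------------------------------------
# binocular session
# --------------------------------------------------------------------------

@dataclass
class GapSession:
    """Synchronized wheel trace + binocular eye traces + lighting metadata.

    All channels share ``times``.  Wheel position is in unwrapped degrees of
    wheel rotation; forward walking increases it.
    """

    times: np.ndarray
    wheel: np.ndarray
    left: EyeTrace
    right: EyeTrace
    lighting: tuple[LightingEpoch, ...] = ()

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.wheel = np.asarray(self.wheel, dtype=float)
        if self.times.shape != self.wheel.shape:
            raise ValueError("wheel trace must share the session time base")
        for tr in (self.left, self.right):
            if tr.times.shape != self.times.shape or not np.allclose(tr.times, self.times):
                raise ValueError("eye traces must share the session time base")

    @property
    def dt(self) -> float:
        return float(np.median(np.diff(self.times)))

    def lighting_label(self, t: float) -> str:
        for ep in self.lighting:
            if ep.start <= t < ep.end:
                return ep.label
        return ""


@dataclass(frozen=True)
class CrossingEvent:
    """A wheel-threshold crossing (gap crossing)."""

    time: float
    direction: str  # "forward" | "backward"
    lighting: str = ""


# --------------------------------------------------------------------------
# tuning curves and receptive fields
# --------------------------------------------------------------------------

@dataclass
class TuningCurve:
    """Stimulus-position-indexed mean response (e.g. Vm vs bar position).

    ``positions`` are screen coordinates in degrees, strictly monotonic;
    ``trials`` is (n_trials, n_positions); ``mean`` is the trial mean.
    """

    positions: np.ndarray
    trials: np.ndarray
    direction: int = 0  # bar sweep direction, +1 rightward / -1 leftward
    condition: str = "control"

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.trials = np.atleast_2d(np.asarray(self.trials, dtype=float))
        if self.trials.shape[1] != self.positions.size:
            raise ValueError("trials must have one column per position")
        d = np.diff(self.positions)
        if self.positions.size >= 2 and not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("positions must be strictly monotonic")
        if np.any(np.diff(self.positions) < 0):  # store ascending
            self.positions = self.positions[::-1].copy()
            self.trials = self.trials[:, ::-1].copy()

    @property
    def mean(self) -> np.ndarray:
        return self.trials.mean(axis=0)

    @property
    def n_trials(self) -> int:
        return int(self.trials.shape[0])


@dataclass
class RFMap:
    """Grid receptive-field map: response amplitude per screen position."""

    azimuths: np.ndarray
    elevations: np.ndarray
    amplitude: np.ndarray  # (n_el, n_az)

    @property
    def peak_position(self) -> tuple[float, float]:
        i, j = np.unravel_index(int(np.argmax(self.amplitude)), self.amplitude.shape)
        return float(self.azimuths[j]), float(self.elevations[i])


@dataclass(frozen=True)
class ShiftEstimate:
    """Angular shift between two tuning curves, in screen degrees."""

    shift: float
    quality: float  # peak normalized correlation
    per_direction: tuple[float, ...] = ()


# --------------------------------------------------------------------------
# triggered averages
# --------------------------------------------------------------------------

@dataclass
class TriggeredAverage:
    """Event-triggered snippets and their mean, per channel."""

    lags: np.ndarray
    means: dict[str, np.ndarray]
    snippets: dict[str, np.ndarray]  # (n_events, n_lags) per channel
    n_events: int
    n_excluded: int
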