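"""Deep-pseudopupil detection, sub-pixel tracking and degree calibration.

The deep pseudopupil appears as seven bright dots (one ommatidium's
receptor array, magnified) in an infrared image of the compound eye.  Its
intensity-weighted center of mass is a proxy for retinal position.  Pixel
displacements are converted to degrees through the inter-photoreceptor
spacing of the dot pattern: one spacing corresponds to one
inter-ommatidial angle (default 5 degrees).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .types import (
    AmbiguousScene,
    Calibration,
    DotSet,
    EyeTrace,
    FrameStack,
    NoPupilFound,
    TrackingError,
)


@dataclass(frozen=True)
class TrackerConfig:
    """Detection and tracking parameters.

    The detection threshold is ``median + threshold_k * MAD`` of the frame
    (robust to illumination level); when the MAD is zero (noise-free
    frames) Otsu's threshold is used instead.  ``fill_policy`` for frames
    that fail detection is ``"hold"`` (repeat last good position) or
    ``"gap"`` (NaN).
    """

    threshold_k: float = 6.0
    min_area: int = 3  # px, reject single-pixel noise components
    max_dots: int = 7
    max_components: int = 40
    fill_policy: str = "hold"


def detect_pseudopupil(frame: np.ndarray,
                       cfg: TrackerConfig | None = None) -> DotSet:
    """Detect the bright dot cluster in one frame.

    Pixels above threshold are grouped into connected components, ranked
    by integrated (background-subtracted) intensity, and up to
    ``cfg.max_dots`` are retained.  The cluster centroid is the
    intensity-weighted center of mass over all retained member pixels,
    giving sub-pixel precision.
    """
    cfg = cfg or TrackerConfig()
    frame = np.asarray(frame, dtype=float)
    if frame.size == 0:
        raise NoPupilFound("empty frame")
    bg = float(np.median(frame))
    mad = float(np.median(np.abs(frame - bg)))
    if mad > 0:
        thr = bg + cfg.threshold_k * mad
    elif frame.max() > frame.min():
        thr = float(threshold_otsu(frame))
    else:
        raise NoPupilFound("frame has no intensity variation")
    mask = frame > thr
    if not mask.any():
        raise NoPupilFound(f"no pixel above threshold {thr:.1f}")
    labels, n_comp = ndimage.label(mask)
    if n_comp > cfg.max_components:
        raise AmbiguousScene(
            f"{n_comp} components above threshold (max {cfg.max_components})")

    weights = np.clip(frame - bg, 0.0, None)
    idx = np.arange(1, n_comp + 1)
    integrated = ndimage.sum_labels(weights, labels, idx)
    areas = ndimage.sum_labels(np.ones_like(frame), labels, idx)
    keep = idx[areas >= cfg.min_area]
    if keep.size == 0:
        raise NoPupilFound("all components below minimum area")
    keep = keep[np.argsort(integrated[keep - 1])[::-1][:cfg.max_dots]]

    centroids = []
    intensities = []
    for lab in keep:
        rows, cols = np.nonzero(labels == lab)
        w = weights[rows, cols]
        s = w.sum()
        centroids.append((float((cols * w).sum() / s),
                          float((rows * w).sum() / s)))
        intensities.append(float(s))
    rows, cols = np.nonzero(np.isin(labels, keep))
    w = weights[rows, cols]
    s = w.sum()
    cluster = np.array([float((cols * w).sum() / s),
                        float((rows * w).sum() / s)])
    order = np.argsort(intensities)[::-1]
    return DotSet(centroids=np.asarray(centroids)[order],
                  intensities=np.asarray(intensities)[order],
                  centroid=cluster)


@dataclass
class TrackResult:
    """Per-frame cluster centroid in pixels with quality flags."""

    times: np.ndarray
    x_px: np.ndarray
    y_px: np.ndarray
    quality: np.ndarray  # bool, True where detection succeeded
    dots: DotSet  # from the first successfully detected frame


def track_stack(stack: FrameStack,
                cfg: TrackerConfig | None = None) -> TrackResult:
    """Track the pseudopupil centroid across a frame stack.

    Frames failing detection are flagged; their position is filled
    according to ``cfg.fill_policy`` so the trace length always equals the
    stack length.  Raises ``TrackingError`` if every frame fails.
    """
    cfg = cfg or TrackerConfig()
    if stack.n_frames < 1:
        raise TrackingError("empty stack")
    n = stack.n_frames
    x = np.full(n, np.nan)
    y = np.full(n, np.nan)
    ok = np.zeros(n, dtype=bool)
    first_dots: DotSet | None = None
    for i in range(n):
        try:
            dots = detect_pseudopupil(stack.frames[i], cfg)
        except (NoPupilFound, AmbiguousScene):
            continue
        x[i], y[i] = dots.centroid
        ok[i] = True
        if first_dots is None:
            first_dots = dots
    if first_dots is None:
        raise TrackingError("pseudopupil detection failed on every frame")
    if cfg.fill_policy == "hold":
        # forward-fill from the last good sample; leading gaps take the
        # first good value
        last = np.where(ok, np.arange(n), -1)
        last = np.maximum.accumulate(last)
        first_good = int(np.argmax(ok))
        last[last < 0] = first_good
        x = x[last]
        y = y[last]
    elif cfg.fill_policy != "gap":
        raise ValueError(f"unknown fill_policy {cfg.fill_policy!r}")
    return TrackResult(stack.times, x, y, ok, first_dots)


def estimate_spacing(dots: DotSet) -> float:
    """Median distance from the central dot to the others, in pixels.

    The central dot is the one nearest the cluster centroid; in the
    hexagon-plus-center pseudopupil pattern the median center-to-neighbor
    distance is the inter-photoreceptor spacing.
    """
    if dots.n_dots < 2:
        raise ValueError("need at least 2 dots to estimate spacing")
    d_center = np.linalg.norm(dots.centroids - dots.centroid, axis=1)
    c = int(np.argmin(d_center))
    others = np.delete(np.arange(dots.n_dots), c)
    dist = np.linalg.norm(dots.centroids[others] - dots.centroids[c], axis=1)
    return float(np.median(dist))


def to_degrees(track: TrackResult, calib: Calibration,
               reference: tuple[float, float] | str = "mean",
               eye: str = "right") -> EyeTrace:
    """Convert a pixel trace to a head-centered EyeTrace in degrees.

    ``x_deg = (x_px - ref_x) / px_per_spacing * deg_per_spacing``; the
    image y-axis (down) is flipped so +y points up.  ``reference`` is the
    pixel origin: the trace mean by default, or an explicit ``(x, y)``.
    """
    if calib.px_per_spacing == 0:
        raise ValueError("px_per_spacing must be non-zero")
    if reference == "mean":
        ref_x = float(np.nanmean(track.x_px))
        ref_y = float(np.nanmean(track.y_px))
    else:
        ref_x, ref_y = map(float, reference)
    scale = calib.deg_per_spacing / calib.px_per_spacing
    x_deg = (track.x_px - ref_x) * scale
    y_deg = -(track.y_px - ref_y) * scale
    return EyeTrace(track.times, x_deg, y_deg, eye=eye)
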