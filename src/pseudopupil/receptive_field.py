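"""Receptive-field maps, tuning-curve widths and angular shift estimation.

Flash-grid responses give a 2-D receptive-field (RF) map (response-window
mean minus baseline-window mean per screen position).  Bar-sweep tuning
curves measured at two retinal positions are compared by normalized
cross-correlation to estimate the angular RF shift; because a fixed
response latency displaces the curves for the two sweep directions by
equal and opposite screen offsets (offset = bar_speed * latency), the
per-direction shift estimates are averaged to cancel the latency bias.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .synthetic import FlashGridRecords
from .types import RFMap, ShiftEstimate, TuningCurve


# --------------------------------------------------------------------------
# flash-grid RF map
# --------------------------------------------------------------------------

def rf_map(flashes: FlashGridRecords,
           response_window: tuple[float, float] = (0.0, 0.2),
           baseline_window: tuple[float, float] = (-0.1, 0.0),
           strict_windows: bool = True) -> RFMap:
    """Receptive-field map from flash responses.

    Per grid position: mean voltage in the response window minus mean in
    the baseline window, averaged over repeats.  With ``strict_windows``
    the baseline window must end by flash onset and the response window
    must start at or after it.
    """
    if strict_windows:
        if baseline_window[1] > flashes.flash_onset + 1e-12:
            raise ValueError("baseline window overlaps the flash")
        if response_window[0] < flashes.flash_onset - 1e-12:
            raise ValueError("response window starts before the flash")
    df = flashes.records
    t = df["time_s"]
    resp = df[(t >= response_window[0]) & (t < response_window[1])]
    base = df[(t >= baseline_window[0]) & (t < baseline_window[1])]
    keys = ["position_el", "position_az", "trial"]
    amp = (resp.groupby(keys)["vm_mV"].mean()
           - base.groupby(keys)["vm_mV"].mean())
    per_pos = amp.groupby(["position_el", "position_az"]).mean().unstack()
    return RFMap(azimuths=per_pos.columns.to_numpy(dtype=float),
                 elevations=per_pos.index.to_numpy(dtype=float),
                 amplitude=per_pos.to_numpy(dtype=float))


# --------------------------------------------------------------------------
# FWHM
# --------------------------------------------------------------------------

def rf_width(positions: np.ndarray, values: np.ndarray) -> float:
    """Full width at half of (peak - minimum), linear interpolation.

    Raises ``ValueError`` on a flat profile or when a half-maximum
    crossing lies outside the sampled support.
    """
    positions = np.asarray(positions, dtype=float)
    values = np.asarray(values, dtype=float)
    vmin, vmax = float(values.min()), float(values.max())
    if vmax <= vmin:
        raise ValueError("flat profile: width undefined")
    half = vmin + 0.5 * (vmax - vmin)
    ipk = int(np.argmax(values))

    def _cross(idx_range, reverse):
        seq = idx_range[::-1] if reverse else idx_range
        for i in seq:
            j = i + 1
            lo, hi = values[i], values[j]
            if (lo - half) * (hi - half) <= 0 and lo != hi:
                return positions[i] + (half - lo) / (hi - lo) * (
                    positions[j] - positions[i])
        raise ValueError("half-maximum crossing outside sampled support")

    left = _cross(range(0, ipk), reverse=True) if ipk > 0 else None
    right = _cross(range(ipk, values.size - 1), reverse=False) \
        if ipk < values.size - 1 else None
    if left is None or right is None:
        raise ValueError("half-maximum crossing outside sampled support")
    return float(right - left)


# --------------------------------------------------------------------------
# shift estimation
# --------------------------------------------------------------------------

def _norm_corr(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    den = np.sqrt((a * a).sum() * (b * b).sum())
    if den == 0:
        return 0.0
    return float((a * b).sum() / den)


def estimate_shift(curve_a: TuningCurve, curve_b: TuningCurve,
                   search_range: float = 20.0,
                   n_steps: int = 400,
                   min_overlap: float | None = None) -> ShiftEstimate:
    """Shift of ``curve_b`` relative to ``curve_a`` in screen degrees.

    Scans candidate shifts delta in [-search_range, +search_range],
    computing the normalized cross-correlation between a(p) and the
    linearly interpolated b(p + delta) over the overlapping support, then
    refines the peak by parabolic interpolation of the three samples
    around it.  Positive shift means curve_b is displaced toward positive
    screen positions (b(p) ~ a(p - shift)).
    """
    pa, ma = curve_a.positions, curve_a.mean
    pb, mb = curve_b.positions, curve_b.mean
    if min_overlap is None:
        min_overlap = 3 * float(np.median(np.diff(pa)))
    deltas = np.linspace(-search_range, search_range, n_steps + 1)
    corr = np.full(deltas.shape, -np.inf)
    for i, d in enumerate(deltas):
        lo = max(pa[0], pb[0] - d)
        hi = min(pa[-1], pb[-1] - d)
        if hi - lo < min_overlap:
            continue
        sel = (pa >= lo) & (pa <= hi)
        if sel.sum() < 4:
            continue
        bi = np.interp(pa[sel] + d, pb, mb)
        corr[i] = _norm_corr(ma[sel], bi)
    if not np.isfinite(corr).any():
        raise ValueError("insufficient overlap over the whole search range")
    k = int(np.argmax(corr))
    shift = float(deltas[k])
    quality = float(corr[k])
    if 0 < k < deltas.size - 1 and np.isfinite(corr[k - 1]) and np.isfinite(corr[k + 1]):
        y0, y1, y2 = corr[k - 1], corr[k], corr[k + 1]
        denom = y0 - 2 * y1 + y2
        if denom < 0:  # proper maximum
            frac = 0.5 * (y0 - y2) / denom
            step = deltas[1] - deltas[0]
            shift += float(np.clip(frac, -1, 1)) * step
            quality = float(y1 - 0.25 * (y0 - y2) * np.clip(frac, -1, 1))
    return ShiftEstimate(shift=shift, quality=quality)


def pool_directions(curve_pos: TuningCurve, curve_neg: TuningCurve,
                    condition: str = "pooled") -> TuningCurve:
    """Average the two sweep directions' curves onto a common position grid.

    A fixed response latency displaces the two directions' curves by
    equal and opposite screen offsets (offset = bar_speed * latency), so
    the pooled curve is centered on the latency-free receptive-field
    position.
    """
    pos = curve_pos.positions
    interp = np.interp(pos, curve_neg.positions, curve_neg.mean)
    pooled = 0.5 * (curve_pos.mean + interp)
    return TuningCurve(pos.copy(), pooled[None, :], direction=0,
                       condition=condition)


def combine_directions(sweeps: Mapping[tuple[str, int], TuningCurve],
                       search_range: float = 20.0) -> ShiftEstimate:
    """Latency-cancelling combined shift between control and activated curves.

    ``sweeps`` maps ``(condition, direction)`` to a TuningCurve, with
    condition in {"control", "activated"} and direction +1/-1.  Each
    direction's activated curve is compared against the direction-pooled
    control curve: the per-direction estimates therefore carry the
    latency offsets +/- bar_speed*latency, which are equal and opposite,
    so their average is the latency-free retinal shift.
    """
    for d in (+1, -1):
        for cond in ("control", "activated"):
            if (cond, d) not in sweeps:
                raise KeyError(f"missing sweep ({cond!r}, {d:+d})")
    control = pool_directions(sweeps[("control", +1)],
                              sweeps[("control", -1)], "control")
    per_dir: dict[int, ShiftEstimate] = {}
    for d in (+1, -1):
        per_dir[d] = estimate_shift(control, sweeps[("activated", d)],
                                    search_range=search_range)
    combined = 0.5 * (per_dir[+1].shift + per_dir[-1].shift)
    quality = 0.5 * (per_dir[+1].quality + per_dir[-1].quality)
    return ShiftEstimate(shift=float(combined), quality=float(quality),
                         per_direction=(per_dir[+1].shift, per_dir[-1].shift))


def normalize_to_peak(curve: TuningCurve) -> TuningCurve:
    """Return a copy with trials scaled so the mean curve's peak is 1."""
    peak = float(np.abs(curve.mean).max())
    if peak == 0:
        raise ValueError("cannot normalize a zero curve")
    return TuningCurve(curve.positions.copy(), curve.trials / peak,
                       direction=curve.direction, condition=curve.condition)
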