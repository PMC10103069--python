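"""Binocular vergence, gap-crossing events, triggered averages, statistics.

The vergence metric is the sign-inverted product of the baseline-referenced
left- and right-eye horizontal retinal shifts,

    V(t) = -(x_L(t) - b_L) * (x_R(t) - b_R),

which goes positive during coincident convergent (mirror-symmetric)
movements and negative during conjugate ones.  Gap crossings are detected
as hysteresis threshold crossings of the unwrapped wheel angle (two gaps
per revolution, 180 degrees apart).  Event-triggered averages align
channel snippets at crossing times; per-event deltas use fixed analysis
windows: position channels mean[+2,+5] - mean[-5,-2] s, vergence
mean[-0.5,+0.5] - mean[-2.5,-1.5] s around the event.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import CrossingEvent, GapSession, TriggeredAverage


# --------------------------------------------------------------------------
# vergence metric
# --------------------------------------------------------------------------

def vergence_series(session: GapSession,
                    baseline: str | tuple[float, float] = "global",
                    events: Sequence[CrossingEvent] | None = None,
                    baseline_window: tuple[float, float] = (-2.5, -1.5),
                    ) -> np.ndarray:
    """Sign-inverted product of left- and right-eye horizontal shifts, deg^2.

    ``baseline`` is ``"global"`` (per-eye trace mean), ``"none"`` (zero), an
    explicit ``(b_L, b_R)`` tuple, or ``"per_event"``: each sample uses the
    baselines from the ``baseline_window`` (seconds, relative to the event)
    of the nearest event, matching the per-event windows of the delta
    analysis.  ``per_event`` requires ``events``.
    """
    if session.left is None or session.right is None:
        raise ValueError("both eye traces are required")
    xl, xr = session.left.x, session.right.x
    if baseline == "global":
        bl = np.full_like(xl, xl.mean())
        br = np.full_like(xr, xr.mean())
    elif baseline == "none":
        bl = np.zeros_like(xl)
        br = np.zeros_like(xr)
    elif baseline == "per_event":
        if not events:
            raise ValueError("per_event baseline requires events")
        t = session.times
        ev_times = np.array([e.time for e in events])
        bl = np.empty_like(xl)
        br = np.empty_like(xr)
        # piecewise-constant baselines: each sample takes the baseline of
        # the nearest event
        nearest = np.abs(t[:, None] - ev_times[None, :]).argmin(axis=1)
        for k, tev in enumerate(ev_times):
            sel_base = (t >= tev + baseline_window[0]) & (t <= tev + baseline_window[1])
            if not sel_base.any():
                raise ValueError(f"baseline window empty for event at {tev:.2f}s")
            seg = nearest == k
            bl[seg] = xl[sel_base].mean()
            br[seg] = xr[sel_base].mean()
    else:
        b_l, b_r = baseline  # type: ignore[misc]
        bl = np.full_like(xl, float(b_l))
        br = np.full_like(xr, float(b_r))
    return -(xl - bl) * (xr - br)


# --------------------------------------------------------------------------
# crossing detection
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CrossingConfig:
    """Wheel threshold-crossing detector parameters.

    The wheel angle is unwrapped; with ``wrap_levels`` the threshold is
    replicated every ``gap_spacing_deg`` (two gaps per revolution).  A
    crossing fires when the wheel passes a level after having been at
    least ``hysteresis`` below it (above, for backward events); events
    closer than ``min_interval`` are discarded so +/-5 s analysis windows
    never overlap.
    """

    hysteresis: float = 5.0  # wheel deg
    min_interval: float = 10.0  # s
    wrap_levels: bool = True
    gap_spacing_deg: float = 180.0


def detect_crossings(times: np.ndarray, wheel: np.ndarray,
                     threshold: float,
                     cfg: CrossingConfig | None = None,
                     session: GapSession | None = None
                     ) -> list[CrossingEvent]:
    """Detect forward/backward threshold crossings of the wheel trace.

    Returns events sorted in time, labeled with the session lighting epoch
    when a session is given.  A threshold outside the trace range yields
    an empty list.
    """
    cfg = cfg or CrossingConfig()
    times = np.asarray(times, dtype=float)
    wheel = np.asarray(wheel, dtype=float)
    lo, hi = float(wheel.min()), float(wheel.max())
    if cfg.wrap_levels:
        k0 = int(np.ceil((lo - threshold) / cfg.gap_spacing_deg))
        k1 = int(np.floor((hi - threshold) / cfg.gap_spacing_deg))
        levels = [threshold + k * cfg.gap_spacing_deg for k in range(k0, k1 + 1)]
    else:
        levels = [threshold] if lo <= threshold <= hi else []

    raw: list[CrossingEvent] = []
    for level in levels:
        armed_fwd = wheel[0] <= level - cfg.hysteresis
        armed_bwd = wheel[0] >= level + cfg.hysteresis
        for i in range(1, wheel.size):
            w = wheel[i]
            if armed_fwd and w >= level:
                # linear interpolation of the crossing instant
                w0 = wheel[i - 1]
                frac = 0.0 if w == w0 else (level - w0) / (w - w0)
                tc = float(times[i - 1] + frac * (times[i] - times[i - 1]))
                raw.append(CrossingEvent(tc, "forward"))
                armed_fwd = False
            elif armed_bwd and w <= level:
                w0 = wheel[i - 1]
                frac = 0.0 if w == w0 else (level - w0) / (w - w0)
                tc = float(times[i - 1] + frac * (times[i] - times[i - 1]))
                raw.append(CrossingEvent(tc, "backward"))
                armed_bwd = False
            if w <= level - cfg.hysteresis:
                armed_fwd = True
            if w >= level + cfg.hysteresis:
                armed_bwd = True

    raw.sort(key=lambda e: e.time)
    out: list[CrossingEvent] = []
    for ev in raw:
        if out and ev.time - out[-1].time < cfg.min_interval:
            continue
        label = session.lighting_label(ev.time) if session is not None else ""
        out.append(CrossingEvent(ev.time, ev.direction, label))
    return out


# --------------------------------------------------------------------------
# triggered averaging
# --------------------------------------------------------------------------

def triggered_average(channels: Mapping[str, tuple[np.ndarray, np.ndarray]],
                      events: Sequence[CrossingEvent | float],
                      window: tuple[float, float] = (5.0, 5.0),
                      ) -> TriggeredAverage:
    """Event-triggered snippets and mean per channel.

    ``channels`` maps a name to ``(times, values)``; all channels must
    share a uniform time base.  ``window`` is ``(pre, post)`` seconds.
    Events whose window exits the trace are excluded and counted.  The
    mean is the arithmetic mean of the included snippets per lag.
    """
    if not channels:
        raise ValueError("no channels given")
    name0 = next(iter(channels))
    t0 = np.asarray(channels[name0][0], dtype=float)
    dt = float(np.median(np.diff(t0)))
    pre, post = window
    n_pre = int(round(pre / dt))
    n_post = int(round(post / dt))
    lags = np.arange(-n_pre, n_post + 1) * dt

    ev_times = [e.time if isinstance(e, CrossingEvent) else float(e)
                for e in events]
    idx: list[int] = []
    n_excl = 0
    for tev in ev_times:
        i = int(round((tev - t0[0]) / dt))
        if i - n_pre < 0 or i + n_post >= t0.size:
            n_excl += 1
            continue
        idx.append(i)
    if not idx:
        raise ValueError("all events excluded: windows exit the trace")

    snippets: dict[str, np.ndarray] = {}
    means: dict[str, np.ndarray] = {}
    for name, (t, v) in channels.items():
        v = np.asarray(v, dtype=float)
        snip = np.stack([v[i - n_pre:i + n_post + 1] for i in idx])
        snippets[name] = snip
        means[name] = snip.mean(axis=0)
    return TriggeredAverage(lags=lags, means=means, snippets=snippets,
                            n_events=len(idx), n_excluded=n_excl)


def session_channels(session: GapSession
                     ) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Standard channel dict (wheel, xL, xR) for a session."""
    return {"wheel": (session.times, session.wheel),
            "xL": (session.times, session.left.x),
            "xR": (session.times, session.right.x)}


# --------------------------------------------------------------------------
# event deltas (fixed analysis windows)
# --------------------------------------------------------------------------

#: analysis windows in seconds relative to the crossing event
POSITION_BASE_WINDOW = (-5.0, -2.0)
POSITION_RESP_WINDOW = (2.0, 5.0)
VERGENCE_BASE_WINDOW = (-2.5, -1.5)
VERGENCE_RESP_WINDOW = (-0.5, 0.5)


def _window_mean(lags: np.ndarray, snip: np.ndarray,
                 win: tuple[float, float]) -> np.ndarray:
    sel = (lags >= win[0] - 1e-9) & (lags <= win[1] + 1e-9)
    if not sel.any():
        raise ValueError(f"snippet does not cover window {win}")
    return snip[:, sel].mean(axis=1)


def event_deltas(avg: TriggeredAverage) -> pd.DataFrame:
    """Per-event baseline-subtracted deltas for wheel, x_L, x_R and vergence.

    Position channels: mean over [+2, +5] s minus mean over [-5, -2] s.
    Vergence: mean over [-0.5, +0.5] s minus mean over [-2.5, -1.5] s,
    where the vergence snippet is computed from the eye snippets with
    per-event baselines taken from the same [-2.5, -1.5] s window.
    Requires snippets covering [-5, +5] s.
    """
    lags = avg.lags
    if lags[0] > POSITION_BASE_WINDOW[0] + 1e-9 or lags[-1] < POSITION_RESP_WINDOW[1] - 1e-9:
        raise ValueError("snippets must cover [-5, +5] s around the event")
    out: dict[str, np.ndarray] = {}
    for name in ("wheel", "xL", "xR"):
        if name not in avg.snippets:
            continue
        snip = avg.snippets[name]
        out[f"{name}_delta"] = (_window_mean(lags, snip, POSITION_RESP_WINDOW)
                                - _window_mean(lags, snip, POSITION_BASE_WINDOW))
    if "xL" in avg.snippets and "xR" in avg.snippets:
        xl, xr = avg.snippets["xL"], avg.snippets["xR"]
        bl = _window_mean(lags, xl, VERGENCE_BASE_WINDOW)
        br = _window_mean(lags, xr, VERGENCE_BASE_WINDOW)
        verg = -(xl - bl[:, None]) * (xr - br[:, None])
        out["vergence_delta"] = (_window_mean(lags, verg, VERGENCE_RESP_WINDOW)
                                 - _window_mean(lags, verg, VERGENCE_BASE_WINDOW))
    return pd.DataFrame(out)


# --------------------------------------------------------------------------
# statistics
# --------------------------------------------------------------------------

def deltas_ttest(deltas: pd.DataFrame | Mapping[str, Sequence[float]],
                 m_tests: int = 9, alpha: float = 0.05) -> pd.DataFrame:
    """Two-sided one-sample t-tests vs 0 with Bonferroni correction.

    Returns a DataFrame indexed by distribution name with columns
    ``t``, ``p``, ``n`` and ``significant`` (p < alpha / m_tests).
    """
    df = pd.DataFrame(dict(deltas))
    rows = {}
    for col in df.columns:
        x = np.asarray(df[col].dropna(), dtype=float)
        if x.size < 2:
            raise ValueError(f"distribution {col!r} needs n >= 2")
        if np.allclose(x, 0) or np.ptp(x) == 0 and x[0] == 0:
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_1samp(x, 0.0)
        rows[col] = {"t": float(t), "p": float(p), "n": int(x.size),
                     "significant": bool(p < alpha / m_tests)}
    return pd.DataFrame(rows).T


@dataclass
class CrossingHeightResult:
    """Per-fly median crossing heights and the group Welch comparison."""

    medians: dict[str, np.ndarray]
    group_mean: dict[str, float]
    group_sem: dict[str, float]
    t: float
    p: float


def crossing_height(groups: Mapping[str, Sequence[Sequence[np.ndarray]]]
                    ) -> CrossingHeightResult:
    """Per-fly median of per-cross minimum y; two-sided Welch test on groups.

    ``groups`` maps a group label to a list (flies) of lists of (n, 2)
    x-y paths.  Exactly two groups are compared.
    """
    if len(groups) != 2:
        raise ValueError("exactly two groups are required")
    medians: dict[str, np.ndarray] = {}
    for label, flies in groups.items():
        per_fly = []
        for paths in flies:
            if len(paths) < 1:
                raise ValueError("each fly needs >= 1 cross")
            mins = [float(np.min(np.asarray(p)[:, 1])) for p in paths]
            per_fly.append(float(np.median(mins)))
        medians[label] = np.asarray(per_fly)
    (la, a), (lb, b) = medians.items()
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return CrossingHeightResult(
        medians=medians,
        group_mean={k: float(v.mean()) for k, v in medians.items()},
        group_sem={k: float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else np.nan
                   for k, v in medians.items()},
        t=float(t), p=float(p))


def crossing_rate(events: Sequence[CrossingEvent],
                  epochs: Sequence,
                  forward_only: bool = True) -> pd.DataFrame:
    """Forward-crossing rate per lighting epoch.

    Returns a DataFrame indexed by epoch label with columns ``n_events``,
    ``duration_s`` and ``rate_per_s``.
    """
    if not epochs:
        raise ValueError("labeled epochs are required")
    rows = {}
    for ep in epochs:
        n = sum(1 for e in events
                if ep.start <= e.time < ep.end
                and (not forward_only or e.direction == "forward"))
        dur = ep.end - ep.start
        rows[ep.label] = {"n_events": n, "duration_s": dur,
                          "rate_per_s": n / dur}
    return pd.DataFrame(rows).T


def compare_rates(rates_by_fly: pd.DataFrame,
                  epoch_a: str, epoch_b: str) -> tuple[float, float]:
    """Paired t-test across flies between two epochs.

    ``rates_by_fly`` has one row per fly and one column per epoch label
    (rates in events/s).  Returns (t, p).
    """
    a = np.asarray(rates_by_fly[epoch_a], dtype=float)
    b = np.asarray(rates_by_fly[epoch_b], dtype=float)
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)
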