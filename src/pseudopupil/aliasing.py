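"""Spatial-aliasing model: Reichardt correlator array on a sampled retina.

A 1-D array of photoreceptors with inter-ommatidial angle dphi feeds
nearest-neighbour elementary motion detectors (EMDs): each pair
delay-filters one input (first-order low-pass, tau = 50 ms), multiplies it
with the undelayed neighbour and subtracts the mirror-symmetric product
(opponency).  For a drifting sinusoidal grating of wavelength lam the
time-averaged opponent output is proportional to sin(2*pi*dphi/lam): it is
veridical for lam > 2*dphi, zero at the cut-off lam_L = 2*dphi, and
*inverted* (spatial aliasing) for dphi < lam < 2*dphi — for dphi = 5
degrees the inversion band is (5, 10) degrees, the band in which flies'
retinal optokinetic and walking optomotor responses reverse sign.

The low-pass time constant and any acceptance-angle blur scale the output
magnitude but never move the zero crossings, which is what the band edges
are read from.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq


@dataclass(frozen=True)
class SamplingArray:
    """1-D photoreceptor array with fixed angular sampling.

    ``delta_phi`` is the inter-ommatidial angle in degrees;
    ``acceptance_angle`` (optional, degrees FWHM) applies Gaussian spatial
    blur, attenuating but not sign-flipping sinusoidal responses.
    """

    delta_phi: float = 5.0
    n_receptors: int = 12
    acceptance_angle: float | None = None
    tau: float = 0.050  # s, delay low-pass time constant

    def __post_init__(self) -> None:
        if self.delta_phi <= 0:
            raise ValueError("delta_phi must be positive")
        if self.n_receptors < 2:
            raise ValueError("need at least 2 receptors")


@dataclass(frozen=True)
class GratingStimulus:
    """Drifting grating: spatial wavelength (deg), temporal frequency, direction."""

    wavelength: float
    temporal_frequency: float = 4.0  # Hz
    direction: int = 1  # +1 / -1
    contrast: float = 0.5
    waveform: str = "sine"  # "sine" | "square"

    def __post_init__(self) -> None:
        if self.wavelength <= 0:
            raise ValueError("wavelength must be positive")


def cutoff_wavelength(array: SamplingArray) -> float:
    """Aliasing cut-off lam_L = 2 * delta_phi."""
    return 2.0 * array.delta_phi


def _receptor_signals(grating: GratingStimulus, array: SamplingArray,
                      t: np.ndarray) -> np.ndarray:
    """(n_receptors, n_t) luminance signals at the sampled directions."""
    x = np.arange(array.n_receptors) * array.delta_phi
    k = 2.0 * np.pi / grating.wavelength
    omega = 2.0 * np.pi * grating.temporal_frequency
    phase = k * x[:, None] - grating.direction * omega * t[None, :]
    contrast = grating.contrast
    if array.acceptance_angle:
        # modulation transfer of a Gaussian acceptance function (FWHM rho)
        rho = array.acceptance_angle
        contrast = contrast * float(
            np.exp(-(np.pi * rho / grating.wavelength) ** 2 / (4 * np.log(2))))
    if grating.waveform == "square":
        return contrast * np.sign(np.sin(phase))
    return contrast * np.sin(phase)


def _lowpass(sig: np.ndarray, dt: float, tau: float) -> np.ndarray:
    """First-order low-pass along the last axis (exponential recursion)."""
    alpha = float(np.exp(-dt / tau))
    out = np.empty_like(sig)
    out[..., 0] = sig[..., 0] * (1 - alpha)
    for i in range(1, sig.shape[-1]):
        out[..., i] = alpha * out[..., i - 1] + (1 - alpha) * sig[..., i]
    return out


def emd_mean_response(grating: GratingStimulus, array: SamplingArray,
                      duration: float | None = None,
                      dt: float | None = None,
                      normalized: bool = True) -> float:
    """Time-averaged opponent correlator output, summed over the array.

    Positive output means the array reports the true drift direction.
    ``duration`` must cover at least two temporal periods (default 5,
    after a transient of 5 tau that is discarded); the average runs over
    a whole number of periods.  With ``normalized`` the known
    frequency-dependent gain of the correlator is divided out so the
    response equals ``direction * sin(2*pi*delta_phi/lambda)`` up to
    simulation error for a sinusoidal grating at low contrast.
    """
    period = 1.0 / grating.temporal_frequency
    if duration is None:
        duration = 5.0 * period
    if duration < 2.0 * period:
        raise ValueError("duration must cover at least 2 temporal periods")
    if dt is None:
        dt = min(period / 200.0, array.tau / 20.0)
    transient = 5.0 * array.tau
    n_periods = max(int(np.floor(duration / period)), 2)
    t = np.arange(0.0, transient + n_periods * period, dt)
    s = _receptor_signals(grating, array, t)
    d = _lowpass(s, dt, array.tau)
    # opponent pair i: delayed left arm x undelayed right arm, minus mirror
    out = d[:-1] * s[1:] - s[:-1] * d[1:]
    keep = t >= transient
    raw = float(out[:, keep].mean())
    if not normalized:
        return raw
    # steady-state gain of the opponent correlator for a unit-contrast
    # sinusoid through the first-order low-pass: |H| sin(arg H) with
    # H = 1/(1 + i omega tau)
    omega = 2.0 * np.pi * grating.temporal_frequency
    wt = omega * array.tau
    gain = (grating.contrast ** 2) * wt / (1.0 + wt**2)
    if array.acceptance_angle:
        rho = array.acceptance_angle
        gain *= float(np.exp(-(np.pi * rho / grating.wavelength) ** 2
                             / (2 * np.log(2))))
    return raw / gain


def inversion_band(array: SamplingArray,
                   lambdas: Sequence[float] | None = None,
                   temporal_frequency: float = 4.0,
                   contrast: float = 0.5) -> tuple[float, float]:
    """Wavelength band adjacent to the 2*delta_phi cut-off with inverted sign.

    Scans the response over ``lambdas`` (default 0.5..4 * delta_phi), finds
    the contiguous negative interval bordering the cut-off, and refines
    both edges by root bracketing of the simulated response curve.
    Returns (lambda_low, lambda_high); for delta_phi = 5 this is (5, 10).
    """
    if lambdas is None:
        lambdas = np.arange(0.5 * array.delta_phi, 4.0 * array.delta_phi + 1e-9,
                            array.delta_phi / 20.0)
    lambdas = np.asarray(sorted(lambdas), dtype=float)
    if lambdas[0] > 0.5 * array.delta_phi or lambdas[-1] < 4.0 * array.delta_phi:
        raise ValueError("lambda grid must span (0.5*delta_phi, 4*delta_phi)")

    def resp(lam: float) -> float:
        return emd_mean_response(
            GratingStimulus(lam, temporal_frequency, 1, contrast), array)

    vals = np.array([resp(l) for l in lambdas])
    neg = vals < 0
    if not neg.any():
        raise ValueError("no sign inversion found on the wavelength grid")
    # negative run nearest below the cut-off
    cutoff = 2.0 * array.delta_phi
    runs = []
    i = 0
    while i < neg.size:
        if neg[i]:
            j = i
            while j + 1 < neg.size and neg[j + 1]:
                j += 1
            runs.append((i, j))
            i = j + 1
        else:
            i += 1
    run = min(runs, key=lambda r: abs(lambdas[r[1]] - cutoff))
    i0, i1 = run
    if i0 == 0 or i1 == neg.size - 1:
        raise ValueError("inversion band not bracketed by the grid")
    lo = brentq(resp, lambdas[i0 - 1], lambdas[i0], xtol=1e-4)
    hi = brentq(resp, lambdas[i1], lambdas[i1 + 1], xtol=1e-4)
    return float(lo), float(hi)


def response_curve(array: SamplingArray,
                   lambdas: Sequence[float],
                   directions: Sequence[int] = (1, -1),
                   temporal_frequency: float = 4.0,
                   contrast: float = 0.5) -> pd.DataFrame:
    """Signed mean response per wavelength and direction.

    Returns a DataFrame with columns (lambda_deg, direction, response),
    suitable for comparing arrays with different delta_phi (e.g. the
    higher-acuity eye of D. suzukii inverts at smaller wavelengths than
    D. melanogaster).
    """
    lambdas = list(lambdas)
    if not lambdas:
        raise ValueError("lambda list must be non-empty")
    rows = []
    for lam in lambdas:
        for d in directions:
            r = emd_mean_response(
                GratingStimulus(lam, temporal_frequency, d, contrast), array)
            rows.append({"lambda_deg": float(lam), "direction": int(d),
                         "response": r})
    return pd.DataFrame(rows)
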