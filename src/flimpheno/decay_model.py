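"""Forward model of a periodically excited biexponential fluorescence decay.

Single source of truth shared by the synthetic generator and the fitter: under
pulsed excitation at period T, incomplete decay from earlier pulses wraps
around, so each exponential component contributes
``exp(-t/tau) / (1 - exp(-T/tau))`` on ``t in [0, T)``.  The detected curve is
the circular convolution of this wrapped decay with the instrument response.
"""

from __future__ import annotations

import numpy as np

from .core import BiexpParams, IRFCurve, TimeGrid

__all__ = ["wrapped_biexp", "convolve_irf", "model_curve", "mean_lifetime"]


def mean_lifetime(params: BiexpParams) -> float:
    """Amplitude-weighted mean lifetime ``tau_m = alpha1*tau1 + alpha2*tau2`` in ns."""
    return params.alpha1 * params.tau1 + params.alpha2 * params.tau2


def wrapped_biexp(params: BiexpParams, grid: TimeGrid) -> np.ndarray:
    """Unit-sum biexponential decay with periodic wrap-around, at channel centers."""
    t = grid.channel_centers
    T = grid.period
    curve = params.alpha1 * np.exp(-t / params.tau1) / -np.expm1(-T / params.tau1)
    if params.alpha1 < 1.0:
        curve = curve + (1.0 - params.alpha1) * np.exp(-t / params.tau2) / -np.expm1(
            -T / params.tau2
        )
    return curve / curve.sum()


def convolve_irf(curve: np.ndarray, irf: IRFCurve) -> np.ndarray:
    """Circular convolution with the unit-sum IRF (sum-preserving)."""
    kernel = irf.normalized
    out = np.fft.irfft(np.fft.rfft(curve) * np.fft.rfft(kernel), n=curve.size)
    # FFT round-off can leave tiny negative values on near-zero channels.
    return np.clip(out, 0.0, None)


def model_curve(
    params: BiexpParams,
    irf: IRFCurve,
    grid: TimeGrid,
    amplitude: float,
    background: float | None = None,
) -> np.ndarray:
    """Expected per-channel counts: amplitude * (wrapped biexp (*) IRF) + background.

    ``amplitude`` is the total expected signal photon count (the decay shape and
    IRF are both unit-sum, and circular convolution preserves the sum).  When
    ``background`` is None the constant offset is taken from ``params``.
    """
    if irf.grid != grid:
        raise ValueError("IRF and requested grid do not match")
    if background is None:
        background = params.background
    return amplitude * convolve_irf(wrapped_biexp(params, grid), irf) + background
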