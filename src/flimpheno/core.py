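"""Core containers for time-correlated single photon counting (TCSPC) data.

A TCSPC acquisition records, for every image pixel, a histogram of photon
arrival times over one laser repetition period.  These containers carry the
time axis (:class:`TimeGrid`), the biexponential decay model parameters
(:class:`BiexpParams`), the measured instrument response (:class:`IRFCurve`)
and the photon-count stacks themselves (:class:`TCSPCImage`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "TimeGrid",
    "BiexpParams",
    "IRFCurve",
    "TCSPCImage",
    "CHANNEL_NAMES",
    "spatial_bin_sum",
]

#: Recognised spectral channel names (NAD(P)H and FAD autofluorescence).
CHANNEL_NAMES = ("NADPH", "FAD")


@dataclass(frozen=True)
class TimeGrid:
    """Uniform time binning of one laser repetition period.

    Parameters
    ----------
    n_channels
        Number of time bins (TCSPC ADC channels).
    period
        Measurement window ``T`` in ns; equals ``1/f`` for laser repetition
        frequency ``f`` (12.5 ns at 80 MHz).
    """

    n_channels: int = 256
    period: float = 12.5

    def __post_init__(self) -> None:
        if int(self.n_channels) != self.n_channels or self.n_channels < 2:
            raise ValueError(f"n_channels must be an integer >= 2, got {self.n_channels}")
        if not self.period > 0:
            raise ValueError(f"period must be positive, got {self.period}")

    @property
    def channel_width(self) -> float:
        """Width of one time bin in ns."""
        return self.period / self.n_channels

    @property
    def channel_centers(self) -> np.ndarray:
        """Bin midpoints in ns, strictly increasing, all inside (0, period)."""
        h = self.channel_width
        return (np.arange(self.n_channels) + 0.5) * h

    @property
    def frequency(self) -> float:
        """Repetition frequency in GHz (cycles per ns)."""
        return 1.0 / self.period

    @property
    def omega(self) -> float:
        """First-harmonic angular frequency ``2*pi*f`` in rad/ns."""
        return 2.0 * np.pi / self.period


@dataclass(frozen=True)
class BiexpParams:
    """Parameters of the two-component decay I(t) = a1*exp(-t/tau1) + a2*exp(-t/tau2) + C.

    ``alpha1`` and ``alpha2 = 1 - alpha1`` are the normalized amplitude
    fractions of the short- and long-lifetime components; lifetimes are in ns;
    ``background`` is the constant offset C in expected counts per channel.
    """

    alpha1: float
    tau1: float
    tau2: float
    background: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha1 <= 1.0:
            raise ValueError(f"alpha1 must be in [0, 1], got {self.alpha1}")
        if not 0.0 < self.tau1 < self.tau2:
            raise ValueError(
                f"lifetimes must satisfy 0 < tau1 < tau2, got tau1={self.tau1}, tau2={self.tau2}"
            )
        if self.background < 0:
            raise ValueError(f"background must be >= 0, got {self.background}")

    @property
    def alpha2(self) -> float:
        return 1.0 - self.alpha1

    @property
    def tau_m(self) -> float:
        """Amplitude-weighted mean lifetime ``alpha1*tau1 + alpha2*tau2`` (ns)."""
        return self.alpha1 * self.tau1 + self.alpha2 * self.tau2


@dataclass(frozen=True)
class IRFCurve:
    """Instrument response function sampled on a :class:`TimeGrid`."""

    counts: np.ndarray
    grid: TimeGrid

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "counts", counts)
        if counts.ndim != 1 or counts.size != self.grid.n_channels:
            raise ValueError(
                f"IRF must be 1-D with {self.grid.n_channels} channels, got shape {counts.shape}"
            )
        if np.any(counts < 0):
            raise ValueError("IRF counts must be nonnegative")
        if not counts.sum() > 0:
            raise ValueError("IRF must contain at least one positive count")

    @property
    def normalized(self) -> np.ndarray:
        """Unit-sum copy of the response curve."""
        return self.counts / self.counts.sum()


@dataclass(frozen=True)
class TCSPCImage:
    """Photon-count histogram stack indexed (row, column, time channel)."""

    counts: np.ndarray
    grid: TimeGrid
    channel_name: str = "NADPH"

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        object.__setattr__(self, "counts", counts)
        if counts.ndim != 3:
            raise ValueError(f"counts must be 3-D (y, x, time), got {counts.ndim}-D")
        if counts.shape[0] < 1 or counts.shape[1] < 1:
            raise ValueError("spatial dimensions must be >= 1")
        if counts.shape[2] != self.grid.n_channels:
            raise ValueError(
                f"time dimension {counts.shape[2]} != grid.n_channels {self.grid.n_channels}"
            )
        if np.any(counts < 0):
            raise ValueError("photon counts must be nonnegative")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(counts == np.round(counts)):
                raise ValueError("photon counts must be integer-valued")
        if self.channel_name not in CHANNEL_NAMES:
            raise ValueError(f"channel_name must be one of {CHANNEL_NAMES}, got {self.channel_name!r}")

    @property
    def shape(self) -> tuple:
        return self.counts.shape

    def intensity(self) -> np.ndarray:
        """Total photons per pixel (sum over time channels)."""
        return np.asarray(self.counts, dtype=float).sum(axis=2)


def spatial_bin_sum(array: np.ndarray, radius: int) -> np.ndarray:
    """Sum over the square spatial neighborhood of the given radius.

    For ``radius = r`` each output pixel is the sum of the input over the
    ``(2r+1) x (2r+1)`` window centered on it, with zero padding at the image
    border.  Works on 2-D maps and on 3-D stacks (summed per time channel).
    This is the binning applied identically before decay fitting and before
    the phasor transform, so both feature routes see the same pixel support.
    """
    if radius < 0 or int(radius) != radius:
        raise ValueError(f"radius must be a nonnegative integer, got {radius}")
    arr = np.asarray(array, dtype=float)
    if radius == 0:
        return arr.copy()
    w = 2 * radius + 1
    size = (w, w) + (1,) * (arr.ndim - 2)
    return ndimage.uniform_filter(arr, size=size, mode="constant") * (w * w)
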