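"""Time base and instrument response for time-correlated single photon counting.

A TCSPC acquisition bins photon arrival times into fixed-width channels
spanning one laser repetition period. The configuration here (20 ps channels,
1250 channels, i.e. a 25 ns window at 40 MHz repetition) is shared by the
simulator and every fitting / mapping stage so that time axes always agree.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtr

__all__ = ["TCSPCConfig", "IRFSpec", "delta_irf"]

_FWHM_TO_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))


@dataclass(frozen=True)
class TCSPCConfig:
    """Time base of a TCSPC acquisition.

    Parameters
    ----------
    channel_width : float
        Width of one time channel in nanoseconds (default 0.020 ns = 20 ps).
    n_channels : int
        Number of channels spanning one repetition period (default 1250,
        i.e. 25 ns at a 40 MHz pulsed laser).
    analysis_channels : int
        Number of channels, counted from the decay origin, used for fitting
        and for the barycenter mean lifetime (default 1200 -> 24 ns).
    """

    channel_width: float = 0.020
    n_channels: int = 1250
    analysis_channels: int = 1200

    def __post_init__(self) -> None:
        if not (self.channel_width > 0 and math.isfinite(self.channel_width)):
            raise ValueError("channel_width must be positive and finite")
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        if not 0 < self.analysis_channels <= self.n_channels:
            raise ValueError("analysis_channels must lie in (0, n_channels]")

    @property
    def repetition_period(self) -> float:
        """Laser repetition period in ns (channel_width x n_channels)."""
        return self.channel_width * self.n_channels

    def channel_edges(self) -> np.ndarray:
        """Channel boundary times, length n_channels + 1, in ns."""
        return np.arange(self.n_channels + 1) * self.channel_width

    def channel_midpoints(self) -> np.ndarray:
        """Channel midpoint times, length n_channels, in ns."""
        return (np.arange(self.n_channels) + 0.5) * self.channel_width


@dataclass(frozen=True)
class IRFSpec:
    """Instrument response function, parametric Gaussian or tabulated.

    The parametric default (Gaussian, 100 ps FWHM, centered 0.5 ns into the
    window) stands in for a measured lamp/scatter histogram; a tabulated
    per-channel histogram may be supplied instead for realism.
    """

    kind: str = "gaussian"
    center: float = 0.5
    fwhm: float = 0.1
    counts: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.kind not in ("gaussian", "tabulated"):
            raise ValueError(f"unknown IRF kind {self.kind!r}")
        if self.kind == "gaussian":
            if not (self.fwhm > 0 and math.isfinite(self.fwhm)):
                raise ValueError("parametric IRF requires fwhm > 0")
        else:
            c = np.asarray(self.counts, dtype=float)
            if c.ndim != 1 or c.size == 0:
                raise ValueError("tabulated IRF requires a 1-D counts histogram")
            if np.any(c < 0) or not np.all(np.isfinite(c)):
                raise ValueError("tabulated IRF counts must be finite and non-negative")
            if c.sum() <= 0:
                raise ValueError("tabulated IRF must have a positive total")
            object.__setattr__(self, "counts", c)

    def profile(self, config: TCSPCConfig) -> np.ndarray:
        """Normalized (unit-sum) per-channel IRF, length n_channels."""
        if self.kind == "tabulated":
            c = np.zeros(config.n_channels)
            n = min(self.counts.size, config.n_channels)
            c[:n] = self.counts[:n]
            total = c.sum()
            if total <= 0:
                raise ValueError("tabulated IRF is empty inside the window")
            return c / total
        sigma = self.fwhm / _FWHM_TO_SIGMA
        edges = config.channel_edges()
        mass = ndtr((edges[1:] - self.center) / sigma) - ndtr(
            (edges[:-1] - self.center) / sigma
        )
        total = mass.sum()
        if total <= 0:
            raise ValueError("Gaussian IRF lies outside the acquisition window")
        return mass / total

    def peak_channel(self, config: TCSPCConfig) -> int:
        """Channel index of the IRF maximum (the decay origin by default)."""
        if self.kind == "tabulated":
            return int(np.argmax(self.counts[: config.n_channels]))
        return int(math.floor(self.center / config.channel_width + 0.5))


def delta_irf(config: TCSPCConfig, channel: int = 0) -> IRFSpec:
    """An idealized instantaneous IRF: all weight in a single channel."""
    if not 0 <= channel < config.n_channels:
        raise ValueError("delta IRF channel outside the window")
    counts = np.zeros(config.n_channels)
    counts[channel] = 1.0
    return IRFSpec(kind="tabulated", counts=counts)
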