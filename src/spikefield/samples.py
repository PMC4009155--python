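"""Windowed multiscale neural data containers.

A single analysis window pairs the spike times of every sorted unit with a
segment of every LFP channel.  Windows are the atomic inputs of the kernel
operators, the Q-KLMS learner and the controller.  All times inside windows
are in milliseconds relative to the window start; file formats use seconds
(see :mod:`spikefield.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import WindowMismatchError

__all__ = [
    "SpikeWindow",
    "MultiunitSpikeWindow",
    "LFPWindow",
    "MultichannelLFPWindow",
    "MultiscaleSample",
    "IntensityEstimate",
]


@dataclass(frozen=True, eq=False)
class SpikeWindow:
    """Spike times of one unit inside an analysis window.

    Parameters
    ----------
    times
        Strictly increasing spike times in ms, each in ``[0, window_length]``.
        May be empty (a silent unit is a valid window).
    window_length
        Window support ``T_s`` in ms.
    """

    times: np.ndarray
    window_length: float

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)
        if t.ndim != 1:
            raise ValueError("spike times must be a 1-D sequence")
        if self.window_length <= 0:
            raise ValueError("window_length must be positive")
        if t.size:
            if np.any(np.diff(t) < 0):
                raise ValueError("spike times must be non-decreasing")
            if t[0] < 0 or t[-1] > self.window_length:
                raise ValueError("spike times must lie in [0, window_length]")

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True, eq=False)
class MultiunitSpikeWindow:
    """Per-unit spike windows sharing one support ``T_s``."""

    units: tuple[SpikeWindow, ...]

    def __post_init__(self) -> None:
        units = tuple(self.units)
        object.__setattr__(self, "units", units)
        if not units:
            raise ValueError("at least one unit is required")
        T = units[0].window_length
        if any(u.window_length != T for u in units):
            raise WindowMismatchError("all units must share window_length")

    @property
    def window_length(self) -> float:
        return self.units[0].window_length

    @property
    def n_units(self) -> int:
        return len(self.units)


@dataclass(frozen=True, eq=False)
class LFPWindow:
    """Uniformly sampled LFP segment.

    ``samples[k]`` is taken to represent the field potential over the interval
    ending at ``(k + 1) * sample_period`` ms, so the window is causal and its
    support is ``(0, window_length]``.
    """

    samples: np.ndarray
    sample_period: float

    def __post_init__(self) -> None:
        x = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", x)
        if x.ndim != 1 or x.size == 0:
            raise ValueError("samples must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(x)):
            raise ValueError("LFP samples must be finite")
        if self.sample_period <= 0:
            raise ValueError("sample_period must be positive")

    @property
    def window_length(self) -> float:
        """Window support ``T_x`` in ms."""
        return self.samples.size * self.sample_period


@dataclass(frozen=True, eq=False)
class MultichannelLFPWindow:
    """Congruent per-channel LFP windows."""

    channels: tuple[LFPWindow, ...]

    def __post_init__(self) -> None:
        ch = tuple(self.channels)
        object.__setattr__(self, "channels", ch)
        if not ch:
            raise ValueError("at least one channel is required")
        n, tau = ch[0].samples.size, ch[0].sample_period
        if any(c.samples.size != n or c.sample_period != tau for c in ch):
            raise WindowMismatchError("channels must share shape and sample_period")

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def window_length(self) -> float:
        return self.channels[0].window_length

    def as_matrix(self) -> np.ndarray:
        """Channels stacked as a (n_channels, n_samples) array."""
        return np.stack([c.samples for c in self.channels])


@dataclass(frozen=True, eq=False)
class MultiscaleSample:
    """One joint analysis window: multiunit spikes plus multichannel LFP.

    Both parts refer to the same prediction time (their shared right edge);
    the alignment is established by the windowing operation in
    :mod:`spikefield.decoding`.
    """

    spikes: MultiunitSpikeWindow
    lfp: MultichannelLFPWindow


@dataclass(frozen=True, eq=False)
class IntensityEstimate:
    """Exact piecewise-constant estimate of a point-process intensity.

    The estimate is constant at ``levels[i]`` (in 1/ms) on
    ``[breakpoints[i], breakpoints[i + 1])`` and zero outside the support
    ``[0, breakpoints[-1]]``.
    """

    breakpoints: np.ndarray
    levels: np.ndarray

    def __post_init__(self) -> None:
        bp = np.asarray(self.breakpoints, dtype=float)
        lv = np.asarray(self.levels, dtype=float)
        object.__setattr__(self, "breakpoints", bp)
        object.__setattr__(self, "levels", lv)
        if bp.size != lv.size + 1:
            raise ValueError("need one more breakpoint than levels")
        if np.any(np.diff(bp) <= 0):
            raise ValueError("breakpoints must be strictly increasing")
        if np.any(lv < 0):
            raise ValueError("intensity levels must be non-negative")

    @property
    def support(self) -> tuple[float, float]:
        return float(self.breakpoints[0]), float(self.breakpoints[-1])

    def __call__(self, t) -> np.ndarray:
        """Evaluate the intensity at times ``t`` (ms)."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.breakpoints, t, side="right") - 1
        inside = (idx >= 0) & (idx < self.levels.size)
        out = np.zeros_like(t, dtype=float)
        out[inside] = self.levels[idx[inside]]
        return out

    def integral(self) -> float:
        """Integral of the intensity over its support."""
        return float(np.sum(self.levels * np.diff(self.breakpoints)))
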