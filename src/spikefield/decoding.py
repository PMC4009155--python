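"""Dataset assembly and decoder training/evaluation.

A continuous :class:`Recording` (spike event table, multichannel LFP,
stimulus trace) is turned into a supervised dataset by sliding causal
windows: at each target time ``t_k = k * step`` (ms) the spike window covers
``(t_k - T_s, t_k]``, the LFP window covers ``(t_k - T_x, t_k]`` and the
target is the stimulus value at ``t_k``.  The per-modality window lengths
are chosen from the data by the autocorrelation criterion: the smallest lag
beyond which the sample autocorrelation stays inside the +-2 SE confidence
band of zero.

Decoding accuracy is measured by the normalized mean squared error
``NMSE = sum (y - d)^2 / sum (d - mean(d))^2`` and, for spike outputs, the
Pearson correlation of binned counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, NamedTuple, Sequence

import numpy as np
import pandas as pd
from statsmodels.tsa.stattools import acf

from .errors import DegenerateScaleError, WindowMismatchError
from .kernels import (
    CompositeKernelSpec,
    combine_modalities,
    modality_grams,
)
from .qklms import LearningTrace, QKLMSModel, train
from .samples import (
    LFPWindow,
    MultichannelLFPWindow,
    MultiscaleSample,
    MultiunitSpikeWindow,
    SpikeWindow,
)

__all__ = [
    "Recording",
    "DecodingDataset",
    "slide_windows",
    "autocorr",
    "autocorr_bounds",
    "estimate_window_length",
    "WindowLengthEstimate",
    "nmse",
    "binned_counts",
    "binned_correlation",
    "binned_crosscorrelation",
    "train_decoder",
    "evaluate_decoder",
    "compare_modalities",
]


@dataclass(eq=False)
class Recording:
    """A continuous multiscale recording with its stimulus.

    Times on disk and in ``spikes`` are in seconds; windowing converts to ms.

    Parameters
    ----------
    spikes
        Event table with integer column ``unit`` and float column ``time_s``.
    n_units
        Total number of units (units with no events are still units).
    lfp
        Field potentials, shape (samples, channels); sample ``i`` represents
        the interval ending at ``(i + 1) / lfp_fs`` seconds.
    stimulus
        Stimulus trace(s), shape (samples, channels), same convention at
        ``stim_fs``.
    """

    spikes: pd.DataFrame
    n_units: int
    lfp: np.ndarray
    lfp_fs: float
    stimulus: np.ndarray
    stim_fs: float
    duration_s: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.lfp = np.atleast_2d(np.asarray(self.lfp, dtype=float))
        self.stimulus = np.atleast_2d(np.asarray(self.stimulus, dtype=float))
        if self.lfp.shape[0] < self.lfp.shape[1]:  # allow (C, T) input
            pass
        if self.lfp_fs <= 0 or self.stim_fs <= 0:
            raise ValueError("sampling rates must be positive")
        if self.duration_s <= 0:
            raise ValueError("duration must be positive")
        t = self.spikes["time_s"].to_numpy()
        if t.size and (t.min() < 0 or t.max() > self.duration_s):
            raise ValueError("spike times must lie in [0, duration_s]")

    def spike_times_by_unit(self) -> list[np.ndarray]:
        """Sorted spike times (seconds) per unit id 0..n_units-1."""
        out = []
        by = self.spikes.groupby("unit")["time_s"]
        groups = {int(k): np.sort(v.to_numpy()) for k, v in by}
        for u in range(self.n_units):
            out.append(groups.get(u, np.empty(0)))
        return out


@dataclass(eq=False)
class DecodingDataset:
    """Windowed samples with aligned targets.

    ``times_ms[k]`` is the right edge of window ``k``; the target is the
    stimulus at that edge (windows are causal).
    """

    samples: list[MultiscaleSample]
    targets: np.ndarray            # (n_samples, n_output_channels)
    times_ms: np.ndarray           # (n_samples,)
    step: float
    T_s: float
    T_x: float
    alignment: str = "right_edge"

    def __post_init__(self) -> None:
        self.targets = np.atleast_2d(np.asarray(self.targets, dtype=float))
        if self.targets.shape[0] != len(self.samples):
            raise ValueError("sample/target counts differ")

    def __len__(self) -> int:
        return len(self.samples)


def slide_windows(
    rec: Recording,
    T_s: float = 9.0,
    T_x: float = 20.0,
    step: float = 5.0,
    target_lag_ms: float = 0.0,
) -> DecodingDataset:
    """Slide causal windows over a recording.

    ``target_lag_ms`` shifts the target back in time: the target of the
    window ending at ``t_k`` is the stimulus at ``t_k - target_lag_ms``.
    This is how a window is paired with the stimulation pulse whose evoked
    response it contains (inverse modeling); for ordinary decoding it is 0.

    The first window ends at the first multiple of ``step`` that is at least
    ``max(T_s, T_x) + target_lag_ms``, the last at the final multiple of
    ``step`` within the recording.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    dur_ms = rec.duration_s * 1000.0
    maxT = max(T_s, T_x)
    if maxT > dur_ms:
        raise WindowMismatchError("window longer than recording")
    lead = maxT + max(target_lag_ms, 0.0)
    k_min = int(math.ceil(lead / step - 1e-9))
    k_max = int(math.floor(dur_ms / step + 1e-9))
    if k_max < k_min:
        raise WindowMismatchError("recording too short for a single window")
    times = np.arange(k_min, k_max + 1) * step

    unit_times_ms = [t * 1000.0 for t in rec.spike_times_by_unit()]
    tau_x = 1000.0 / rec.lfp_fs
    n_x = int(round(T_x / tau_x))
    if n_x < 1:
        raise ValueError("T_x shorter than one LFP sample period")
    lfp = rec.lfp

    samples = []
    for t_k in times:
        units = []
        t0 = t_k - T_s
        for ut in unit_times_ms:
            lo = np.searchsorted(ut, t0, side="right")
            hi = np.searchsorted(ut, t_k, side="right")
            units.append(SpikeWindow(ut[lo:hi] - t0, T_s))
        # LFP sample i represents time (i + 1) * tau; window is (t_k - T_x, t_k]
        end = int(round(t_k / tau_x))
        chans = tuple(
            LFPWindow(lfp[end - n_x : end, c], tau_x) for c in range(lfp.shape[1])
        )
        samples.append(
            MultiscaleSample(MultiunitSpikeWindow(tuple(units)), MultichannelLFPWindow(chans))
        )

    # nearest stimulus sample to each (possibly lagged) target time
    t_target = times - target_lag_ms
    tau_st = 1000.0 / rec.stim_fs
    idx = np.clip(
        np.round(t_target / tau_st).astype(int) - 1, 0, rec.stimulus.shape[0] - 1
    )
    targets = rec.stimulus[idx, :]
    return DecodingDataset(samples, targets, times, step, T_s, T_x)


# ---------------------------------------------------------------------------
# time-scale estimation
# ---------------------------------------------------------------------------

def autocorr(y: np.ndarray, max_lag: int) -> np.ndarray:
    """Sample autocorrelation coefficients ``rho_0..rho_max_lag``.

    Uses the standard biased estimator (sum of lagged products over the total
    sum of squares).  2-D input (time, channels) is computed per channel and
    averaged.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    if y.shape[0] <= max_lag:
        raise ValueError("signal must be longer than max_lag")
    if np.any(np.ptp(y, axis=0) == 0):
        raise DegenerateScaleError("constant signal has no autocorrelation")
    rhos = np.stack(
        [acf(y[:, c], nlags=max_lag, fft=True, adjusted=False) for c in range(y.shape[1])]
    )
    return rhos.mean(axis=0)


def autocorr_bounds(rho: np.ndarray, N: int, h: int) -> tuple[float, float]:
    """Approximate 95% confidence bounds of a zero autocorrelation at lag
    ``h``: ``+- 2 * sqrt((1 + 2 sum_{i<h} rho_i^2) / N)``."""
    if N <= 0 or h < 1:
        raise ValueError("need N > 0 and h >= 1")
    rho = np.asarray(rho, dtype=float)
    se = math.sqrt((1.0 + 2.0 * float(np.sum(rho[1:h] ** 2))) / N)
    return (-2.0 * se, 2.0 * se)


class WindowLengthEstimate(NamedTuple):
    """Result of the autocorrelation window-length criterion."""

    length_ms: float
    lag: int
    converged: bool  # False when the ACF never stays inside the bounds


def estimate_window_length(
    y: np.ndarray, max_lag: int, sample_period: float = 1.0
) -> WindowLengthEstimate:
    """Smallest lag beyond which the autocorrelation stays inside the zero
    confidence band, converted to ms.

    If no lag sustains insignificance up to ``max_lag``, the estimate is
    ``max_lag`` with ``converged=False``.
    """
    y = np.asarray(y, dtype=float)
    N = y.shape[0]
    rho = autocorr(y, max_lag)
    inside = np.empty(max_lag + 1, dtype=bool)
    inside[0] = False
    for h in range(1, max_lag + 1):
        lo, hi = autocorr_bounds(rho, N, h)
        inside[h] = lo < rho[h] < hi
    sustained = np.flip(np.logical_and.accumulate(np.flip(inside[1:])))
    hits = np.nonzero(sustained)[0]
    if hits.size:
        h_star = int(hits[0]) + 1
        return WindowLengthEstimate(h_star * sample_period, h_star, True)
    return WindowLengthEstimate(max_lag * sample_period, max_lag, False)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def nmse(y: np.ndarray, d: np.ndarray) -> float:
    """Normalized mean squared error ``sum (y - d)^2 / sum (d - mean d)^2``.

    Equals 0 for a perfect reconstruction and 1 for predicting the target
    mean.  Invariant to adding a common constant to both signals.
    """
    y = np.asarray(y, dtype=float).ravel()
    d = np.asarray(d, dtype=float).ravel()
    if y.shape != d.shape:
        raise ValueError("y and d must have equal length")
    num = float(np.sum((y - d) ** 2))
    denom = float(np.sum((d - d.mean()) ** 2))
    if denom == 0.0:
        if num == 0.0:
            return 0.0  # exact reconstruction of a constant target
        raise DegenerateScaleError("target signal is constant")
    return num / denom


def binned_counts(
    spikes: pd.DataFrame, n_units: int, duration_s: float, bin_ms: float
) -> np.ndarray:
    """Per-unit spike counts in contiguous bins, shape (units, bins)."""
    if bin_ms <= 0:
        raise ValueError("bin_ms must be positive")
    n_bins = int(round(duration_s * 1000.0 / bin_ms))
    edges = np.arange(n_bins + 1) * (bin_ms / 1000.0)
    out = np.zeros((n_units, n_bins))
    for u, t in enumerate(
        Recording(
            spikes=spikes, n_units=n_units, lfp=np.zeros((1, 1)), lfp_fs=1.0,
            stimulus=np.zeros((1, 1)), stim_fs=1.0, duration_s=duration_s,
        ).spike_times_by_unit()
    ):
        out[u], _ = np.histogram(t, bins=edges)
    return out


def binned_correlation(
    spikes_a: pd.DataFrame,
    spikes_b: pd.DataFrame,
    n_units: int,
    duration_s: float,
    bin_ms: float = 5.0,
) -> float:
    """Mean over units of the Pearson correlation between binned counts of
    two spike responses observed over the same span.

    Units whose count vector is constant on either side carry no correlation
    information and are skipped; if every unit is degenerate an error is
    raised.
    """
    ca = binned_counts(spikes_a, n_units, duration_s, bin_ms)
    cb = binned_counts(spikes_b, n_units, duration_s, bin_ms)
    ccs = []
    for u in range(n_units):
        if np.ptp(ca[u]) == 0 or np.ptp(cb[u]) == 0:
            continue
        ccs.append(float(np.corrcoef(ca[u], cb[u])[0, 1]))
    if not ccs:
        raise DegenerateScaleError("all bin-count vectors are constant")
    return float(np.mean(ccs))


def binned_crosscorrelation(
    spikes_a: pd.DataFrame,
    spikes_b: pd.DataFrame,
    n_units: int,
    duration_s: float,
    bin_ms: float = 5.0,
    max_lag_bins: int = 10,
) -> tuple[np.ndarray, np.ndarray]:
    """Unit-averaged Pearson correlation of binned counts at integer bin
    lags.  Returns ``(lags, cc)``; a peak at lag 0 means the two responses
    are time-locked, and a peak at a positive lag means the *first* train
    lags the second by that many bins."""
    ca = binned_counts(spikes_a, n_units, duration_s, bin_ms)
    cb = binned_counts(spikes_b, n_units, duration_s, bin_ms)
    lags = np.arange(-max_lag_bins, max_lag_bins + 1)
    cc = np.zeros(lags.size)
    for i, lag in enumerate(lags):
        if lag >= 0:
            xa, xb = ca[:, lag:], cb[:, : cb.shape[1] - lag]
        else:
            xa, xb = ca[:, :lag], cb[:, -lag:]
        vals = []
        for u in range(n_units):
            if np.ptp(xa[u]) == 0 or np.ptp(xb[u]) == 0:
                continue
            vals.append(float(np.corrcoef(xa[u], xb[u])[0, 1]))
        cc[i] = np.mean(vals) if vals else 0.0
    return lags, cc


# ---------------------------------------------------------------------------
# decoder wrappers
# ---------------------------------------------------------------------------

def train_decoder(
    ds: DecodingDataset,
    spec: CompositeKernelSpec | None = None,
    learning_rate: float = 0.5,
    quantization_size: float = 0.0,
    epochs: int = 3,
) -> tuple[QKLMSModel, LearningTrace]:
    """Fit a Q-KLMS decoder on a windowed dataset.

    Unset kernel sizes are resolved from the training samples with the
    average-pairwise-distance heuristic.
    """
    spec = (spec or CompositeKernelSpec()).resolved(ds.samples)
    model = QKLMSModel(
        spec, n_outputs=ds.targets.shape[1],
        learning_rate=learning_rate, quantization_size=quantization_size,
    )
    trace = train(model, ds.samples, ds.targets, epochs=epochs)
    return model, trace


def evaluate_decoder(
    model: QKLMSModel, ds: DecodingDataset, cross_gram: np.ndarray | None = None
) -> np.ndarray:
    """Per-output-channel NMSE of a trained decoder on a dataset.

    Evaluation performs no model updates.
    """
    if cross_gram is None:
        from .kernels import pairwise_kernel

        cross_gram = pairwise_kernel(model.centers, ds.samples, model.kernel_spec)
    preds = model.coefficients @ cross_gram  # (M, K)
    return np.array(
        [nmse(preds[m], ds.targets[:, m]) for m in range(ds.targets.shape[1])]
    )


def compare_modalities(
    train_ds: DecodingDataset,
    test_ds: DecodingDataset,
    rules: Sequence[str] = ("product", "spikes_only", "lfp_only"),
    learning_rate: float = 0.5,
    quantization_size: float = 0.0,
    epochs: int = 3,
    base_spec: CompositeKernelSpec | None = None,
) -> dict[str, np.ndarray]:
    """Train and test one decoder per modality rule on shared kernel blocks.

    The per-modality Gram blocks (direct-sum spike kernel, direct-sum LFP
    kernel) are computed once and recombined per rule, so the three decoders
    see numerically identical factor kernels.  Returns per-rule arrays of
    per-channel test NMSE.
    """
    base = base_spec or CompositeKernelSpec()
    spec = base.resolved(train_ds.samples)
    Ks_tr, Kx_tr = modality_grams(train_ds.samples, None, spec)
    Ks_te, Kx_te = modality_grams(train_ds.samples, test_ds.samples, spec)

    out: dict[str, np.ndarray] = {}
    for rule in rules:
        rspec = CompositeKernelSpec(
            sigma_s=spec.sigma_s, sigma_x=spec.sigma_x,
            smoothing_width=spec.smoothing_width,
            normalize_channels=spec.normalize_channels, modality_rule=rule,
        )
        gram = combine_modalities(Ks_tr, Kx_tr, rule)
        gram = 0.5 * (gram + gram.T)
        model = QKLMSModel(
            rspec, n_outputs=train_ds.targets.shape[1],
            learning_rate=learning_rate, quantization_size=quantization_size,
        )
        train(model, train_ds.samples, train_ds.targets, epochs=epochs, gram=gram)
        src = np.asarray(model.center_sources, dtype=int)
        cross = combine_modalities(Ks_te, Kx_te, rule)[src, :]
        out[rule] = evaluate_decoder(model, test_ds, cross_gram=cross)
    return out
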