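"""Schoenberg kernels on spike trains and LFPs, and their compositions.

The similarity between two spike windows is the Gaussian-type (Schoenberg)
kernel on their estimated intensity functions,

    kappa_s(a, b) = exp(-int_0^Ts (lam_a(t) - lam_b(t))^2 dt / sigma_s^2),

where ``lam`` is obtained by convolving the spike train with a rectangular
smoothing kernel of width ``smoothing_width`` (an estimate of the conditional
intensity from a single realization).  Because the smoothed intensities are
piecewise constant, the integral is computed in closed form from rectangle
overlaps - no gridding is involved.  The LFP kernel is the same Gaussian form
on sampled waveforms with the integral approximated by a left Riemann sum.

Multiunit / multichannel similarities are direct sums (optionally divided by
the channel count so that self-similarity is exactly 1), and the two
modalities are fused either by a tensor product (strict joint similarity) or
a direct sum.  Products and sums of positive-definite kernels are positive
definite, so every composition here defines a valid RKHS.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, replace
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .errors import DegenerateScaleError, WindowMismatchError
from .samples import (
    IntensityEstimate,
    LFPWindow,
    MultichannelLFPWindow,
    MultiscaleSample,
    MultiunitSpikeWindow,
    SpikeWindow,
)

__all__ = [
    "CompositeKernelSpec",
    "estimate_intensity",
    "spike_kernel",
    "multiunit_spike_kernel",
    "lfp_kernel",
    "multichannel_lfp_kernel",
    "joint_kernel",
    "rkhs_distance",
    "gram_matrix",
    "kernel_size_heuristic",
    "pairwise_kernel",
    "modality_grams",
    "combine_modalities",
]

ModalityRule = Literal["product", "sum", "spikes_only", "lfp_only"]

_RULES = ("product", "sum", "spikes_only", "lfp_only")


@dataclass(frozen=True)
class CompositeKernelSpec:
    """Hyperparameters of the composite multiscale kernel.

    Parameters
    ----------
    sigma_s
        Spike kernel size.  ``sigma_s**2`` carries the units of the squared
        intensity-difference integral (1/ms).  ``None`` means "resolve from
        data with :func:`kernel_size_heuristic` before use".
    sigma_x
        LFP kernel size; ``sigma_x**2`` carries the units of the Riemann
        integral of the squared amplitude difference (amplitude^2 * ms).
    smoothing_width
        Width (ms) of the rectangular intensity-smoothing kernel.  ``None``
        defaults to the spike window length at evaluation time, honoring the
        cumulative-count reading of the smoother (width much larger than the
        interspike interval).
    normalize_channels
        Divide each direct-sum kernel by its channel count so that
        self-similarity is 1 and the ``sqrt(2 - 2 kappa)`` distance shortcut
        applies.  The unnormalized, literal direct sum is one flag away.
    modality_rule
        How spike and LFP similarities are fused: ``"product"`` (tensor
        product, strict joint similarity), ``"sum"``, or one of the
        single-modality pass-throughs.
    """

    sigma_s: float | None = None
    sigma_x: float | None = None
    smoothing_width: float | None = None
    normalize_channels: bool = True
    modality_rule: ModalityRule = "product"

    def __post_init__(self) -> None:
        for name in ("sigma_s", "sigma_x", "smoothing_width"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ValueError(f"{name} must be positive, got {v!r}")
        if self.modality_rule not in _RULES:
            raise ValueError(f"modality_rule must be one of {_RULES}")

    # -- serialization ----------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "sigma_s": self.sigma_s,
                "sigma_x": self.sigma_x,
                "smoothing_width_ms": self.smoothing_width,
                "normalize_channels": self.normalize_channels,
                "modality_rule": self.modality_rule,
            }
        )

    @classmethod
    def from_json(cls, doc: str) -> "CompositeKernelSpec":
        d = json.loads(doc)
        return cls(
            sigma_s=d["sigma_s"],
            sigma_x=d["sigma_x"],
            smoothing_width=d["smoothing_width_ms"],
            normalize_channels=bool(d["normalize_channels"]),
            modality_rule=d["modality_rule"],
        )

    def resolved(self, samples: Sequence[MultiscaleSample]) -> "CompositeKernelSpec":
        """Fill any unset kernel size from the data via the pairwise-distance
        heuristic (only for the modalities the rule actually uses)."""
        spec = self
        if spec.sigma_s is None and spec.modality_rule != "lfp_only":
            spec = replace(
                spec,
                sigma_s=kernel_size_heuristic(
                    samples, "spikes", smoothing_width=spec.smoothing_width
                ),
            )
        if spec.sigma_x is None and spec.modality_rule != "spikes_only":
            spec = replace(spec, sigma_x=kernel_size_heuristic(samples, "lfp"))
        return spec


# ---------------------------------------------------------------------------
# intensity estimation
# ---------------------------------------------------------------------------

def estimate_intensity(spikes: SpikeWindow, smoothing_width: float) -> IntensityEstimate:
    """Rectangular-kernel intensity estimate of a windowed spike train.

    Each spike at ``t_m`` contributes ``1/smoothing_width`` on
    ``[t_m, t_m + smoothing_width)``; contributions are truncated to the
    window support ``[0, T_s]``.  The result is an exact piecewise-constant
    function (no gridding).
    """
    if not smoothing_width > 0:
        raise ValueError("smoothing_width must be positive")
    T = spikes.window_length
    t = spikes.times
    if t.size == 0:
        return IntensityEstimate(np.array([0.0, T]), np.array([0.0]))
    starts = np.clip(t, 0.0, T)
    ends = np.clip(t + smoothing_width, 0.0, T)
    edges = np.unique(np.concatenate(([0.0, T], starts, ends)))
    mids = 0.5 * (edges[:-1] + edges[1:])
    # level on each piece = (number of covering rectangles) / width
    counts = (starts[None, :] <= mids[:, None]) & (mids[:, None] < ends[None, :])
    levels = counts.sum(axis=1) / smoothing_width
    return IntensityEstimate(edges, levels.astype(float))


def _smoothing(spec: CompositeKernelSpec, T: float) -> float:
    return T if spec.smoothing_width is None else spec.smoothing_width


def _rect_cross_integral(ta: np.ndarray, tb: np.ndarray, T: float, tau: float) -> float:
    """Closed-form ``int lam_a lam_b dt`` over ``[0, T]`` for rectangular
    smoothing of width ``tau``: a sum of pairwise rectangle overlaps."""
    if ta.size == 0 or tb.size == 0:
        return 0.0
    hi = np.minimum(np.minimum(ta[:, None] + tau, tb[None, :] + tau), T)
    lo = np.maximum(ta[:, None], tb[None, :])
    return float(np.sum(np.maximum(0.0, hi - lo))) / (tau * tau)


def _spike_sq_dist(a: SpikeWindow, b: SpikeWindow, tau: float) -> float:
    """Pre-exponential squared distance ``int (lam_a - lam_b)^2 dt``."""
    T = a.window_length
    d = (
        _rect_cross_integral(a.times, a.times, T, tau)
        + _rect_cross_integral(b.times, b.times, T, tau)
        - 2.0 * _rect_cross_integral(a.times, b.times, T, tau)
    )
    return max(d, 0.0)


def spike_kernel(a: SpikeWindow, b: SpikeWindow, spec: CompositeKernelSpec) -> float:
    """Schoenberg kernel between two single-unit spike windows, in (0, 1]."""
    if a.window_length != b.window_length:
        raise WindowMismatchError("spike windows must share window_length")
    if spec.sigma_s is None:
        raise ValueError("sigma_s is unset; resolve the spec first")
    tau = _smoothing(spec, a.window_length)
    return float(np.exp(-_spike_sq_dist(a, b, tau) / spec.sigma_s**2))


def multiunit_spike_kernel(
    a: MultiunitSpikeWindow, b: MultiunitSpikeWindow, spec: CompositeKernelSpec
) -> float:
    """Direct-sum kernel over units, matched by index."""
    if a.n_units != b.n_units:
        raise WindowMismatchError("unit counts differ")
    total = sum(spike_kernel(ua, ub, spec) for ua, ub in zip(a.units, b.units))
    return total / a.n_units if spec.normalize_channels else total


def lfp_kernel(a: LFPWindow, b: LFPWindow, spec: CompositeKernelSpec) -> float:
    """Schoenberg kernel between two single-channel LFP windows.

    The integral is the left Riemann sum ``sum_k (a_k - b_k)^2 * tau_samp``,
    so ``sigma_x**2`` has time-integral units and the value is invariant to
    resampling in the fine-grid limit.
    """
    if a.samples.size != b.samples.size or a.sample_period != b.sample_period:
        raise WindowMismatchError("LFP windows must share shape and sample_period")
    if spec.sigma_x is None:
        raise ValueError("sigma_x is unset; resolve the spec first")
    d = float(np.sum((a.samples - b.samples) ** 2)) * a.sample_period
    return float(np.exp(-d / spec.sigma_x**2))


def multichannel_lfp_kernel(
    a: MultichannelLFPWindow, b: MultichannelLFPWindow, spec: CompositeKernelSpec
) -> float:
    """Direct-sum kernel over LFP channels, matched by index."""
    if a.n_channels != b.n_channels:
        raise WindowMismatchError("channel counts differ")
    total = sum(lfp_kernel(ca, cb, spec) for ca, cb in zip(a.channels, b.channels))
    return total / a.n_channels if spec.normalize_channels else total


def joint_kernel(
    a: MultiscaleSample, b: MultiscaleSample, spec: CompositeKernelSpec
) -> float:
    """Composite similarity of two multiscale samples under the spec's rule.

    The tensor product is a strict joint similarity: if either modality's
    factor is ~0 the product is ~0 regardless of the other factor.
    """
    rule = spec.modality_rule
    if rule == "spikes_only":
        return multiunit_spike_kernel(a.spikes, b.spikes, spec)
    if rule == "lfp_only":
        return multichannel_lfp_kernel(a.lfp, b.lfp, spec)
    ks = multiunit_spike_kernel(a.spikes, b.spikes, spec)
    kx = multichannel_lfp_kernel(a.lfp, b.lfp, spec)
    return ks * kx if rule == "product" else ks + kx


def rkhs_distance(k_aa: float, k_bb: float, k_ab: float) -> float:
    """Distance induced in the RKHS by a kernel:
    ``sqrt(kappa(a,a) + kappa(b,b) - 2 kappa(a,b))``.

    The argument of the square root is clipped at zero against round-off; for
    normalized kernels this reduces to ``sqrt(2 - 2 kappa)``.
    """
    return float(np.sqrt(max(k_aa + k_bb - 2.0 * k_ab, 0.0)))


# ---------------------------------------------------------------------------
# batch evaluation
# ---------------------------------------------------------------------------

def _pad_unit_times(windows: Sequence[SpikeWindow]) -> tuple[np.ndarray, np.ndarray]:
    """Stack ragged spike-time arrays into a padded (K, M) matrix + mask."""
    K = len(windows)
    M = max((w.times.size for w in windows), default=0)
    times = np.zeros((K, max(M, 1)))
    mask = np.zeros((K, max(M, 1)), dtype=bool)
    for i, w in enumerate(windows):
        m = w.times.size
        times[i, :m] = w.times
        mask[i, :m] = True
    return times, mask

def _unit_sq_dist_matrix(
    wa: Sequence[SpikeWindow], wb: Sequence[SpikeWindow], T: float, tau: float
) -> np.ndarray:
    """Pre-exponential squared intensity distances for one unit, all pairs."""
    ta, ma = _pad_unit_times(wa)
    tb, mb = _pad_unit_times(wb)

    def _cross(t1, m1, t2, m2):
        # sum of rectangle overlaps, accumulated spike-pair by spike-pair to
        # keep memory at O(K_a * K_b)
        q = np.zeros((t1.shape[0], t2.shape[0]))
        for m in range(t1.shape[1]):
            for n in range(t2.shape[1]):
                hi = np.minimum(np.minimum(t1[:, m, None] + tau, t2[None, :, n] + tau), T)
                lo = np.maximum(t1[:, m, None], t2[None, :, n])
                ov = np.maximum(0.0, hi - lo)
                ov *= m1[:, m, None] & m2[None, :, n]
                q += ov
        return q / (tau * tau)

    def _self(t1, m1):
        q = np.zeros(t1.shape[0])
        for m in range(t1.shape[1]):
            for n in range(t1.shape[1]):
                hi = np.minimum(np.minimum(t1[:, m] + tau, t1[:, n] + tau), T)
                lo = np.maximum(t1[:, m], t1[:, n])
                q += np.maximum(0.0, hi - lo) * (m1[:, m] & m1[:, n])
        return q / (tau * tau)

    qaa = _self(ta, ma)
    qbb = _self(tb, mb)
    qab = _cross(ta, ma, tb, mb)
    return np.maximum(qaa[:, None] + qbb[None, :] - 2.0 * qab, 0.0)


def _spike_unit_windows(samples: Sequence[MultiscaleSample], unit: int):
    return [s.spikes.units[unit] for s in samples]


def _check_congruent(samples: Sequence[MultiscaleSample]) -> None:
    s0 = samples[0]
    for s in samples[1:]:
        if s.spikes.n_units != s0.spikes.n_units:
            raise WindowMismatchError("unit counts differ across samples")
        if s.spikes.window_length != s0.spikes.window_length:
            raise WindowMismatchError("spike window lengths differ across samples")
        if (
            s.lfp.n_channels != s0.lfp.n_channels
            or s.lfp.channels[0].samples.size != s0.lfp.channels[0].samples.size
            or s.lfp.channels[0].sample_period != s0.lfp.channels[0].sample_period
        ):
            raise WindowMismatchError("LFP shapes differ across samples")


def modality_grams(
    A: Sequence[MultiscaleSample],
    B: Sequence[MultiscaleSample] | None,
    spec: CompositeKernelSpec,
) -> tuple[np.ndarray, np.ndarray]:
    """Direct-sum spike and LFP Gram blocks between two sample lists.

    Returns ``(K_s, K_x)``, each of shape ``(len(A), len(B))``.  Passing
    ``B=None`` evaluates ``A`` against itself.  These blocks are the shared
    ingredients of every modality rule, so callers comparing rules can reuse
    them via :func:`combine_modalities`.
    """
    symmetric = B is None
    B = A if B is None else B
    _check_congruent(list(A) + list(B))
    if spec.sigma_s is None or spec.sigma_x is None:
        raise ValueError("kernel sizes are unset; resolve the spec first")

    s0 = A[0]
    T_s = s0.spikes.window_length
    tau = _smoothing(spec, T_s)
    n_units = s0.spikes.n_units
    n_ch = s0.lfp.n_channels
    dt = s0.lfp.channels[0].sample_period

    Ks = np.zeros((len(A), len(B)))
    for u in range(n_units):
        D = _unit_sq_dist_matrix(
            _spike_unit_windows(A, u), _spike_unit_windows(B, u), T_s, tau
        )
        Ks += np.exp(-D / spec.sigma_s**2)
    if spec.normalize_channels:
        Ks /= n_units

    Kx = np.zeros((len(A), len(B)))
    for c in range(n_ch):
        Xa = np.stack([s.lfp.channels[c].samples for s in A])
        Xb = Xa if symmetric else np.stack([s.lfp.channels[c].samples for s in B])
        D = cdist(Xa, Xb, "sqeuclidean") * dt
        Kx += np.exp(-D / spec.sigma_x**2)
    if spec.normalize_channels:
        Kx /= n_ch
    return Ks, Kx


def combine_modalities(Ks: np.ndarray, Kx: np.ndarray, rule: ModalityRule) -> np.ndarray:
    if rule == "product":
        return Ks * Kx
    if rule == "sum":
        return Ks + Kx
    if rule == "spikes_only":
        return Ks
    if rule == "lfp_only":
        return Kx
    raise ValueError(f"unknown modality rule {rule!r}")


def pairwise_kernel(
    A: Sequence[MultiscaleSample],
    B: Sequence[MultiscaleSample] | None,
    spec: CompositeKernelSpec,
) -> np.ndarray:
    """Kernel matrix between two sample lists under the spec's rule."""
    Ks, Kx = modality_grams(A, B, spec)
    return combine_modalities(Ks, Kx, spec.modality_rule)


def gram_matrix(
    samples: Sequence[MultiscaleSample], spec: CompositeKernelSpec
) -> np.ndarray:
    """Symmetric Gram matrix of a sample list.

    The result is positive semidefinite up to numerical tolerance for every
    modality rule, being a sum/product of positive-definite kernels.
    """
    if len(samples) == 0:
        raise ValueError("need at least one sample")
    G = pairwise_kernel(samples, None, spec)
    return 0.5 * (G + G.T)  # exact symmetrization against round-off


# ---------------------------------------------------------------------------
# kernel size heuristic
# ---------------------------------------------------------------------------

def kernel_size_heuristic(
    samples: Sequence,
    modality: Literal["spikes", "lfp"],
    smoothing_width: float | None = None,
) -> float:
    """Data-driven kernel size from the average pairwise sample distance.

    ``sigma**2`` is the mean, over all unordered training-sample pairs and
    over units/channels, of the *pre-exponential* squared distance (the
    intensity-difference integral for spikes; the Riemann amplitude integral
    for LFPs).  Averaging the pre-exponential distances avoids the circular
    definition one gets by measuring distances in the very RKHS whose scale
    is being chosen.

    ``samples`` may be :class:`MultiscaleSample` objects or bare
    spike/LFP windows of the requested modality.
    """
    if len(samples) < 2:
        raise ValueError("need at least two samples")

    if all(isinstance(s, MultiscaleSample) for s in samples):
        # batch path: one distance matrix per unit/channel, averaged
        samples = list(samples)
        K = len(samples)
        iu = np.triu_indices(K, 1)
        if modality == "spikes":
            T = samples[0].spikes.window_length
            tau = T if smoothing_width is None else smoothing_width
            n_units = samples[0].spikes.n_units
            D = np.zeros((K, K))
            for u in range(n_units):
                w = _spike_unit_windows(samples, u)
                D += _unit_sq_dist_matrix(w, w, T, tau)
            mean_sq = float(np.mean(D[iu])) / n_units
        elif modality == "lfp":
            dt = samples[0].lfp.channels[0].sample_period
            n_ch = samples[0].lfp.n_channels
            D = np.zeros((K, K))
            for c in range(n_ch):
                X = np.stack([s.lfp.channels[c].samples for s in samples])
                D += cdist(X, X, "sqeuclidean") * dt
            mean_sq = float(np.mean(D[iu])) / n_ch
        else:
            raise ValueError("modality must be 'spikes' or 'lfp'")
        if mean_sq <= 0.0:
            raise DegenerateScaleError(
                "all samples are identical; kernel size cannot be estimated"
            )
        return float(np.sqrt(mean_sq))

    if modality == "spikes":
        windows: list[MultiunitSpikeWindow] = [
            s.spikes if isinstance(s, MultiscaleSample) else s for s in samples
        ]
        windows = [
            MultiunitSpikeWindow((w,)) if isinstance(w, SpikeWindow) else w
            for w in windows
        ]
        T = windows[0].window_length
        tau = T if smoothing_width is None else smoothing_width
        total, n_pairs = 0.0, 0
        for a, b in itertools.combinations(windows, 2):
            per_unit = [
                _spike_sq_dist(ua, ub, tau) for ua, ub in zip(a.units, b.units)
            ]
            total += float(np.mean(per_unit))
            n_pairs += 1
    elif modality == "lfp":
        lfps: list[MultichannelLFPWindow] = [
            s.lfp if isinstance(s, MultiscaleSample) else s for s in samples
        ]
        lfps = [
            MultichannelLFPWindow((w,)) if isinstance(w, LFPWindow) else w
            for w in lfps
        ]
        dt = lfps[0].channels[0].sample_period
        total, n_pairs = 0.0, 0
        for a, b in itertools.combinations(lfps, 2):
            d = np.mean(
                [
                    np.sum((ca.samples - cb.samples) ** 2) * dt
                    for ca, cb in zip(a.channels, b.channels)
                ]
            )
            total += float(d)
            n_pairs += 1
    else:
        raise ValueError("modality must be 'spikes' or 'lfp'")

    mean_sq = total / n_pairs
    if mean_sq <= 0.0:
        raise DegenerateScaleError(
            "all samples are identical; kernel size cannot be estimated"
        )
    return float(np.sqrt(mean_sq))
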