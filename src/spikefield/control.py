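"""Filtered-error adaptive inverse control of neural responses in RKHS.

The plant is the stimulated neural circuit: multichannel microstimulation in,
multiscale neural response out.  A kernel inverse model ``P^-1`` (a Q-KLMS
decoder from neural windows to per-channel stimulation amplitude) doubles as
the initial controller ``C``.  During control, the target neural response is
fed through ``C`` to produce raw stimulation amplitudes; these are
post-processed into a deliverable pulse sequence; the plant's actual response
``z`` is compared to the (delay-aligned) target ``x`` *through the inverse
model*, giving the filtered error per stimulation channel

    eps_j = W_j phi(x_delta) - W_j phi(z),

which adapts only the controller's coefficient matrix - its dictionary stays
frozen so the control law remains a fixed-size kernel expansion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .errors import EmptyModelError, SpikefieldError
from .kernels import pairwise_kernel
from .qklms import QKLMSModel, train
from .samples import MultiscaleSample

__all__ = [
    "StimulationSequence",
    "StimulationConstraints",
    "audit_stimulation",
    "constrain_stimulation",
    "filtered_error",
    "update_controller",
    "initialize_controller",
    "run_control_loop",
    "ControlTrace",
]


@dataclass(frozen=True)
class StimulationConstraints:
    """Hardware-safety rules for deliverable microstimulation."""

    min_interval_ms: float = 10.0     # per-channel inter-pulse spacing
    amplitude_range_ua: tuple[float, float] = (8.0, 30.0)
    exclusive_channels: bool = True   # one channel only at any time point


@dataclass(eq=False)
class StimulationSequence:
    """Per-channel microstimulation pulses (times in ms, amplitudes in uA)."""

    times_ms: np.ndarray
    channels: np.ndarray
    amplitudes_ua: np.ndarray
    n_channels: int
    duration_s: float

    def __post_init__(self) -> None:
        t = np.asarray(self.times_ms, dtype=float)
        c = np.asarray(self.channels, dtype=int)
        a = np.asarray(self.amplitudes_ua, dtype=float)
        if not (t.shape == c.shape == a.shape):
            raise ValueError("times, channels and amplitudes must align")
        order = np.lexsort((c, t))
        self.times_ms = t[order]
        self.channels = c[order]
        self.amplitudes_ua = a[order]
        if t.size and (c.min() < 0 or c.max() >= self.n_channels):
            raise ValueError("channel index out of range")
        if t.size and (t.min() < 0 or t.max() > self.duration_s * 1000.0):
            raise ValueError("pulse times outside the sequence duration")

    @property
    def n_pulses(self) -> int:
        return int(self.times_ms.size)

    def channel_pulses(self, channel: int) -> tuple[np.ndarray, np.ndarray]:
        m = self.channels == channel
        return self.times_ms[m], self.amplitudes_ua[m]

    def dense(self, sample_period_ms: float, start_ms: float = 0.0) -> np.ndarray:
        """Amplitude matrix (channels, samples) on a regular grid; each pulse
        lands on its nearest grid point."""
        n = int(round((self.duration_s * 1000.0 - start_ms) / sample_period_ms)) + 1
        out = np.zeros((self.n_channels, n))
        idx = np.round((self.times_ms - start_ms) / sample_period_ms).astype(int)
        ok = (idx >= 0) & (idx < n)
        out[self.channels[ok], idx[ok]] = self.amplitudes_ua[ok]
        return out


def audit_stimulation(
    seq: StimulationSequence, constraints: StimulationConstraints = StimulationConstraints()
) -> list[str]:
    """Check a sequence against the delivery constraints; returns a list of
    human-readable violations (empty when compliant)."""
    viol: list[str] = []
    lo, hi = constraints.amplitude_range_ua
    for i, (t, c, a) in enumerate(
        zip(seq.times_ms, seq.channels, seq.amplitudes_ua)
    ):
        if not (lo <= a <= hi):
            viol.append(f"pulse {i}: amplitude {a:.3f} uA outside [{lo}, {hi}]")
    for c in range(seq.n_channels):
        t, _ = seq.channel_pulses(c)
        gaps = np.diff(np.sort(t))
        for g in gaps[gaps < constraints.min_interval_ms]:
            viol.append(f"channel {c}: inter-pulse interval {g:.3f} ms < "
                        f"{constraints.min_interval_ms} ms")
    if constraints.exclusive_channels:
        t_sorted = np.sort(seq.times_ms)
        dup = t_sorted[:-1][np.diff(t_sorted) == 0]
        for t in np.unique(dup):
            viol.append(f"multiple channels pulse simultaneously at {t:.3f} ms")
    return viol


def constrain_stimulation(
    raw: np.ndarray,
    sample_period_ms: float,
    duration_s: float | None = None,
    start_ms: float = 0.0,
    constraints: StimulationConstraints = StimulationConstraints(),
) -> StimulationSequence:
    """Turn raw per-channel amplitude traces into a deliverable pulse train.

    Per channel, candidate pulses are the strictly positive local maxima of
    the raw trace; candidates closer than the minimum interval are thinned by
    non-maximum suppression in descending amplitude order (a deterministic
    stand-in for flat-kernel mode seeking on 10 ms neighborhoods).  At any
    surviving time point only the largest-amplitude channel keeps its pulse
    (ties go to the lowest channel index).  Surviving amplitudes are clipped
    into the allowed range; sub-minimum candidates are raised to the range
    floor rather than dropped, since the range describes what the stimulator
    delivers, not a rejection rule.
    """
    raw = np.atleast_2d(np.asarray(raw, dtype=float))
    if not np.all(np.isfinite(raw)):
        raise ValueError("raw stimulation must be finite")
    M, T = raw.shape
    if duration_s is None:
        duration_s = (start_ms + (T - 1) * sample_period_ms) / 1000.0

    kept_t, kept_c, kept_a = [], [], []
    for c in range(M):
        x = raw[c]
        # local maxima (plateau edges count once), strictly positive
        cand = [
            i for i in range(T)
            if x[i] > 0
            and (i == 0 or x[i] >= x[i - 1])
            and (i == T - 1 or x[i] > x[i + 1])
        ]
        # greedy non-maximum suppression, largest amplitude first
        cand.sort(key=lambda i: (-x[i], i))
        chosen: list[int] = []
        for i in cand:
            t_i = start_ms + i * sample_period_ms
            if all(
                abs(t_i - (start_ms + j * sample_period_ms))
                >= constraints.min_interval_ms
                for j in chosen
            ):
                chosen.append(i)
        for i in chosen:
            kept_t.append(start_ms + i * sample_period_ms)
            kept_c.append(c)
            kept_a.append(x[i])

    kept_t = np.asarray(kept_t)
    kept_c = np.asarray(kept_c, dtype=int)
    kept_a = np.asarray(kept_a)

    if constraints.exclusive_channels and kept_t.size:
        keep = np.ones(kept_t.size, dtype=bool)
        for t in np.unique(kept_t):
            at = np.nonzero(kept_t == t)[0]
            if at.size > 1:
                # max amplitude wins, ties to the lowest channel index
                order = sorted(at, key=lambda i: (-kept_a[i], kept_c[i]))
                keep[order[1:]] = False
        kept_t, kept_c, kept_a = kept_t[keep], kept_c[keep], kept_a[keep]

    lo, hi = constraints.amplitude_range_ua
    kept_a = np.clip(kept_a, lo, hi)
    return StimulationSequence(kept_t, kept_c, kept_a, M, duration_s)


# ---------------------------------------------------------------------------
# filtered-error adaptation
# ---------------------------------------------------------------------------

def filtered_error(
    inv: QKLMSModel, x_delayed: MultiscaleSample, z: MultiscaleSample
) -> np.ndarray:
    """Overall system error filtered through the inverse plant model:
    ``inv.predict(x_delayed) - inv.predict(z)`` per stimulation channel."""
    if inv.n_centers == 0:
        raise EmptyModelError("inverse model has no centers")
    return inv.predict(x_delayed) - inv.predict(z)


def update_controller(
    ctrl: QKLMSModel,
    x: MultiscaleSample,
    eps: np.ndarray,
    learning_rate: float | None = None,
) -> None:
    """Filtered-error coefficient update on a frozen-dictionary controller.

    The coefficient column of the center the input quantizes onto receives
    ``eta * eps``; if the input is farther than the quantization size from
    every center, the nearest center is still used (the dictionary never
    grows during control).
    """
    if ctrl.n_centers == 0:
        raise EmptyModelError("controller has no centers")
    eps = np.asarray(eps, dtype=float)
    eta = ctrl.learning_rate if learning_rate is None else learning_rate
    idx, _ = ctrl.nearest_center(x)
    ctrl._coef_arr[:, idx] += eta * eps


def initialize_controller(
    dataset,
    spec=None,
    learning_rate: float = 0.5,
    quantization_size: float = 0.0,
    epochs: int = 3,
) -> tuple[QKLMSModel, QKLMSModel]:
    """Train the inverse plant model on random-stimulation data and clone it
    as the controller.

    ``dataset`` maps plant responses (neural windows) to the stimulation
    amplitudes that evoked them (a :class:`~spikefield.decoding.DecodingDataset`
    built with a target lag of the modeling delay).  Returns
    ``(inverse_model, controller)``; the controller's dictionary is frozen by
    contract - control-time adaptation touches only its coefficients.
    """
    from .decoding import train_decoder  # local import to avoid a cycle

    if len(dataset) == 0:
        raise ValueError("initialization dataset is empty")
    inv, _ = train_decoder(
        dataset, spec=spec, learning_rate=learning_rate,
        quantization_size=quantization_size, epochs=epochs,
    )
    ctrl = inv.copy()
    return inv, ctrl


@dataclass
class ControlTrace:
    """Per-epoch summary of a control run."""

    mean_abs_error: np.ndarray          # (epochs,) mean |filtered error|
    dict_size_inverse: np.ndarray       # (epochs,) inverse-model centers


def run_control_loop(
    ctrl: QKLMSModel,
    inv: QKLMSModel,
    plant: Callable[[StimulationSequence], "object"] | None,
    target,
    delta_ms: float | None = None,
    epochs: int = 5,
    T_s: float = 9.0,
    T_x: float = 20.0,
    step: float = 5.0,
    eta_ctrl: float = 0.01,
    update_inverse: bool = False,
    constraints: StimulationConstraints = StimulationConstraints(),
    output_gain: float | str = "auto",
    emission_offset_ms: float = 5.0,
):
    """Open- or closed-loop adaptive inverse control toward a target response.

    The target :class:`~spikefield.decoding.Recording` is windowed; the
    controller maps each target window (right edge ``t_k``) to stimulation
    amplitudes emitted at ``t_k - delta``, where the modeling delay ``delta``
    defaults to ``max(T_s, T_x)`` so the controller input window fully covers
    the response it must anticipate.  Advancing the stimulation by the same
    delay keeps the controlled response time-locked to the target at lag
    zero.

    With ``plant=None`` the loop is open: the constrained stimulation
    sequence is emitted after a single pass, with no plant calls and no
    adaptation.  Otherwise, per epoch: predict raw stimulation, constrain it,
    drive the plant, window its response ``z``, and adapt the controller
    coefficients with the filtered error on delay-aligned targets.  By
    default the inverse model stays as pretrained (the error filter is a
    fixed reference, as in offline open-loop generation); pass
    ``update_inverse=True`` to also keep training it online on
    ``(z, delivered stimulation)`` while it filters the error.

    Returns ``(stim_sequence, trace, last_response)`` where ``trace`` holds
    the mean absolute filtered error per epoch (empty for open loop).
    """
    from .decoding import slide_windows  # local import to avoid a cycle

    if ctrl.n_centers == 0 or inv.n_centers == 0:
        raise EmptyModelError("controller and inverse model must be trained")
    delta = max(T_s, T_x) if delta_ms is None else float(delta_ms)
    M = ctrl.n_outputs

    tgt_ds = slide_windows(target, T_s=T_s, T_x=T_x, step=step, target_lag_ms=delta)
    X = tgt_ds.samples
    tx = tgt_ds.times_ms
    # stimulation emission grid: advanced by the modeling delay, then pushed
    # back by the emission-phase calibration (the plant responds with a few
    # ms latency; delivering one grid step after t - delta keeps the evoked
    # response centered on the target's)
    te = tx - delta + emission_offset_ms
    spec = ctrl.kernel_spec

    Kcx = pairwise_kernel(ctrl.centers, X, spec)      # frozen for the run

    def _emit() -> StimulationSequence:
        raw = ctrl.coefficients @ Kcx                 # (M, K)
        # stimulator gain calibration: kernel regression attenuates the
        # amplitude scale it was trained on, so map the upper tail of the
        # positive raw output onto the top of the deliverable range to keep
        # the emitted pulses amplitude-modulated rather than floor-clipped
        if output_gain == "auto":
            pos = raw[raw > 0]
            gain = (
                constraints.amplitude_range_ua[1] / np.quantile(pos, 0.95)
                if pos.size else 1.0
            )
        else:
            gain = float(output_gain)
        return constrain_stimulation(
            gain * raw, sample_period_ms=step, duration_s=target.duration_s,
            start_ms=float(te[0]), constraints=constraints,
        )

    if plant is None:
        return _emit(), ControlTrace(np.zeros(0), np.zeros(0, dtype=int)), None

    # controller-side matches are fixed: centers and targets do not move
    diag_x = np.diag(pairwise_kernel(X, None, spec))
    d2 = np.maximum(
        ctrl.self_similarities[:, None] + diag_x[None, :] - 2.0 * Kcx, 0.0
    )
    match_idx = np.argmin(d2, axis=0)

    KiX = pairwise_kernel(inv.centers, X, spec)       # grows with inv
    mean_abs, inv_sizes = [], []
    seq = None
    z_rec = None
    for _ in range(epochs):
        seq = _emit()
        z_rec = plant(seq)
        z_ds = slide_windows(z_rec, T_s=T_s, T_x=T_x, step=step, target_lag_ms=delta)
        Z = z_ds.samples
        if len(Z) != len(X):
            raise SpikefieldError("plant response does not span the target duration")
        delivered = seq.dense(step, start_ms=float(te[0]))[:, : len(X)]

        n_before = inv.n_centers
        G_old = pairwise_kernel(inv.centers, Z, spec)
        Pzz = pairwise_kernel(Z, None, spec)
        if update_inverse:
            train(inv, Z, delivered.T, epochs=1, gram=Pzz, cross_gram=G_old)
            new_src = [
                inv.center_sources[i] for i in range(n_before, inv.n_centers)
            ]
            if new_src:
                KiX = np.vstack([KiX, Pzz[np.asarray(new_src, dtype=int), :]])
            KiZ = (
                np.vstack([G_old, Pzz[np.asarray(new_src, dtype=int), :]])
                if new_src else G_old
            )
        else:
            KiZ = G_old

        pred_x = inv.coefficients @ KiX
        pred_z = inv.coefficients @ KiZ
        eps = pred_x - pred_z                         # (M, K) filtered errors
        np.add.at(ctrl._coef_arr, (slice(None), match_idx), eta_ctrl * eps)
        mean_abs.append(float(np.mean(np.abs(eps))))
        inv_sizes.append(inv.n_centers)

    trace = ControlTrace(np.asarray(mean_abs), np.asarray(inv_sizes, dtype=int))
    return seq, trace, z_rec
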