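"""Seeded generative model of stimulus -> multiscale neural response.

The synthetic plant stands in for a stimulated thalamocortical circuit: a
stimulus (tactile touch pulses, or multichannel current microstimulation)
drives stimulus-locked multiunit spiking and local field potentials.  The two
modalities are complementary by construction:

* spikes are an inhomogeneous Poisson process whose intensity carries sharp,
  short-latency onset bumps (precise event timing) plus a weaker sustained
  component, but single 9 ms windows are sparse;
* LFPs are the stimulus drive convolved with per-channel damped sinusoids
  plus Gaussian noise - a smooth, high-SNR envelope readout that is blind to
  sub-5 ms timing.

All randomness flows from one seed through named independent substreams
(stimulus / spikes / noise), so each component is reproducible on its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .control import StimulationSequence
from .decoding import DecodingDataset, Recording, slide_windows

__all__ = [
    "SyntheticPlantConfig",
    "TouchStimulus",
    "default_gain_matrix",
    "generate_touch_stimulus",
    "generate_random_microstim",
    "simulate_plant",
    "make_decoding_dataset",
    "relabel_touch_sites",
    "slice_recording",
]

_FS = 1000.0  # internal simulation rate, Hz


def default_gain_matrix(n_units: int, n_stim_channels: int, scale: float) -> np.ndarray:
    """Smooth overlapping receptive fields: each stimulation channel drives a
    Gaussian neighborhood of units, peak gain ``scale`` (spikes/s per uA)."""
    u = np.arange(n_units)[:, None]
    centers = np.linspace(0, n_units - 1, n_stim_channels)[None, :]
    return scale * np.exp(-((u - centers) / 1.5) ** 2)


@dataclass(frozen=True)
class SyntheticPlantConfig:
    """Generative parameters of the synthetic neural plant.

    Rates are in spikes/s, times in ms, amplitudes in uA, LFPs in arbitrary
    field-potential units.
    """

    n_units: int = 10
    n_lfp_channels: int = 4
    n_stim_channels: int = 8
    baseline_rate: float = 5.0            # spontaneous rate per unit
    gain_scale: float = 12.0              # peak evoked rate per uA at bump peak
    gain: np.ndarray | None = None        # (units, stim channels); default built
    spike_latency_ms: float = 3.0
    spike_latency_jitter_ms: float = 1.0
    spike_response_width_ms: float = 8.0  # onset-bump width
    sustained_fraction: float = 1.5       # touch: sustained-rate scale vs onset peak
    lfp_amplitude: float = 1.0            # impulse response peak per uA
    lfp_frequency_hz: tuple[float, ...] = (18.0, 24.0, 30.0, 36.0)
    lfp_decay_ms: float = 25.0
    lfp_noise_sd: float = 8.0
    lfp_touch_density: float = 0.1        # per-ms drive weight of touch envelopes
    touch_drive_ua: float = 20.0          # uA-equivalent of a unit-amplitude touch
    saturating: bool = False              # optional tanh saturation of intensity
    seed: int = 0

    def gain_matrix(self) -> np.ndarray:
        if self.gain is not None:
            g = np.asarray(self.gain, dtype=float)
            if g.shape != (self.n_units, self.n_stim_channels):
                raise ValueError("gain matrix has wrong shape")
            if np.any(g < 0):
                raise ValueError("gains must be non-negative")
            return g
        return default_gain_matrix(self.n_units, self.n_stim_channels, self.gain_scale)

    def lfp_weights(self) -> np.ndarray:
        """(lfp channels, stim channels) spatial weights: each LFP channel
        pools the units recorded near it, so it inherits their tuning."""
        g = self.gain_matrix()
        groups = np.array_split(np.arange(self.n_units), self.n_lfp_channels)
        all_units = np.arange(self.n_units)
        w = np.stack(
            [g[idx if idx.size else all_units].mean(axis=0) for idx in groups]
        )
        return self.lfp_amplitude * w / w.max()

    def site_channel(self, site: int, n_sites: int) -> int:
        """Receptive-field mapping from a touch site to the stimulation
        channel whose drive best mimics it."""
        return int((site + 0.5) * self.n_stim_channels / n_sites)


@dataclass(eq=False)
class TouchStimulus:
    """Touch-like stimulus: smooth force pulses at labelled skin sites."""

    trace: np.ndarray           # (samples, n_sites) envelope at 1 kHz
    onsets_ms: np.ndarray
    sites: np.ndarray
    amplitudes: np.ndarray      # unit-scale force amplitudes
    width_ms: float
    duration_s: float

    @property
    def n_sites(self) -> int:
        return self.trace.shape[1]

    @property
    def n_touches(self) -> int:
        return int(self.onsets_ms.size)


def generate_touch_stimulus(
    duration_s: float,
    touch_rate: float = 0.5,
    touch_width_ms: float = 100.0,
    n_sites: int = 1,
    seed: int = 0,
    amplitude_jitter: float = 0.3,
) -> TouchStimulus:
    """Non-overlapping smooth touch pulses at Poisson-thinned times.

    Pulse onsets are a homogeneous Poisson process at ``touch_rate``; draws
    that would overlap a previous pulse are thinned.  Each pulse is a raised
    cosine of the stated width, gets a uniformly random site label and an
    amplitude jittered around 1.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    if touch_rate < 0:
        raise ValueError("touch_rate must be non-negative")
    if touch_rate > 0 and touch_width_ms >= 1000.0 / touch_rate:
        raise ValueError("touch width must be below the mean inter-touch interval")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(0,)))
    n_samp = int(round(duration_s * _FS))
    trace = np.zeros((n_samp, n_sites))
    if touch_rate == 0:
        return TouchStimulus(trace, np.empty(0), np.empty(0, int), np.empty(0),
                             touch_width_ms, duration_s)

    onsets, t = [], 0.0
    while True:
        t += rng.exponential(1000.0 / touch_rate)
        if t + touch_width_ms > duration_s * 1000.0:
            break
        if not onsets or t - onsets[-1] >= touch_width_ms:
            onsets.append(t)
    onsets = np.asarray(onsets)
    sites = rng.integers(0, n_sites, size=onsets.size)
    amps = 1.0 + amplitude_jitter * (2.0 * rng.random(onsets.size) - 1.0)

    t_grid = (np.arange(n_samp) + 1) / _FS * 1000.0  # sample i at (i+1) ms
    for t0, s, a in zip(onsets, sites, amps):
        u = (t_grid - t0) / touch_width_ms
        m = (u >= 0) & (u <= 1)
        trace[m, s] += a * 0.5 * (1.0 - np.cos(2.0 * np.pi * u[m]))
    return TouchStimulus(trace, onsets, sites, amps, touch_width_ms, duration_s)


def generate_random_microstim(
    duration_s: float,
    seed: int = 0,
    mean_isi_ms: float = 100.0,
    n_channels: int = 8,
    amplitudes_ua: Sequence[float] = (10.0, 20.0, 30.0),
) -> StimulationSequence:
    """Randomly patterned microstimulation: exponentially distributed
    inter-stimulus intervals, each pulse on a uniformly random channel at a
    uniformly random amplitude level."""
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(1,)))
    times, t = [], 0.0
    while True:
        t += rng.exponential(mean_isi_ms)
        if t > duration_s * 1000.0:
            break
        times.append(t)
    times = np.asarray(times)
    chans = rng.integers(0, n_channels, size=times.size)
    amps = rng.choice(np.asarray(amplitudes_ua, dtype=float), size=times.size)
    return StimulationSequence(times, chans, amps, n_channels, duration_s)


def _damped_sinusoid(freq_hz: float, decay_ms: float) -> np.ndarray:
    """Unit-peak damped sine on a 1 ms grid, truncated at 5 decay constants."""
    t = np.arange(0.0, 5.0 * decay_ms)
    h = np.exp(-t / decay_ms) * np.sin(2.0 * np.pi * freq_hz * t / 1000.0)
    peak = np.max(np.abs(h))
    return h / peak if peak > 0 else h


def simulate_plant(
    stim: StimulationSequence | TouchStimulus,
    cfg: SyntheticPlantConfig = SyntheticPlantConfig(),
    seed: int | None = None,
) -> Recording:
    """Simulate the multiscale neural response to a stimulus.

    Unit ``n`` fires as an inhomogeneous Poisson process with intensity

        lam_n(t) = baseline + sum_events gain[n, ch] * amp * bump(t - t_e - latency)

    (plus, for touches, a weaker sustained term following the envelope),
    sampled exactly by Lewis-Shedler thinning against the peak of the
    piecewise-linear intensity.  LFP channel ``c`` is the per-channel drive
    convolved with a damped sinusoid plus white Gaussian noise.  The output
    is bit-reproducible given ``(stim, cfg, seed)``.
    """
    seed = cfg.seed if seed is None else seed
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(2,))
    rng_spikes, rng_noise = [np.random.default_rng(s) for s in ss.spawn(2)]

    duration_s = stim.duration_s
    n_samp = int(round(duration_s * _FS))
    t_grid = (np.arange(n_samp) + 1.0)  # ms, sample i at (i+1) ms
    gain = cfg.gain_matrix()
    W = cfg.lfp_weights()
    is_touch = isinstance(stim, TouchStimulus)

    # --- event list driving the onset bumps -----------------------------
    if is_touch:
        ev_t = stim.onsets_ms
        ev_ch = np.array([cfg.site_channel(int(s), stim.n_sites) for s in stim.sites],
                         dtype=int)
        ev_amp = stim.amplitudes * cfg.touch_drive_ua
    else:
        ev_t, ev_ch, ev_amp = stim.times_ms, stim.channels, stim.amplitudes_ua

    # --- stimulus drive per stimulation channel (for the LFP) -----------
    drive = np.zeros((cfg.n_stim_channels, n_samp))
    if is_touch:
        for s in range(stim.n_sites):
            ch = cfg.site_channel(s, stim.n_sites)
            drive[ch] += (
                stim.trace[:, s] * cfg.touch_drive_ua * cfg.lfp_touch_density
            )
    elif ev_t.size:
        idx = np.clip(np.round(ev_t).astype(int) - 1, 0, n_samp - 1)
        np.add.at(drive, (ev_ch, idx), ev_amp)

    # --- LFP -------------------------------------------------------------
    lfp = np.zeros((n_samp, cfg.n_lfp_channels))
    for c in range(cfg.n_lfp_channels):
        h = _damped_sinusoid(
            cfg.lfp_frequency_hz[c % len(cfg.lfp_frequency_hz)], cfg.lfp_decay_ms
        )
        resp = np.zeros(n_samp)
        for j in range(cfg.n_stim_channels):
            if W[c, j] != 0 and np.any(drive[j]):
                resp += W[c, j] * np.convolve(drive[j], h)[:n_samp]
        lfp[:, c] = resp
    if cfg.lfp_noise_sd > 0:
        lfp += rng_noise.normal(0.0, cfg.lfp_noise_sd, size=lfp.shape)

    # --- spiking intensities on the grid ---------------------------------
    w = cfg.spike_response_width_ms
    jitter = (
        rng_spikes.normal(0.0, cfg.spike_latency_jitter_ms,
                          size=(cfg.n_units, ev_t.size))
        if ev_t.size else np.zeros((cfg.n_units, 0))
    )
    lam = np.full((cfg.n_units, n_samp), cfg.baseline_rate)
    for e in range(ev_t.size):
        for n in range(cfg.n_units):
            g = gain[n, ev_ch[e]]
            if g == 0.0:
                continue
            t0 = ev_t[e] + cfg.spike_latency_ms + jitter[n, e]
            u = (t_grid - t0) / w
            m = (u >= 0) & (u <= 1)
            lam[n, m] += g * ev_amp[e] * 0.5 * (1.0 - np.cos(2.0 * np.pi * u[m]))
    if is_touch and cfg.sustained_fraction > 0:
        # sustained drive follows the envelope at the same conduction latency
        # as the onset bumps (plus half the bump width, their group delay)
        shift = int(round(cfg.spike_latency_ms + 0.5 * w))
        for s in range(stim.n_sites):
            ch = cfg.site_channel(s, stim.n_sites)
            env = stim.trace[:, s] * cfg.touch_drive_ua * cfg.sustained_fraction
            env = np.concatenate([np.zeros(shift), env[: n_samp - shift]])
            lam += gain[:, ch : ch + 1] * env[None, :]
    if cfg.saturating:
        cap = 4.0 * cfg.gain_scale * 30.0  # soft ceiling on evoked rate
        lam = cap * np.tanh(lam / cap)

    # --- thinning against the gridded (piecewise-linear) intensity -------
    rows = []
    for n in range(cfg.n_units):
        lam_n = lam[n]
        lam_max = float(lam_n.max())
        if lam_max <= 0:
            continue
        n_cand = rng_spikes.poisson(lam_max * duration_s)
        cand = np.sort(rng_spikes.random(n_cand) * duration_s * 1000.0)
        lam_at = np.interp(cand, t_grid, lam_n)
        keep = rng_spikes.random(n_cand) < lam_at / lam_max
        for t in cand[keep]:
            rows.append((n, t / 1000.0))
    spikes = pd.DataFrame(rows, columns=["unit", "time_s"]).astype(
        {"unit": int, "time_s": float}
    )

    # --- stimulus trace stored with the recording ------------------------
    if is_touch:
        stimulus, stim_fs = stim.trace, _FS
        meta = {
            "kind": "touch",
            "touch_onsets_ms": stim.onsets_ms.tolist(),
            "touch_sites": stim.sites.tolist(),
        }
    else:
        stim_fs = 200.0  # 5 ms stimulus discretization
        stimulus = stim.dense(5.0, start_ms=0.0).T[1:, :]
        meta = {"kind": "microstim"}

    return Recording(
        spikes=spikes, n_units=cfg.n_units, lfp=lfp, lfp_fs=_FS,
        stimulus=stimulus, stim_fs=stim_fs, duration_s=duration_s, meta=meta,
    )


def slice_recording(rec: Recording, t0_s: float, t1_s: float) -> Recording:
    """Extract ``[t0, t1)`` as a standalone recording with shifted times."""
    if not (0 <= t0_s < t1_s <= rec.duration_s + 1e-9):
        raise ValueError("invalid slice bounds")
    m = (rec.spikes["time_s"] >= t0_s) & (rec.spikes["time_s"] < t1_s)
    spikes = rec.spikes.loc[m].copy()
    spikes["time_s"] = spikes["time_s"] - t0_s
    i0, i1 = int(round(t0_s * rec.lfp_fs)), int(round(t1_s * rec.lfp_fs))
    j0, j1 = int(round(t0_s * rec.stim_fs)), int(round(t1_s * rec.stim_fs))
    return Recording(
        spikes=spikes.reset_index(drop=True), n_units=rec.n_units,
        lfp=rec.lfp[i0:i1], lfp_fs=rec.lfp_fs,
        stimulus=rec.stimulus[j0:j1], stim_fs=rec.stim_fs,
        duration_s=t1_s - t0_s, meta=dict(rec.meta),
    )


def make_decoding_dataset(
    kind: Literal["touch", "microstim"],
    cfg: SyntheticPlantConfig = SyntheticPlantConfig(),
    durations: tuple[float, float] = (8.0, 4.0),
    seed: int = 0,
    T_s: float = 9.0,
    T_x: float = 20.0,
    step: float = 5.0,
    n_sites: int = 1,
) -> tuple[DecodingDataset, DecodingDataset]:
    """Simulate one recording and split it into disjoint train/test windows.

    Touch datasets decode the concurrent stimulus envelope; microstimulation
    datasets decode the 8-channel sparse amplitude series, lagged by
    ``max(T_s, T_x)`` so each window contains the response the stimulus it
    reconstructs evoked.
    """
    train_s, test_s = durations
    if train_s <= 0 or test_s <= 0:
        raise ValueError("durations must be positive")
    total = train_s + test_s
    if kind == "touch":
        stim = generate_touch_stimulus(total, n_sites=n_sites, seed=seed)
        lag = 0.0
    elif kind == "microstim":
        stim = generate_random_microstim(total, seed=seed,
                                         n_channels=cfg.n_stim_channels)
        lag = max(T_s, T_x)
    else:
        raise ValueError("kind must be 'touch' or 'microstim'")
    rec = simulate_plant(stim, cfg, seed=seed)
    rec_train = slice_recording(rec, 0.0, train_s)
    rec_test = slice_recording(rec, train_s, total)
    ds_train = slide_windows(rec_train, T_s=T_s, T_x=T_x, step=step, target_lag_ms=lag)
    ds_test = slide_windows(rec_test, T_s=T_s, T_x=T_x, step=step, target_lag_ms=lag)
    return ds_train, ds_test


def relabel_touch_sites(
    stim: TouchStimulus, site: int, n_sites: int
) -> TouchStimulus:
    """Assign every touch in a stimulus to one site (same onsets and
    amplitudes).  Useful for building matched stimulus classes that differ
    only in the skin site they excite."""
    if not 0 <= site < n_sites:
        raise ValueError("site out of range")
    n_samp = stim.trace.shape[0]
    trace = np.zeros((n_samp, n_sites))
    trace[:, site] = stim.trace.sum(axis=1)
    return TouchStimulus(
        trace, stim.onsets_ms, np.full(stim.onsets_ms.size, site, dtype=int),
        stim.amplitudes, stim.width_ms, stim.duration_s,
    )
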