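"""On-disk formats.

Times in files are seconds, written with 9 decimal places; all internal
computation is in milliseconds.  A recording directory contains::

    spikes.csv     unit,time_s
    lfp.csv        one column per channel (header = channel names)
    stimulus.csv   time_s plus one column per stimulus channel
    meta.json      {"lfp_fs_hz": ..., "stim_fs_hz": ..., "duration_s": ...,
                    "n_units": ...}

CSV files are comma-separated with a mandatory header row, UTF-8 and '.'
decimal separator.  Malformed rows are rejected with their 1-based line
number.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .control import StimulationSequence
from .decoding import DecodingDataset, Recording
from .errors import RecordingFormatError
from .kernels import CompositeKernelSpec
from .qklms import QKLMSModel
from .samples import (
    LFPWindow,
    MultichannelLFPWindow,
    MultiscaleSample,
    MultiunitSpikeWindow,
    SpikeWindow,
)

__all__ = [
    "write_recording",
    "read_recording",
    "write_stimulation",
    "read_stimulation",
    "save_model",
    "load_model",
    "write_gram",
    "dataset_to_hdf5",
    "dataset_from_hdf5",
]

_TIME_FMT = "%.9f"


def write_recording(rec: Recording, directory: str | Path) -> None:
    """Write a recording as spikes.csv / lfp.csv / stimulus.csv / meta.json."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    rec.spikes.to_csv(d / "spikes.csv", index=False,
                      float_format=_TIME_FMT, columns=["unit", "time_s"])
    lfp_cols = [f"lfp{c}" for c in range(rec.lfp.shape[1])]
    pd.DataFrame(rec.lfp, columns=lfp_cols).to_csv(
        d / "lfp.csv", index=False, float_format="%.12g"
    )
    t = (np.arange(rec.stimulus.shape[0]) + 1) / rec.stim_fs
    stim = pd.DataFrame(
        {"time_s": t, **{f"stim{c}": rec.stimulus[:, c]
                         for c in range(rec.stimulus.shape[1])}}
    )
    stim.to_csv(d / "stimulus.csv", index=False, float_format=_TIME_FMT)
    meta = {
        "lfp_fs_hz": rec.lfp_fs,
        "stim_fs_hz": rec.stim_fs,
        "duration_s": rec.duration_s,
        "n_units": rec.n_units,
    }
    (d / "meta.json").write_text(json.dumps(meta, indent=2))


def _read_csv(path: Path) -> pd.DataFrame:
    try:
        return pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise RecordingFormatError(f"{path.name}: {exc}") from exc


def read_recording(directory: str | Path) -> Recording:
    """Read a recording directory, validating shapes and times."""
    d = Path(directory)
    for name in ("spikes.csv", "lfp.csv", "stimulus.csv", "meta.json"):
        if not (d / name).exists():
            raise RecordingFormatError(f"missing file: {name}")
    meta = json.loads((d / "meta.json").read_text())

    spikes = _read_csv(d / "spikes.csv")
    if list(spikes.columns) != ["unit", "time_s"]:
        raise RecordingFormatError("spikes.csv: header must be 'unit,time_s'")
    bad = np.nonzero(spikes["time_s"].to_numpy() < 0)[0]
    if bad.size:
        raise RecordingFormatError(
            f"spikes.csv line {bad[0] + 2}: negative spike time"
        )

    lfp_df = _read_csv(d / "lfp.csv")
    if lfp_df.isna().any().any():
        line = int(np.nonzero(lfp_df.isna().any(axis=1).to_numpy())[0][0]) + 2
        raise RecordingFormatError(f"lfp.csv line {line}: ragged or missing value")
    stim_df = _read_csv(d / "stimulus.csv")
    if "time_s" not in stim_df.columns:
        raise RecordingFormatError("stimulus.csv: missing time_s column")
    tcol = stim_df["time_s"].to_numpy()
    dt = np.diff(tcol)
    if np.any(dt <= 0):
        line = int(np.nonzero(dt <= 0)[0][0]) + 3
        raise RecordingFormatError(
            f"stimulus.csv line {line}: non-monotone time base"
        )
    return Recording(
        spikes=spikes.astype({"unit": int, "time_s": float}),
        n_units=int(meta["n_units"]),
        lfp=lfp_df.to_numpy(dtype=float),
        lfp_fs=float(meta["lfp_fs_hz"]),
        stimulus=stim_df.drop(columns="time_s").to_numpy(dtype=float),
        stim_fs=float(meta["stim_fs_hz"]),
        duration_s=float(meta["duration_s"]),
    )


# ---------------------------------------------------------------------------
# stimulation sequences
# ---------------------------------------------------------------------------

def write_stimulation(seq: StimulationSequence, path: str | Path) -> None:
    """CSV export (time_s, channel, amplitude_uA), sorted by time."""
    df = pd.DataFrame(
        {
            "time_s": seq.times_ms / 1000.0,
            "channel": seq.channels,
            "amplitude_uA": seq.amplitudes_ua,
        }
    ).sort_values("time_s", kind="stable")
    df.to_csv(path, index=False, float_format=_TIME_FMT)


def read_stimulation(
    path: str | Path, n_channels: int, duration_s: float
) -> StimulationSequence:
    """Load and validate a stimulation CSV; violations name line numbers."""
    path = Path(path)
    df = _read_csv(path)
    expected = ["time_s", "channel", "amplitude_uA"]
    if list(df.columns) != expected:
        raise RecordingFormatError(f"{path.name}: header must be {','.join(expected)}")
    t = df["time_s"].to_numpy(dtype=float)
    for i, v in enumerate(t):
        if v < 0 or v > duration_s:
            raise RecordingFormatError(
                f"{path.name} line {i + 2}: time {v} outside [0, {duration_s}]"
            )
    ch = df["channel"].to_numpy(dtype=int)
    for i, v in enumerate(ch):
        if v < 0 or v >= n_channels:
            raise RecordingFormatError(
                f"{path.name} line {i + 2}: channel {v} out of range"
            )
    return StimulationSequence(
        t * 1000.0, ch, df["amplitude_uA"].to_numpy(dtype=float),
        n_channels, duration_s,
    )


# ---------------------------------------------------------------------------
# models, Gram matrices, datasets (HDF5)
# ---------------------------------------------------------------------------

def _write_samples(g: h5py.Group, samples: list[MultiscaleSample]) -> None:
    s0 = samples[0]
    n_units, n_ch = s0.spikes.n_units, s0.lfp.n_channels
    g.attrs["T_s"] = s0.spikes.window_length
    g.attrs["lfp_sample_period"] = s0.lfp.channels[0].sample_period
    times = [
        s.spikes.units[u].times for s in samples for u in range(n_units)
    ]
    g.create_dataset("spike_times", data=np.concatenate(times) if times else [])
    g.create_dataset(
        "spike_offsets",
        data=np.cumsum([0] + [t.size for t in times]).astype(np.int64),
    )
    g.attrs["n_units"] = n_units
    g.create_dataset(
        "lfp", data=np.stack([s.lfp.as_matrix() for s in samples])
    )  # (K, C, L)


def _read_samples(g: h5py.Group) -> list[MultiscaleSample]:
    T_s = float(g.attrs["T_s"])
    tau = float(g.attrs["lfp_sample_period"])
    n_units = int(g.attrs["n_units"])
    flat = g["spike_times"][...]
    offs = g["spike_offsets"][...]
    lfp = g["lfp"][...]
    K = lfp.shape[0]
    samples = []
    for i in range(K):
        units = tuple(
            SpikeWindow(flat[offs[i * n_units + u]:offs[i * n_units + u + 1]], T_s)
            for u in range(n_units)
        )
        chans = tuple(LFPWindow(lfp[i, c], tau) for c in range(lfp.shape[1]))
        samples.append(
            MultiscaleSample(MultiunitSpikeWindow(units), MultichannelLFPWindow(chans))
        )
    return samples


def save_model(model: QKLMSModel, path: str | Path) -> None:
    """Persist a Q-KLMS model (dictionary, coefficients, hyperparameters)."""
    with h5py.File(path, "w") as f:
        f.attrs["learning_rate"] = model.learning_rate
        f.attrs["quantization_size"] = model.quantization_size
        f.attrs["kernel_spec"] = model.kernel_spec.to_json()
        f.attrs["n_outputs"] = model.n_outputs
        f.create_dataset("coefficients", data=model.coefficients)
        f.create_dataset("self_similarities", data=model.self_similarities)
        if model.centers:
            _write_samples(f.create_group("centers"), model.centers)


def load_model(path: str | Path) -> QKLMSModel:
    with h5py.File(path, "r") as f:
        model = QKLMSModel(
            CompositeKernelSpec.from_json(f.attrs["kernel_spec"]),
            n_outputs=int(f.attrs["n_outputs"]),
            learning_rate=float(f.attrs["learning_rate"]),
            quantization_size=float(f.attrs["quantization_size"]),
        )
        coef = f["coefficients"][...]
        sims = f["self_similarities"][...]
        centers = _read_samples(f["centers"]) if "centers" in f else []
    for u, col, s in zip(centers, coef.T, sims):
        model._append_center(u, col, float(s))
    return model


def write_gram(
    gram: np.ndarray, spec: CompositeKernelSpec, path: str | Path
) -> None:
    """Write a Gram matrix to HDF5 (dataset 'gram', spec in attrs) or CSV,
    chosen by file extension."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            d = f.create_dataset("gram", data=gram)
            d.attrs["kernel_spec"] = spec.to_json()
    elif path.suffix == ".csv":
        np.savetxt(path, gram, delimiter=",")
    else:
        raise ValueError("gram path must end in .h5, .hdf5 or .csv")


def dataset_to_hdf5(ds: DecodingDataset, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["T_s"] = ds.T_s
        f.attrs["T_x"] = ds.T_x
        f.attrs["step"] = ds.step
        f.attrs["alignment"] = ds.alignment
        f.create_dataset("targets", data=ds.targets)
        f.create_dataset("times_ms", data=ds.times_ms)
        _write_samples(f.create_group("samples"), ds.samples)


def dataset_from_hdf5(path: str | Path) -> DecodingDataset:
    with h5py.File(path, "r") as f:
        return DecodingDataset(
            samples=_read_samples(f["samples"]),
            targets=f["targets"][...],
            times_ms=f["times_ms"][...],
            step=float(f.attrs["step"]),
            T_s=float(f.attrs["T_s"]),
            T_x=float(f.attrs["T_x"]),
            alignment=str(f.attrs["alignment"]),
        )
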