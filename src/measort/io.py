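"""Reading and writing recordings, traces and results.

Recordings travel as HDF5 containers (``/signal`` float32 µV,
``/sampling_rate``, optional ``/ground_truth/spike_times`` and
``/ground_truth/labels``) or as delimited text with a mandatory
sampling-rate header line.  Calcium traces are two-column CSV
(frame_time_s, intensity).  Detection and sorting outputs go to HDF5
(waveforms, features, events, labels, soft assignments, centroids).
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .simulate import CalciumTrace, GroundTruth, RawRecording

__all__ = [
    "FormatError",
    "write_recording",
    "read_recording",
    "write_recording_text",
    "write_calcium_trace",
    "read_calcium_trace",
    "read_multi_roi_csv",
    "write_detection",
    "write_sort_result",
    "save_model",
    "load_model",
]

_TEXT_HEADER = "# sampling_rate_hz:"


class FormatError(ValueError):
    """A file is missing a required field or holds invalid values."""


def write_recording(path, rec: RawRecording, truth: GroundTruth | None = None) -> None:
    """Write a recording (and optional ground truth) to an HDF5 container."""
    with h5py.File(path, "w") as f:
        f.create_dataset("signal", data=np.asarray(rec.samples, dtype=np.float32))
        f.create_dataset("sampling_rate", data=float(rec.sampling_rate))
        f.attrs["channel_id"] = rec.channel_id
        if truth is not None:
            g = f.create_group("ground_truth")
            g.create_dataset("spike_times", data=truth.spike_times)
            g.create_dataset("labels", data=truth.neuron_labels)
            g.attrs["n_neurons"] = truth.n_neurons


def write_recording_text(path, rec: RawRecording) -> None:
    """Write a recording as delimited text with a sampling-rate header."""
    with open(path, "w") as f:
        f.write(f"{_TEXT_HEADER} {rec.sampling_rate}\n")
        f.write("voltage_uV\n")
        np.savetxt(f, np.asarray(rec.samples), fmt="%.6f")


def read_recording(path, fmt: str | None = None) -> tuple[RawRecording, GroundTruth | None]:
    """Load a recording from HDF5 or headered text.

    The sampling rate is mandatory (HDF5 dataset or text header line);
    a missing rate raises :class:`FormatError` naming the field, and any
    NaN samples are rejected with their count.
    """
    path = Path(path)
    if fmt is None:
        fmt = "hdf5" if path.suffix.lower() in {".h5", ".hdf5"} else "text"
    if fmt == "hdf5":
        with h5py.File(path, "r") as f:
            if "sampling_rate" not in f:
                raise FormatError(f"{path}: missing required field 'sampling_rate'")
            samples = np.asarray(f["signal"], dtype=float)
            fs = float(f["sampling_rate"][()])
            channel = str(f.attrs.get("channel_id", "ch0"))
            truth = None
            if "ground_truth" in f:
                g = f["ground_truth"]
                truth = GroundTruth(
                    spike_times=np.asarray(g["spike_times"], dtype=np.int64),
                    neuron_labels=np.asarray(g["labels"], dtype=np.int64),
                    n_neurons=int(g.attrs["n_neurons"]),
                )
    elif fmt == "text":
        with open(path) as f:
            first = f.readline()
            if not first.startswith(_TEXT_HEADER):
                raise FormatError(
                    f"{path}: missing required header '{_TEXT_HEADER} <Hz>' "
                    "(field: sampling_rate_hz)"
                )
            fs = float(first[len(_TEXT_HEADER):])
            f.readline()  # column header
            samples = np.loadtxt(f)
        channel, truth = "ch0", None
    else:
        raise ValueError(f"unknown format {fmt!r}")
    n_nan = int(np.isnan(samples).sum())
    if n_nan:
        raise FormatError(f"{path}: {n_nan} NaN samples rejected")
    return RawRecording(samples=samples, sampling_rate=fs, channel_id=channel), truth


def write_calcium_trace(path, trace: CalciumTrace) -> None:
    pd.DataFrame(
        {"frame_time_s": trace.times, "intensity": trace.intensities}
    ).to_csv(path, index=False)


def read_calcium_trace(path, roi_id: str = "roi0") -> CalciumTrace:
    df = pd.read_csv(path)
    if "intensity" not in df or "frame_time_s" not in df:
        raise FormatError(f"{path}: need columns frame_time_s, intensity")
    t = df["frame_time_s"].to_numpy(dtype=float)
    if len(t) < 2:
        raise FormatError(f"{path}: need at least two frames")
    return CalciumTrace(
        intensities=df["intensity"].to_numpy(dtype=float),
        frame_interval=float(np.median(np.diff(t))),
        roi_id=roi_id,
    )


def read_multi_roi_csv(path) -> list[CalciumTrace]:
    """Load a wide CSV (frame_time_s plus one intensity column per ROI)."""
    df = pd.read_csv(path)
    if "frame_time_s" not in df:
        raise FormatError(f"{path}: need a frame_time_s column")
    t = df["frame_time_s"].to_numpy(dtype=float)
    if len(t) < 2:
        raise FormatError(f"{path}: need at least two frames")
    dt = float(np.median(np.diff(t)))
    return [
        CalciumTrace(df[col].to_numpy(dtype=float), dt, roi_id=str(col))
        for col in df.columns
        if col != "frame_time_s"
    ]


def write_detection(path, waveforms, features: np.ndarray, events) -> None:
    """Persist extracted waveforms, gradient features and event indices."""
    with h5py.File(path, "w") as f:
        if len(waveforms):
            f.create_dataset(
                "waveforms", data=np.vstack([w.samples for w in waveforms])
            )
        f.create_dataset("features", data=features)
        g = f.create_group("events")
        g.create_dataset(
            "threshold_index", data=np.asarray([e.threshold_index for e in events])
        )
        g.create_dataset(
            "trough_index", data=np.asarray([e.trough_index for e in events])
        )


def read_features(path) -> np.ndarray:
    with h5py.File(path, "r") as f:
        return np.asarray(f["features"], dtype=float)


def write_sort_result(path, result) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("labels", data=result.labels)
        f.create_dataset("soft_assignments", data=result.soft_assignments)
        f.create_dataset("centroids", data=result.model.centroids)


def save_model(path, model) -> None:
    """Serialize a :class:`~measort.sort.ClusterModel` to a portable npz file."""
    arrays = {
        "centroids": model.centroids,
        "K": np.asarray(model.K),
        "feature_mean": model.feature_mean,
        "feature_scale": model.feature_scale,
    }
    if model.autoencoder is not None:
        arrays["sizes"] = np.asarray(model.autoencoder.sizes)
        for name, net in (("enc", model.autoencoder.encoder),
                          ("dec", model.autoencoder.decoder)):
            for i, layer in enumerate(net.layers):
                arrays[f"{name}{i}_W"] = layer.W
                arrays[f"{name}{i}_b"] = layer.b
    np.savez(path, **arrays)


def load_model(path):
    """Restore a ClusterModel written by :func:`save_model`."""
    from ._nn import Autoencoder
    from .sort import ClusterModel

    with np.load(path) as data:
        ae = None
        if "sizes" in data:
            sizes = [int(s) for s in data["sizes"]]
            ae = Autoencoder(sizes, np.random.default_rng(0))
            for name, net in (("enc", ae.encoder), ("dec", ae.decoder)):
                for i, layer in enumerate(net.layers):
                    layer.W = data[f"{name}{i}_W"]
                    layer.b = data[f"{name}{i}_b"]
        return ClusterModel(
            autoencoder=ae,
            centroids=data["centroids"],
            K=int(data["K"]),
            feature_mean=data["feature_mean"],
            feature_scale=data["feature_scale"],
        )
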