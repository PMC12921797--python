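"""Readers and writers for continuous EEG, epochs, and result tables.

Continuous data come either from EDF files (via MNE's built-in reader)
or from plain delimited text matrices — channels × samples with a header
row of channel labels.  Epoch sets are written as one delimited matrix
per trial plus an index TSV; connectivity matrices as square delimited
text with a channel-label header.  All outputs are plain text.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import ConnectivityMatrix
from .preprocess import EpochSet

__all__ = [
    "read_edf", "read_delimited_matrix", "write_delimited_matrix",
    "write_epochs", "read_epochs", "write_connectivity_matrix",
    "read_connectivity_matrix", "write_tsv", "write_json",
]


def read_edf(path) -> tuple[np.ndarray, float, tuple[str, ...]]:
    """Read a continuous EDF recording.

    Returns ``(data_uv, fs, channel_labels)`` with data channels × samples
    in microvolts.
    """
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # MNE loads volts
    return data, float(raw.info["sfreq"]), tuple(raw.ch_names)


def read_delimited_matrix(path, sep: str = "\t"
                          ) -> tuple[np.ndarray, tuple[str, ...]]:
    """Read a channels × samples text matrix with a channel-label header.

    Rows are channels; the first column of the header row is each
    channel's label.
    """
    df = pd.read_csv(path, sep=sep, index_col=0)
    return df.to_numpy(dtype=float), tuple(str(c) for c in df.index)


def write_delimited_matrix(path, data: np.ndarray, channels,
                           sep: str = "\t") -> None:
    data = np.atleast_2d(data)
    df = pd.DataFrame(data, index=list(channels))
    df.to_csv(path, sep=sep, float_format="%.6g")


def write_epochs(directory, epochs: EpochSet, stem: str = "trial") -> None:
    """Write an epoch set as per-trial delimited matrices plus an index.

    Creates ``<stem><k>.tsv`` per trial and ``index.tsv`` with the
    metadata (fs, subject, group, condition, window).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for t in range(epochs.n_trials):
        fname = f"{stem}{t:04d}.tsv"
        write_delimited_matrix(directory / fname, epochs.data[t],
                               epochs.channels or
                               range(epochs.n_channels))
        rows.append({"trial": t, "file": fname, "fs": epochs.fs,
                     "subject": epochs.subject, "group": epochs.group,
                     "condition": epochs.condition,
                     "window_ms": epochs.window_ms})
    pd.DataFrame(rows).to_csv(directory / "index.tsv", sep="\t", index=False)


def read_epochs(directory) -> EpochSet:
    """Read an epoch set previously written by :func:`write_epochs`."""
    directory = Path(directory)
    index = pd.read_csv(directory / "index.tsv", sep="\t")
    data, channels = [], None
    for fname in index["file"]:
        mat, channels = read_delimited_matrix(directory / fname)
        data.append(mat)
    first = index.iloc[0]
    return EpochSet(data=np.stack(data), fs=float(first["fs"]),
                    channels=channels,
                    subject=str(first.get("subject", "") or ""),
                    group=str(first.get("group", "") or ""),
                    condition=str(first.get("condition", "") or ""),
                    window_ms=float(first["window_ms"]))


def write_connectivity_matrix(path, mat: ConnectivityMatrix,
                              sep: str = "\t") -> None:
    labels = mat.channels or tuple(str(i) for i in range(mat.n_channels))
    df = pd.DataFrame(mat.values, index=labels, columns=labels)
    df.to_csv(path, sep=sep, float_format="%.6g")


def read_connectivity_matrix(path, sep: str = "\t") -> ConnectivityMatrix:
    df = pd.read_csv(path, sep=sep, index_col=0)
    return ConnectivityMatrix(values=df.to_numpy(dtype=float),
                              channels=tuple(str(c) for c in df.index))


def write_tsv(path, df: pd.DataFrame) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_json(path, payload) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.bool_,)):
            return bool(o)
        raise TypeError(f"not JSON serialisable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, default=default)
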