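"""Reading and writing segment sets and feature tables.

Segment sets travel as HDF5 containers (datasets ``/data`` [n x c x t] and
``/labels``, root attributes ``fs``, ``segment_duration`` and
``channel_labels``) or as EDF recordings plus a label CSV; feature tables
are plain CSV with a final ``label`` column.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .features import EEGSegmentSet, FeatureMatrix

__all__ = ["save_segments_h5", "load_segments_h5", "load_segments_edf",
           "save_features_csv", "load_features_csv"]


def save_segments_h5(path, segments: EEGSegmentSet) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=segments.data)
        f.create_dataset("labels", data=segments.labels)
        f.attrs["fs"] = segments.fs
        f.attrs["segment_duration"] = segments.segment_duration
        f.attrs["channel_labels"] = [c.encode() for c in
                                     segments.channel_labels]


def load_segments_h5(path) -> EEGSegmentSet:
    import h5py

    with h5py.File(path, "r") as f:
        labels = np.asarray(f["labels"])
        channels = [c.decode() if isinstance(c, bytes) else str(c)
                    for c in f.attrs["channel_labels"]]
        return EEGSegmentSet(
            data=np.asarray(f["data"]),
            fs=float(f.attrs["fs"]),
            channel_labels=channels,
            labels=labels,
            segment_duration=float(f.attrs["segment_duration"]),
        )


def load_segments_edf(edf_paths: list, label_csv,
                      segment_duration: float = 3.0) -> EEGSegmentSet:
    """Read EDF files (one segment each) plus a CSV of per-file labels.

    The label CSV needs columns ``file`` and ``label``.  Requires the
    optional ``mne`` dependency.
    """
    import mne  # optional dependency, imported on use

    table = pd.read_csv(label_csv)
    label_map = dict(zip(table["file"].astype(str), table["label"]))
    data, labels, channels, fs = [], [], None, None
    for path in edf_paths:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
        if channels is None:
            channels = list(raw.ch_names)
            fs = float(raw.info["sfreq"])
        n_t = int(round(fs * segment_duration))
        data.append(raw.get_data()[:, :n_t] * 1e6)  # volts -> microvolts
        import os
        labels.append(int(label_map[os.path.basename(str(path))]))
    return EEGSegmentSet(data=np.stack(data), fs=fs, channel_labels=channels,
                         labels=np.asarray(labels),
                         segment_duration=segment_duration)


def save_features_csv(path, features: FeatureMatrix) -> None:
    features.to_csv(path)


def load_features_csv(path, label_column: str = "label") -> FeatureMatrix:
    return FeatureMatrix.from_csv(path, label_column)
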