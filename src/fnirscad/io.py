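"""File I/O: SNIRF (HDF5) and a plain-text CSV dialect for recordings.

SNIRF files follow the v1.0 layout with one ``measurementList`` entry per
data column (``dataType`` 99999 with ``dataTypeLabel`` ``"dOD"`` for
processed optical density).  Columns are channel-major: channel 1 at
780 nm, channel 1 at 850 nm, channel 2 at 780 nm, ...

The CSV dialect is one row per sample with a leading ``time`` column and
then either ``<ch>_780nm, <ch>_850nm`` optical-density columns or
``<ch>_HbO, <ch>_HbR`` concentration columns (µM).  Event markers live in
a sidecar TSV with columns ``onset  duration  label``.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .preprocess import HbRecording, OpticalDensityRecording

__all__ = [
    "write_snirf",
    "read_snirf",
    "write_od_csv",
    "read_od_csv",
    "write_hb_csv",
    "read_hb_csv",
    "write_events_tsv",
    "read_events_tsv",
]


def _str(group: h5py.Group, name: str, value: str) -> None:
    group.create_dataset(name, data=np.bytes_(value))


def write_snirf(rec: OpticalDensityRecording, path: str | Path, subject_id: str = "unknown") -> None:
    """Write an optical-density recording as a SNIRF v1.0 file."""
    n_t, n_ch, _ = rec.od.shape
    with h5py.File(path, "w") as f:
        _str(f, "formatVersion", "1.0")
        nirs = f.create_group("nirs")
        meta = nirs.create_group("metaDataTags")
        _str(meta, "SubjectID", subject_id)
        _str(meta, "MeasurementDate", "unknown")
        _str(meta, "MeasurementTime", "unknown")
        _str(meta, "LengthUnit", "cm")
        _str(meta, "TimeUnit", "s")
        _str(meta, "FrequencyUnit", "Hz")
        data = nirs.create_group("data1")
        flat = rec.od.reshape(n_t, n_ch * 2)  # channel-major, wavelength fastest
        data.create_dataset("dataTimeSeries", data=flat)
        data.create_dataset("time", data=np.arange(n_t) / rec.sampling_rate)
        for col in range(n_ch * 2):
            ch, wl = divmod(col, 2)
            ml = data.create_group(f"measurementList{col + 1}")
            ml.create_dataset("sourceIndex", data=ch + 1)
            ml.create_dataset("detectorIndex", data=ch + 1)
            ml.create_dataset("wavelengthIndex", data=wl + 1)
            ml.create_dataset("dataType", data=99999)
            _str(ml, "dataTypeLabel", "dOD")
        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.asarray(rec.wavelengths))
        pos = np.zeros((n_ch, 2))
        probe.create_dataset("sourcePos2D", data=pos)
        probe.create_dataset("detectorPos2D", data=pos)
        for k, (onset, dur, label) in enumerate(rec.events):
            stim = nirs.create_group(f"stim{k + 1}")
            _str(stim, "name", label)
            stim.create_dataset("data", data=np.array([[onset, dur, 1.0]]))


def read_snirf(path: str | Path) -> OpticalDensityRecording:
    """Read a SNIRF file written by :func:`write_snirf` (or compatible)."""
    with h5py.File(path, "r") as f:
        nirs = f["nirs"]
        data = nirs["data1"]
        flat = np.asarray(data["dataTimeSeries"])
        time = np.asarray(data["time"])
        fs = float(1.0 / np.median(np.diff(time)))
        wavelengths = tuple(float(w) for w in np.asarray(nirs["probe"]["wavelengths"]))
        n_cols = flat.shape[1]
        cols = np.empty((n_cols, 2), dtype=int)  # (channel, wavelength index)
        for col in range(n_cols):
            ml = data[f"measurementList{col + 1}"]
            cols[col, 0] = int(np.asarray(ml["sourceIndex"])) - 1
            cols[col, 1] = int(np.asarray(ml["wavelengthIndex"])) - 1
        n_ch = cols[:, 0].max() + 1
        od = np.empty((flat.shape[0], n_ch, 2))
        for col in range(n_cols):
            od[:, cols[col, 0], cols[col, 1]] = flat[:, col]
        events = []
        k = 1
        while f"stim{k}" in nirs:
            stim = nirs[f"stim{k}"]
            label = bytes(np.asarray(stim["name"])).decode() if stim["name"].shape == () else "task"
            for onset, dur, _ in np.atleast_2d(np.asarray(stim["data"])):
                events.append((float(onset), float(dur), label))
            k += 1
    events.sort()
    return OpticalDensityRecording(
        od=od, sampling_rate=fs, wavelengths=wavelengths, events=tuple(events)
    )


def _time_index(n: int, fs: float) -> np.ndarray:
    return np.arange(n) / fs


def write_od_csv(rec: OpticalDensityRecording, path: str | Path) -> None:
    n_t, n_ch, _ = rec.od.shape
    cols = {"time": _time_index(n_t, rec.sampling_rate)}
    for ch in range(n_ch):
        for w, wl in enumerate(rec.wavelengths):
            cols[f"ch{ch + 1:02d}_{wl:.0f}nm"] = rec.od[:, ch, w]
    pd.DataFrame(cols).to_csv(path, index=False)


def read_od_csv(
    path: str | Path,
    events: tuple[tuple[float, float, str], ...] = (),
    wavelengths: tuple[float, float] = (780.0, 850.0),
) -> OpticalDensityRecording:
    df = pd.read_csv(path)
    fs = float(1.0 / np.median(np.diff(df["time"].to_numpy())))
    data_cols = [c for c in df.columns if c != "time"]
    n_ch = len(data_cols) // 2
    od = np.empty((len(df), n_ch, 2))
    for ch in range(n_ch):
        for w, wl in enumerate(wavelengths):
            od[:, ch, w] = df[f"ch{ch + 1:02d}_{wl:.0f}nm"].to_numpy()
    return OpticalDensityRecording(
        od=od, sampling_rate=fs, wavelengths=wavelengths, events=events
    )


def write_hb_csv(hb: HbRecording, path: str | Path) -> None:
    n_t, n_ch = hb.dhbo.shape
    cols = {"time": _time_index(n_t, hb.sampling_rate)}
    for ch in range(n_ch):
        cols[f"ch{ch + 1:02d}_HbO"] = hb.dhbo[:, ch]
        cols[f"ch{ch + 1:02d}_HbR"] = hb.dhbr[:, ch]
    pd.DataFrame(cols).to_csv(path, index=False)


def read_hb_csv(
    path: str | Path, events: tuple[tuple[float, float, str], ...] = ()
) -> HbRecording:
    df = pd.read_csv(path)
    fs = float(1.0 / np.median(np.diff(df["time"].to_numpy())))
    n_ch = (len(df.columns) - 1) // 2
    dhbo = np.column_stack([df[f"ch{c + 1:02d}_HbO"] for c in range(n_ch)])
    dhbr = np.column_stack([df[f"ch{c + 1:02d}_HbR"] for c in range(n_ch)])
    return HbRecording(dhbo=dhbo, dhbr=dhbr, sampling_rate=fs, events=events)


def write_events_tsv(
    events: tuple[tuple[float, float, str], ...], path: str | Path
) -> None:
    pd.DataFrame(events, columns=["onset", "duration", "label"]).to_csv(
        path, sep="\t", index=False
    )


def read_events_tsv(path: str | Path) -> tuple[tuple[float, float, str], ...]:
    df = pd.read_csv(path, sep="\t")
    return tuple(
        (float(r.onset), float(r.duration), str(r.label)) for r in df.itertuples()
    )


def write_json_report(report: dict, path: str | Path) -> None:
    """Deterministic JSON serialization (sorted keys, fixed separators)."""
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
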