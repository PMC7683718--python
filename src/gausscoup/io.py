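"""Readers and writers for recordings, spectra and coupling matrices.

Formats
-------
* Time series: CSV/TSV numeric matrix (channels in rows, optional header
  row of channel labels, sampling rate via argument or JSON sidecar) and
  HDF5 (dataset ``data`` + attributes ``sampling_rate`` and ``labels``).
  EDF is supported read-only through :mod:`mne` when it is installed.
* Cross-spectra / coherency: HDF5 with complex values stored as paired
  real datasets (``*_real``, ``*_imag``) and a frequency attribute.
* Coupling matrices: long-format CSV with columns
  (measure, frequency, channel_i, channel_j, value_real, value_imag).
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .coupling import CouplingMatrix
from .spectral import CoherencyMatrix, CrossSpectrum, TimeSeriesData

__all__ = [
    "read_timeseries_csv",
    "write_timeseries_csv",
    "read_timeseries_hdf5",
    "write_timeseries_hdf5",
    "read_timeseries_edf",
    "write_spectral_matrix_hdf5",
    "read_spectral_matrix_hdf5",
    "write_coupling_csv",
    "read_coupling_csv",
]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_timeseries_csv(data: TimeSeriesData, path: str | Path, sep: str = ",") -> None:
    """Channels in rows, labels as header; sampling rate in a JSON sidecar."""
    path = Path(path)
    df = pd.DataFrame(data.values, index=data.channel_labels)
    df.T.to_csv(path, sep=sep, index=False)
    _sidecar_path(path).write_text(
        json.dumps({"sampling_rate": data.sampling_rate, "labels": data.channel_labels})
    )


def read_timeseries_csv(
    path: str | Path, sampling_rate: float | None = None, sep: str | None = None
) -> TimeSeriesData:
    """Read a CSV/TSV matrix; sampling rate from argument or sidecar."""
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    labels = None
    if sampling_rate is None:
        sidecar = _sidecar_path(path)
        if not sidecar.exists():
            raise ValueError(
                f"no sampling rate given and no sidecar {sidecar.name} found"
            )
        meta = json.loads(sidecar.read_text())
        sampling_rate = float(meta["sampling_rate"])
        labels = meta.get("labels")
    df = pd.read_csv(path, sep=sep)
    return TimeSeriesData(
        values=df.to_numpy().T,
        sampling_rate=sampling_rate,
        channel_labels=labels if labels is not None else [str(c) for c in df.columns],
    )


def write_timeseries_hdf5(data: TimeSeriesData, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        dset = f.create_dataset("data", data=data.values)
        dset.attrs["sampling_rate"] = data.sampling_rate
        dset.attrs["labels"] = [str(c) for c in data.channel_labels]


def read_timeseries_hdf5(path: str | Path) -> TimeSeriesData:
    with h5py.File(path, "r") as f:
        dset = f["data"]
        return TimeSeriesData(
            values=dset[()],
            sampling_rate=float(dset.attrs["sampling_rate"]),
            channel_labels=[
                s.decode() if isinstance(s, bytes) else str(s)
                for s in dset.attrs["labels"]
            ],
        )


def read_timeseries_edf(path: str | Path) -> TimeSeriesData:
    """Read an EDF recording (optional; requires mne)."""
    try:
        import mne
    except ImportError as err:  # pragma: no cover
        raise ImportError("reading EDF requires the optional dependency mne") from err
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    return TimeSeriesData(
        values=raw.get_data(),
        sampling_rate=float(raw.info["sfreq"]),
        channel_labels=list(raw.ch_names),
    )


def write_spectral_matrix_hdf5(
    matrices: list[CrossSpectrum] | list[CoherencyMatrix], path: str | Path
) -> None:
    """Store per-frequency complex matrices as paired real datasets."""
    if not matrices:
        raise ValueError("nothing to write")
    stack = np.stack([m.matrix for m in matrices])
    freqs = np.array([m.frequency for m in matrices], dtype=float)
    with h5py.File(path, "w") as f:
        f.create_dataset("matrix_real", data=stack.real)
        f.create_dataset("matrix_imag", data=stack.imag)
        f.attrs["frequencies"] = freqs
        f.attrs["kind"] = type(matrices[0]).__name__
        f.attrs["n_segments"] = int(getattr(matrices[0], "n_segments", 0))
        if matrices[0].channel_labels is not None:
            f.attrs["labels"] = [str(c) for c in matrices[0].channel_labels]


def read_spectral_matrix_hdf5(path: str | Path):
    """Inverse of :func:`write_spectral_matrix_hdf5`."""
    with h5py.File(path, "r") as f:
        stack = f["matrix_real"][()] + 1j * f["matrix_imag"][()]
        freqs = np.asarray(f.attrs["frequencies"], dtype=float)
        kind = f.attrs.get("kind", "CrossSpectrum")
        n_seg = int(f.attrs.get("n_segments", 0))
        labels = None
        if "labels" in f.attrs:
            labels = [
                s.decode() if isinstance(s, bytes) else str(s) for s in f.attrs["labels"]
            ]
    cls = CoherencyMatrix if kind == "CoherencyMatrix" else CrossSpectrum
    out = []
    for m, fr in zip(stack, freqs):
        if cls is CrossSpectrum:
            out.append(cls(matrix=m, frequency=fr, n_segments=n_seg, channel_labels=labels))
        else:
            out.append(cls(matrix=m, frequency=fr, n_segments=n_seg, channel_labels=labels))
    return out


def write_coupling_csv(matrices: list[CouplingMatrix], path: str | Path) -> None:
    """Long-format CSV of one or more coupling matrices."""
    rows = []
    for M in matrices:
        labels = M.channel_labels or [str(i) for i in range(M.n_channels)]
        for i in range(M.n_channels):
            for j in range(M.n_channels):
                v = complex(M.values[i, j])
                rows.append(
                    {
                        "measure": M.measure_name,
                        "frequency": M.frequency,
                        "channel_i": labels[i],
                        "channel_j": labels[j],
                        "value_real": v.real,
                        "value_imag": v.imag,
                    }
                )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_coupling_csv(path: str | Path) -> list[CouplingMatrix]:
    """Inverse of :func:`write_coupling_csv`."""
    df = pd.read_csv(path)
    out = []
    for (measure, freq), grp in df.groupby(["measure", "frequency"], sort=False):
        labels = list(dict.fromkeys(grp["channel_i"].astype(str)))
        n = len(labels)
        index = {c: i for i, c in enumerate(labels)}
        vals = np.zeros((n, n), dtype=complex)
        for _, row in grp.iterrows():
            vals[index[str(row.channel_i)], index[str(row.channel_j)]] = (
                row.value_real + 1j * row.value_imag
            )
        if np.allclose(vals.imag, 0):
            vals = vals.real
        out.append(
            CouplingMatrix(
                values=vals, measure_name=measure, frequency=float(freq),
                channel_labels=labels,
            )
        )
    return out
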