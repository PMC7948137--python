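"""Epoch container I/O.

The native interchange format is a small HDF5 layout::

    /data    float64, trials x channels x samples (µV or µV/cm²)
    /labels  UTF-8 strings
    /times   float64, seconds
    attrs: srate (Hz), units, provenance (JSON: command, config, seed)

EEGLAB ``.set`` epoch files can be imported read-only (via MNE-Python),
since that is the ecosystem most ERP pipelines live in.
"""
from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .containers import EpochSet

__all__ = ["read_epochs", "write_epochs"]


def write_epochs(epochs: EpochSet, path, overwrite: bool = False) -> None:
    """Write an :class:`EpochSet` to the HDF5 epoch container."""
    path = Path(path)
    if path.exists() and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite=True to replace it")
    with h5py.File(path, "w") as fh:
        fh.create_dataset("data", data=epochs.data)
        fh.create_dataset("labels", data=np.array(epochs.labels, dtype=object),
                          dtype=h5py.string_dtype())
        fh.create_dataset("times", data=epochs.times)
        fh.attrs["srate"] = float(epochs.srate)
        fh.attrs["units"] = epochs.units
        fh.attrs["provenance"] = json.dumps(epochs.provenance, default=str)


def read_epochs(path, format: str | None = None) -> EpochSet:
    """Read epochs from HDF5 (``hdf5``) or EEGLAB (``eeglab_set``) files.

    ``format`` is inferred from the extension (.h5/.hdf5 vs .set) when
    omitted.
    """
    path = Path(path)
    if format is None:
        format = "eeglab_set" if path.suffix.lower() == ".set" else "hdf5"
    if format == "hdf5":
        return _read_hdf5(path)
    if format == "eeglab_set":
        return _read_eeglab(path)
    raise ValueError(f"unknown epoch format {format!r}; use hdf5 or eeglab_set")


def _read_hdf5(path: Path) -> EpochSet:
    with h5py.File(path, "r") as fh:
        for name in ("data", "labels", "times"):
            if name not in fh:
                raise ValueError(f"{path}: missing required dataset /{name}")
        data = np.asarray(fh["data"])
        labels = [lab.decode() if isinstance(lab, bytes) else str(lab)
                  for lab in fh["labels"][()]]
        times = np.asarray(fh["times"])
        srate = float(fh.attrs.get("srate", np.nan))
        units = str(fh.attrs.get("units", "uV"))
        prov = json.loads(fh.attrs.get("provenance", "{}"))
    if data.ndim != 3:
        raise ValueError(f"{path}: /data must be 3-D (trials, channels, samples)")
    if len(labels) != data.shape[1]:
        raise ValueError(
            f"{path}: {len(labels)} labels for {data.shape[1]} data channels"
        )
    if not np.isfinite(srate):
        raise ValueError(f"{path}: missing srate attribute")
    return EpochSet(data, labels, times, srate, units=units, provenance=prov)


def _read_eeglab(path: Path) -> EpochSet:
    import mne

    raw = mne.io.read_epochs_eeglab(str(path), verbose="error")
    data = raw.get_data() * 1e6  # V -> µV
    return EpochSet(
        data,
        list(raw.ch_names),
        np.asarray(raw.times, dtype=float),
        float(raw.info["sfreq"]),
        units="uV",
        provenance={"source": str(path), "format": "eeglab_set"},
    )
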