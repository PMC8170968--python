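"""Trial-set archive format and optional BCI-competition MAT loading.

A trial-set archive is a directory with two files:

``meta.yaml``
    Plain-text metadata: sampling rate, channel names, labels, the three
    array dimensions, dtype and byte order, plus free-form provenance.
``data.bin``
    One raw array of little-endian 64-bit floats, row-major, with
    dimensions trials x channels x samples.

The split keeps the container language-neutral and makes round trips
bit-exact: the metadata dimensions must match the binary byte length
exactly, and any mismatch is a validation error on read.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from .containers import TrialSet

__all__ = ["write_trialset", "read_trialset", "load_competition_mat"]

_META_NAME = "meta.yaml"
_DATA_NAME = "data.bin"


def write_trialset(path, trials: TrialSet, overwrite: bool = False) -> Path:
    """Write a TrialSet archive; refuses to clobber unless ``overwrite``."""
    path = Path(path)
    meta_path = path / _META_NAME
    data_path = path / _DATA_NAME
    if (meta_path.exists() or data_path.exists()) and not overwrite:
        raise FileExistsError(f"archive already exists at {path} (use overwrite=True)")
    path.mkdir(parents=True, exist_ok=True)
    data = np.ascontiguousarray(trials.data, dtype="<f8")
    meta = {
        "format": "spectra-trialset-v1",
        "fs_hz": float(trials.fs),
        "n_trials": int(trials.n_trials),
        "n_channels": int(trials.n_channels),
        "n_samples": int(trials.n_samples),
        "dtype": "float64",
        "byte_order": "little",
        "order": "row-major",
        "labels": [int(v) for v in trials.labels],
        "channel_names": list(trials.channel_names),
        "provenance": {
            str(k): v for k, v in trials.meta.items() if _yaml_safe(v)
        },
    }
    with open(meta_path, "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)
    data.tofile(data_path)
    return path


def _yaml_safe(v) -> bool:
    try:
        yaml.safe_dump(v)
        return True
    except yaml.YAMLError:
        return False


def read_trialset(path) -> TrialSet:
    """Read and validate a TrialSet archive."""
    path = Path(path)
    meta_path = path / _META_NAME
    data_path = path / _DATA_NAME
    if not meta_path.exists() or not data_path.exists():
        raise FileNotFoundError(f"no trial-set archive at {path}")
    with open(meta_path) as fh:
        meta = yaml.safe_load(fh)
    if meta.get("format") != "spectra-trialset-v1":
        raise ValueError(f"unknown archive format {meta.get('format')!r}")
    if meta.get("dtype") != "float64" or meta.get("byte_order") != "little":
        raise ValueError("unsupported dtype/byte order in archive metadata")
    shape = (meta["n_trials"], meta["n_channels"], meta["n_samples"])
    expected_bytes = int(np.prod(shape)) * 8
    actual_bytes = data_path.stat().st_size
    if actual_bytes != expected_bytes:
        raise ValueError(
            f"data.bin has {actual_bytes} bytes but metadata implies "
            f"{expected_bytes} ({shape})"
        )
    data = np.fromfile(data_path, dtype="<f8").reshape(shape)
    if not np.isfinite(data).all():
        raise ValueError("archive data contains NaN or Inf")
    labels = np.asarray(meta["labels"], dtype=np.int64)
    return TrialSet(
        data=data,
        labels=labels,
        fs=float(meta["fs_hz"]),
        channel_names=list(meta["channel_names"]),
        meta=dict(meta.get("provenance") or {}),
    )


def load_competition_mat(
    path,
    dataset_id: str,
    epoch_window: tuple[float, float] = (0.5, 2.5),
) -> TrialSet:
    """Load a user-downloaded BCI Competition MAT export and epoch it.

    Supports the continuous-format MAT files of BCI Competition III
    dataset IVa (``dataset_id="III-IVa"``) and IV dataset I
    (``dataset_id="IV-I"``), which carry a ``cnt`` sample matrix, an
    ``mrk`` marker struct (cue positions and labels) and an ``nfo``
    header.  Files are never fetched automatically: download them
    manually from the competition site and pass the local path.
    """
    from scipy.io import loadmat  # local import; only needed here

    path = Path(path)
    if dataset_id not in ("III-IVa", "IV-I"):
        raise ValueError(
            f"unsupported dataset_id {dataset_id!r}; supported: 'III-IVa', 'IV-I' "
            "(the IIb recordings are GDF files, outside this loader's scope)"
        )
    if not path.exists():
        raise FileNotFoundError(
            f"{path} not found: BCI Competition data must be downloaded "
            "manually (http://www.bbci.de/competition/) and is never fetched "
            "automatically"
        )
    mat = loadmat(path, squeeze_me=True, struct_as_record=False)
    for key in ("cnt", "mrk", "nfo"):
        if key not in mat:
            raise ValueError(f"MAT file lacks required field {key!r}")
    cnt = np.asarray(mat["cnt"], dtype=np.float64)  # samples x channels
    if dataset_id == "III-IVa":
        cnt *= 0.1  # stored as int16 in units of 0.1 microvolt
    mrk = mat["mrk"]
    nfo = mat["nfo"]
    fs = float(np.atleast_1d(getattr(nfo, "fs"))[0])
    pos = np.atleast_1d(getattr(mrk, "pos")).astype(np.int64)
    y = np.atleast_1d(getattr(mrk, "y")).astype(np.float64)
    keep = ~np.isnan(y)  # unlabeled (competition test) cues are dropped
    pos, y = pos[keep], y[keep]
    labels = np.where(y == 1, 1, -1)
    record = cnt.T  # channels x samples
    t0, t1 = epoch_window
    start = (pos + int(round(t0 * fs))).astype(np.int64)
    stop = (pos + int(round(t1 * fs))).astype(np.int64)
    if np.any(start < 0) or np.any(stop > record.shape[1]):
        raise ValueError("epoch window exceeds the continuous record")
    data = np.stack([record[:, a:b] for a, b in zip(start, stop)])
    clab = getattr(nfo, "clab", None)
    names = [str(c) for c in np.atleast_1d(clab)] if clab is not None else None
    return TrialSet(
        data=data,
        labels=labels,
        fs=fs,
        channel_names=names,
        meta={"source": str(path), "dataset_id": dataset_id,
              "epoch_window": list(epoch_window)},
    )
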