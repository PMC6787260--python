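"""HDF5/CSV/TIFF containers for photon streams and decoded images.

The native photon container is a documented HDF5 layout (see
``docs/hdf5_layout.md``):

* ``/events``     — datasets ``macro_time`` (int64 ticks), ``micro_time``
  (int32, -1 = absent), ``channel`` (int16)
* ``/markers``    — datasets ``kind`` (int8; 0=pixel, 1=line, 2=frame) and
  ``macro_time`` (int64 ticks)
* ``/meta``       — attrs ``clock_hz`` plus a JSON-encoded ``metadata`` attr

Decoded objects use ``/counts`` (line-scan matrix) or ``/decay`` (FLIM stack)
with their geometry stored as attributes.  A CSV export exists for small
streams.  All datasets are written with ``track_times=False`` so identical
inputs produce byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import FormatError
from .tcspc import FlimImage, LineScanMatrix, PhotonStream

_DS = dict(track_times=False)


def _require(group, name: str, path) -> "np.ndarray":
    if name not in group:
        raise FormatError(f"{path}: missing required dataset '{group.name}/{name}'")
    return group[name][()]


def _require_group(f, name: str, path):
    if name not in f:
        raise FormatError(f"{path}: missing required group '/{name}'")
    return f[name]


def write_stream(stream: PhotonStream, path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        ev = f.create_group("events")
        ev.create_dataset("macro_time", data=stream.macro_times, **_DS)
        ev.create_dataset("micro_time", data=stream.micro_times, **_DS)
        ev.create_dataset("channel", data=stream.channels, **_DS)
        mk = f.create_group("markers")
        mk.create_dataset("kind", data=stream.marker_kinds, **_DS)
        mk.create_dataset("macro_time", data=stream.marker_times, **_DS)
        meta = f.create_group("meta")
        meta.attrs["clock_hz"] = stream.clock_hz
        meta.attrs["metadata"] = json.dumps(stream.metadata, sort_keys=True)


def read_stream(path) -> PhotonStream:
    import h5py

    with h5py.File(path, "r") as f:
        ev = _require_group(f, "events", path)
        mk = _require_group(f, "markers", path)
        meta = _require_group(f, "meta", path)
        if "clock_hz" not in meta.attrs:
            raise FormatError(f"{path}: missing required attribute '/meta@clock_hz'")
        return PhotonStream(
            macro_times=_require(ev, "macro_time", path),
            micro_times=_require(ev, "micro_time", path),
            channels=_require(ev, "channel", path),
            marker_kinds=_require(mk, "kind", path),
            marker_times=_require(mk, "macro_time", path),
            clock_hz=float(meta.attrs["clock_hz"]),
            metadata=json.loads(meta.attrs.get("metadata", "{}")),
        )


def write_linescan(matrix: LineScanMatrix, path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        d = f.create_dataset("counts", data=matrix.counts, **_DS)
        d.attrs["line_period_s"] = matrix.line_period
        d.attrs["pixel_size_um"] = matrix.pixel_size
        d.attrs["dropped_photons"] = matrix.dropped_photons


def read_linescan(path) -> LineScanMatrix:
    import h5py

    with h5py.File(path, "r") as f:
        if "counts" not in f:
            raise FormatError(f"{path}: missing required dataset '/counts'")
        d = f["counts"]
        for a in ("line_period_s", "pixel_size_um", "dropped_photons"):
            if a not in d.attrs:
                raise FormatError(f"{path}: missing required attribute '/counts@{a}'")
        return LineScanMatrix(
            counts=d[()],
            line_period=float(d.attrs["line_period_s"]),
            pixel_size=float(d.attrs["pixel_size_um"]),
            dropped_photons=int(d.attrs["dropped_photons"]),
        )


def write_flim_image(img: FlimImage, path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        d = f.create_dataset("decay", data=img.decay, **_DS)
        d.attrs["pixel_size_um"] = img.pixel_size
        d.attrs["bin_width_ns"] = img.bin_width
        d.attrs["dropped_photons"] = img.dropped_photons
        d.attrs["metadata"] = json.dumps(img.metadata, sort_keys=True)


def read_flim_image(path) -> FlimImage:
    import h5py

    with h5py.File(path, "r") as f:
        if "decay" not in f:
            raise FormatError(f"{path}: missing required dataset '/decay'")
        d = f["decay"]
        for a in ("pixel_size_um", "bin_width_ns", "dropped_photons"):
            if a not in d.attrs:
                raise FormatError(f"{path}: missing required attribute '/decay@{a}'")
        return FlimImage(
            decay=d[()],
            pixel_size=float(d.attrs["pixel_size_um"]),
            bin_width=float(d.attrs["bin_width_ns"]),
            dropped_photons=int(d.attrs["dropped_photons"]),
            metadata=json.loads(d.attrs.get("metadata", "{}")),
        )


def stream_to_csv(stream: PhotonStream, path) -> None:
    """CSV export for small fixtures: one row per event or marker."""
    rows = []
    for t, m, c in zip(stream.macro_times, stream.micro_times, stream.channels):
        rows.append(("event", int(t), int(m), int(c), ""))
    for k, t in zip(stream.marker_kinds, stream.marker_times):
        rows.append(("marker", int(t), -1, -1, int(k)))
    df = pd.DataFrame(rows, columns=["record", "macro_time", "micro_time", "channel", "marker_kind"])
    df.to_csv(path, index=False)


def stream_from_csv(path, clock_hz: float | None = None) -> PhotonStream:
    df = pd.read_csv(path)
    ev = df[df["record"] == "event"]
    mk = df[df["record"] == "marker"].sort_values("macro_time", kind="stable")
    from .tcspc import DEFAULT_CLOCK_HZ

    return PhotonStream(
        macro_times=ev["macro_time"].to_numpy(np.int64),
        micro_times=ev["micro_time"].to_numpy(np.int32),
        channels=ev["channel"].to_numpy(np.int16),
        marker_kinds=mk["marker_kind"].to_numpy(np.int8),
        marker_times=mk["macro_time"].to_numpy(np.int64),
        clock_hz=clock_hz or DEFAULT_CLOCK_HZ,
    )


def write_tiff(image: np.ndarray, path, pixel_size: float | None = None) -> None:
    """Write an intensity plane, map or mask to TIFF (masks as 8-bit)."""
    arr = np.asarray(image)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8) * 255
    meta = {"pixel_size_um": pixel_size} if pixel_size is not None else None
    tifffile.imwrite(path, arr, metadata=meta)


def read_tiff(path) -> np.ndarray:
    return tifffile.imread(path)


def write_ground_truth(truth, path) -> None:
    """JSON sidecar for a simulation's :class:`~fcsflim.synthetic.GroundTruth`."""
    Path(path).write_text(truth.to_json())
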