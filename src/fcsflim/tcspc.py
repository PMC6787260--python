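"""Photon-event data model and decoding of marker-tagged TCSPC streams.

A :class:`PhotonStream` is the raw currency of both scanning FCS and FLIM:
per-photon macro-times (arrival, in ticks of an external clock, 20 MHz by
default) with optional micro-times (TCSPC bin index within the excitation
period), plus the pixel/line/frame marker events registered by the scanner.

Decoding turns a stream into either a line-scan matrix (``xt`` imaging mode,
one row per scan period) or a FLIM decay stack (``xy`` raster with a
micro-time axis).  Decoding is total and lossless up to gating: every photon
is either binned or counted in ``dropped_photons``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .errors import DecodingError, StreamIntegrityError

DEFAULT_CLOCK_HZ = 2.0e7

#: integer codes used for marker kinds in memory and in the HDF5 container
MARKER_PIXEL = 0
MARKER_LINE = 1
MARKER_FRAME = 2

MARKER_NAMES = {MARKER_PIXEL: "pixel", MARKER_LINE: "line", MARKER_FRAME: "frame"}
MARKER_CODES = {v: k for k, v in MARKER_NAMES.items()}


@dataclass
class PhotonStream:
    """Time-ordered photon events plus scanner markers.

    Parameters
    ----------
    macro_times:
        Photon arrival times in clock ticks (int64, non-decreasing).
    micro_times:
        TCSPC micro-time bin index per photon, ``-1`` where absent
        (continuous-wave acquisitions carry no micro-time).
    channels:
        Detector/router channel id per photon.
    marker_kinds, marker_times:
        Scanner marker events, kinds coded by :data:`MARKER_PIXEL`,
        :data:`MARKER_LINE`, :data:`MARKER_FRAME`.
    """

    macro_times: np.ndarray
    micro_times: np.ndarray | None = None
    channels: np.ndarray | None = None
    marker_kinds: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int8))
    marker_times: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    clock_hz: float = DEFAULT_CLOCK_HZ
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.macro_times = np.asarray(self.macro_times, dtype=np.int64)
        if self.micro_times is None:
            self.micro_times = np.full(self.macro_times.shape, -1, dtype=np.int32)
        else:
            self.micro_times = np.asarray(self.micro_times, dtype=np.int32)
        if self.channels is None:
            self.channels = np.zeros(self.macro_times.shape, dtype=np.int16)
        else:
            self.channels = np.asarray(self.channels, dtype=np.int16)
        self.marker_kinds = np.asarray(self.marker_kinds, dtype=np.int8)
        self.marker_times = np.asarray(self.marker_times, dtype=np.int64)

    @property
    def n_photons(self) -> int:
        return int(self.macro_times.size)

    def marker_times_of(self, kind: int) -> np.ndarray:
        return self.marker_times[self.marker_kinds == kind]

    def validate(self) -> None:
        """Raise :class:`StreamIntegrityError` on non-monotone times."""
        if self.macro_times.size and np.any(np.diff(self.macro_times) < 0):
            raise StreamIntegrityError("photon macro_times are not non-decreasing")
        if self.marker_times.size and np.any(np.diff(self.marker_times) < 0):
            raise StreamIntegrityError("marker macro_times are not non-decreasing")

    def equals(self, other: "PhotonStream") -> bool:
        return (
            self.clock_hz == other.clock_hz
            and np.array_equal(self.macro_times, other.macro_times)
            and np.array_equal(self.micro_times, other.micro_times)
            and np.array_equal(self.channels, other.channels)
            and np.array_equal(self.marker_kinds, other.marker_kinds)
            and np.array_equal(self.marker_times, other.marker_times)
            and self.metadata == other.metadata
        )


@dataclass
class LineScanMatrix:
    """Decoded ``xt`` photon counts: one row per scan period."""

    counts: np.ndarray  # [n_lines, n_pixels] integer
    line_period: float  # s
    pixel_size: float  # µm
    dropped_photons: int = 0

    @property
    def n_lines(self) -> int:
        return int(self.counts.shape[0])

    @property
    def n_pixels(self) -> int:
        return int(self.counts.shape[1])

    def equals(self, other: "LineScanMatrix") -> bool:
        return (
            np.array_equal(self.counts, other.counts)
            and self.line_period == other.line_period
            and self.pixel_size == other.pixel_size
            and self.dropped_photons == other.dropped_photons
        )


@dataclass
class DecayHistogram:
    """Micro-time histogram of a set of photons (one decay curve)."""

    counts: np.ndarray  # integer per micro-time bin
    bin_width: float  # ns
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)

    @property
    def n_bins(self) -> int:
        return int(self.counts.size)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def times(self) -> np.ndarray:
        """Bin-centre times in ns."""
        return (np.arange(self.n_bins) + 0.5) * self.bin_width


@dataclass
class FlimImage:
    """Per-pixel decay histograms: stack [ny, nx, n_bins]."""

    decay: np.ndarray
    pixel_size: float  # µm
    bin_width: float  # ns
    dropped_photons: int = 0
    metadata: dict[str, Any] = field(default_factory=dict)

    @property
    def intensity(self) -> np.ndarray:
        """Photon counts per pixel (bin-sum of the decay stack, exactly)."""
        return self.decay.sum(axis=-1)

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.decay.shape)  # type: ignore[return-value]

    def pooled_decay(self, mask: np.ndarray | None = None) -> DecayHistogram:
        """Photon-weighted sum decay over ``mask`` (whole image if None)."""
        if mask is None:
            counts = self.decay.sum(axis=(0, 1))
        else:
            counts = self.decay[mask].sum(axis=0)
        return DecayHistogram(counts=counts, bin_width=self.bin_width)

    def equals(self, other: "FlimImage") -> bool:
        return (
            np.array_equal(self.decay, other.decay)
            and self.pixel_size == other.pixel_size
            and self.bin_width == other.bin_width
            and self.dropped_photons == other.dropped_photons
            and self.metadata == other.metadata
        )


def decode_linescan(stream: PhotonStream, n_pixels: int, pixel_size: float = 0.26) -> LineScanMatrix:
    """Decode a line-marker-tagged stream into an ``xt`` count matrix.

    Each photon between consecutive line markers is assigned a pixel by
    linear interpolation of its macro-time across the line interval, using
    half-open intervals ``[start, end)`` and 0-based pixel indices.  Photons
    before the first or at/after the last line marker land in
    ``dropped_photons``.  The line period is the *median* inter-marker
    interval (robust to a corrupted marker).
    """
    stream.validate()
    lt = stream.marker_times_of(MARKER_LINE)
    if lt.size < 2:
        raise DecodingError(f"need >= 2 line markers to decode, got {lt.size}")
    n_lines = lt.size - 1
    counts = np.zeros((n_lines, n_pixels), dtype=np.int64)
    t = stream.macro_times
    idx = np.searchsorted(lt, t, side="right") - 1
    valid = (idx >= 0) & (idx < n_lines)
    dropped = int((~valid).sum())
    if valid.any():
        i = idx[valid]
        frac = (t[valid] - lt[i]) / (lt[i + 1] - lt[i])
        pix = np.minimum((frac * n_pixels).astype(np.int64), n_pixels - 1)
        np.add.at(counts, (i, pix), 1)
    line_period = float(np.median(np.diff(lt)) / stream.clock_hz)
    return LineScanMatrix(counts=counts, line_period=line_period,
                          pixel_size=pixel_size, dropped_photons=dropped)


def decode_flim_image(stream: PhotonStream, nx: int, ny: int, n_bins: int,
                      pixel_size: float = 0.275, bin_width: float | None = None) -> FlimImage:
    """Decode a pixel-marker-tagged raster stream into a FLIM decay stack.

    The raster is defined by pixel markers (one per pixel start, row-major,
    ``nx * ny`` per frame); line markers, when present, must number ``ny``
    per frame and frame markers delimit repeated frames that are summed.
    Photons with no micro-time or with a micro-time outside ``n_bins`` are
    counted as dropped (out-of-gate).
    """
    stream.validate()
    pt = stream.marker_times_of(MARKER_PIXEL)
    lt = stream.marker_times_of(MARKER_LINE)
    per_frame = nx * ny
    if pt.size == 0 or pt.size % per_frame != 0:
        raise DecodingError(
            f"pixel-marker count {pt.size} inconsistent with {nx}x{ny} raster")
    n_frames = pt.size // per_frame
    if lt.size and lt.size != ny * n_frames:
        raise DecodingError(
            f"line-marker count {lt.size} inconsistent with ny={ny}, frames={n_frames}")
    decay = np.zeros((ny, nx, n_bins), dtype=np.int64)
    t = stream.macro_times
    micro = stream.micro_times
    idx = np.searchsorted(pt, t, side="right") - 1
    valid = (idx >= 0) & (micro >= 0) & (micro < n_bins)
    dropped = int((~valid).sum())
    if valid.any():
        k = idx[valid] % per_frame
        y, x = k // nx, k % nx
        np.add.at(decay, (y, x, micro[valid]), 1)
    if bin_width is None:
        bin_width = float(stream.metadata.get("microtime_bin_width_ns", 12.5 / n_bins))
    return FlimImage(decay=decay, pixel_size=pixel_size, bin_width=bin_width,
                     dropped_photons=dropped)
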