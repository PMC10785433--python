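"""Reading and writing flow-cytometry event tables.

Events live in an :class:`EventTable`: one row per cell, one column per
detector channel (forward/side scatter and area-integrated fluorescence such
as ``FITC.A`` or ``PE.CF594.A``), in linear instrument units.  Tables can be
loaded from FCS 3.0/3.1 files or from the CSV files the conversion step
writes, and the two representations round-trip exactly.

The FCS support here is deliberately small: list-mode data, float or integer
storage, little- or big-endian.  Spillover compensation is assumed to have
been applied on-instrument; values are passed through as stored, and negative
values (baseline-restored scatter can dip below zero) are preserved rather
than clamped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import FormatError, MissingChannelError, ParseError, UnsupportedVersionError

__all__ = [
    "EventTable",
    "DEFAULT_CHANNEL_ALIASES",
    "read_fcs",
    "write_fcs",
    "write_csv",
    "read_csv_events",
]

#: Instrument spellings mapped onto the dotted channel names used throughout
#: the pipeline (BD exports use dashes, analysis configs use dots).
DEFAULT_CHANNEL_ALIASES: dict[str, str] = {
    "FSC-H": "FSC.H",
    "FSC-A": "FSC.A",
    "SSC-H": "SSC.H",
    "SSC-A": "SSC.A",
    "FITC-A": "FITC.A",
    "PE-CF594-A": "PE.CF594.A",
    "BV605-A": "BV605.A",
    "BV510-A": "BV510.A",
}


@dataclass
class EventTable:
    """Per-event channel intensities for one sample.

    Parameters
    ----------
    sample_id
        Identifier of the sample the events came from.
    channels
        Ordered, unique channel names, one per column of ``events``.
    events
        ``(n_events, n_channels)`` float array of intensities.  All values
        must be finite; negative values are legal (instrument baselines).
    origin
        Optional per-event provenance labels attached by the simulator.
        Never written to disk and never consumed by analysis stages.
    """

    sample_id: str
    channels: list[str]
    events: np.ndarray
    origin: np.ndarray | None = field(default=None, compare=False, repr=False)

    def __post_init__(self) -> None:
        self.events = np.asarray(self.events, dtype=float)
        if self.events.ndim != 2:
            self.events = self.events.reshape(-1, len(self.channels))
        if self.events.shape[1] != len(self.channels):
            raise ValueError(
                f"events have {self.events.shape[1]} columns for "
                f"{len(self.channels)} channels"
            )
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("channel names must be unique")
        if self.events.size and not np.all(np.isfinite(self.events)):
            raise ValueError("event intensities must be finite")
        if self.origin is not None and len(self.origin) != len(self.events):
            raise ValueError("origin labels must match the number of events")

    def __len__(self) -> int:
        return self.events.shape[0]

    def column(self, channel: str) -> np.ndarray:
        """Return one channel as a 1-D view, raising if it is absent."""
        try:
            idx = self.channels.index(channel)
        except ValueError:
            raise MissingChannelError(channel) from None
        return self.events[:, idx]

    def has_channel(self, channel: str) -> bool:
        return channel in self.channels

    def rename_channels(self, aliases: Mapping[str, str]) -> "EventTable":
        """Return a copy with channel names translated through ``aliases``."""
        renamed = [aliases.get(c, c) for c in self.channels]
        return EventTable(self.sample_id, renamed, self.events.copy(), origin=self.origin)

    def select(self, mask: np.ndarray) -> "EventTable":
        """Return the subset of events where ``mask`` is true."""
        origin = self.origin[mask] if self.origin is not None else None
        return EventTable(self.sample_id, list(self.channels), self.events[mask], origin=origin)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.events, columns=self.channels)


# ---------------------------------------------------------------------------
# FCS 3.0 / 3.1
# ---------------------------------------------------------------------------

_SUPPORTED_VERSIONS = (b"FCS3.0", b"FCS3.1")


def _read_offsets(header: bytes, path: str) -> tuple[int, int]:
    try:
        text_begin = int(header[10:18])
        text_end = int(header[18:26])
    except ValueError as exc:
        raise FormatError(f"{path}: malformed header offsets at byte 10") from exc
    return text_begin, text_end


def _parse_text_segment(raw: bytes, path: str, offset: int) -> dict[str, str]:
    if not raw:
        raise FormatError(f"{path}: empty TEXT segment at offset {offset}")
    delim = raw[0:1].decode("latin-1")
    body = raw[1:].decode("latin-1")
    if body.endswith(delim):
        body = body[:-1]
    parts = body.split(delim)
    if len(parts) % 2:
        # A trailing key without a value: tolerate whitespace padding only.
        if parts[-1].strip():
            raise FormatError(f"{path}: odd keyword/value count in TEXT segment at offset {offset}")
        parts = parts[:-1]
    return {k.strip(): v for k, v in zip(parts[::2], parts[1::2])}


_DTYPE_CODES = {"F": "f4", "D": "f8"}


def read_fcs(
    path: str | Path,
    sample_id: str | None = None,
    aliases: Mapping[str, str] | None = None,
) -> EventTable:
    """Read a list-mode FCS 3.0/3.1 file into an :class:`EventTable`.

    Channel names come from the ``$PnN`` short-name keywords; the event
    count must equal the ``$TOT`` keyword.  ``aliases`` optionally translates
    instrument channel spellings (``"PE-CF594-A"``) into the dotted names the
    gate definitions use.

    Raises
    ------
    UnsupportedVersionError
        If the file is not FCS 3.0 or 3.1.
    FormatError
        If the file is truncated or structurally malformed; the message
        names the failing byte offset.
    """
    path = Path(path)
    blob = path.read_bytes()
    if len(blob) < 58:
        raise FormatError(f"{path}: truncated header, {len(blob)} bytes at offset 0")
    version = blob[:6]
    if version not in _SUPPORTED_VERSIONS:
        raise UnsupportedVersionError(
            f"{path}: version {version.decode('latin-1', 'replace')!r} is not FCS 3.0/3.1"
        )
    text_begin, text_end = _read_offsets(blob, str(path))
    if text_end >= len(blob) or text_begin >= text_end:
        raise FormatError(f"{path}: TEXT segment exceeds file size at offset {text_begin}")
    text = _parse_text_segment(blob[text_begin : text_end + 1], str(path), text_begin)

    def req(key: str) -> str:
        try:
            return text[key]
        except KeyError:
            raise FormatError(f"{path}: missing required keyword {key}") from None

    mode = req("$MODE").strip().upper()
    if mode != "L":
        raise FormatError(f"{path}: only list mode ($MODE L) is supported, got {mode!r}")
    n_par = int(req("$PAR"))
    n_tot = int(req("$TOT"))
    datatype = req("$DATATYPE").strip().upper()
    byteord = req("$BYTEORD").strip()
    endian = "<" if byteord.startswith("1") else ">"

    names = []
    for k in range(1, n_par + 1):
        names.append(text.get(f"$P{k}N", f"P{k}").strip())

    data_begin = int(text.get("$BEGINDATA", "0") or 0)
    data_end = int(text.get("$ENDDATA", "0") or 0)
    if data_begin == 0:
        try:
            data_begin = int(blob[26:34])
            data_end = int(blob[34:42])
        except ValueError as exc:
            raise FormatError(f"{path}: malformed DATA offsets at byte 26") from exc

    if datatype in _DTYPE_CODES:
        dtype = np.dtype(endian + _DTYPE_CODES[datatype])
    elif datatype == "I":
        bits = {int(text.get(f"$P{k}B", "32")) for k in range(1, n_par + 1)}
        if len(bits) != 1 or bits.pop() not in (16, 32):
            raise FormatError(f"{path}: only uniform 16/32-bit integer data is supported")
        width = int(text.get("$P1B", "32")) // 8
        dtype = np.dtype(f"{endian}u{width}")
    else:
        raise FormatError(f"{path}: unsupported $DATATYPE {datatype!r}")

    expected = n_par * n_tot * dtype.itemsize
    if data_end - data_begin + 1 < expected or data_begin + expected > len(blob):
        raise FormatError(
            f"{path}: DATA segment truncated at offset {data_begin} "
            f"(need {expected} bytes)"
        )
    raw = blob[data_begin : data_begin + expected]
    events = np.frombuffer(raw, dtype=dtype).astype(float).reshape(n_tot, n_par)

    table = EventTable(sample_id or path.stem, names, events)
    if aliases:
        table = table.rename_channels(aliases)
    return table


def write_fcs(table: EventTable, path: str | Path) -> Path:
    """Write a minimal FCS 3.1 file (float32, little-endian, list mode).

    Fixture-grade: enough of the standard for round-trip testing of the
    conversion step, not a general-purpose FCS writer.  Intensities are
    stored as float32, so values representable in single precision
    round-trip bit-exactly.
    """
    path = Path(path)
    data = np.ascontiguousarray(table.events, dtype="<f4")
    n_tot, n_par = data.shape

    # TEXT segment with placeholder data offsets, padded to fixed width so
    # the offsets can be patched in without changing segment length.
    d = "/"
    kv: list[tuple[str, str]] = [
        ("$BEGINANALYSIS", "0"),
        ("$ENDANALYSIS", "0"),
        ("$BEGINSTEXT", "0"),
        ("$ENDSTEXT", "0"),
        ("$BEGINDATA", "{begindata:>12d}"),
        ("$ENDDATA", "{enddata:>12d}"),
        ("$MODE", "L"),
        ("$DATATYPE", "F"),
        ("$BYTEORD", "1,2,3,4"),
        ("$NEXTDATA", "0"),
        ("$PAR", str(n_par)),
        ("$TOT", str(n_tot)),
    ]
    for k, name in enumerate(table.channels, start=1):
        if d in name:
            raise ValueError(f"channel name {name!r} contains the delimiter {d!r}")
        kv += [(f"$P{k}N", name), (f"$P{k}B", "32"), (f"$P{k}E", "0,0"), (f"$P{k}R", "262144")]

    text_template = d + d.join(f"{k}{d}{v}" for k, v in kv) + d
    text_begin = 58
    text_end = text_begin + len(text_template.format(begindata=0, enddata=0)) - 1
    data_begin = text_end + 1
    data_end = data_begin + data.nbytes - 1 if data.nbytes else data_begin
    text = text_template.format(begindata=data_begin, enddata=data_end)

    header = b"FCS3.1    " + (
        f"{text_begin:>8d}{text_end:>8d}"
        + (f"{data_begin:>8d}{data_end:>8d}" if data_end <= 99_999_999 else f"{0:>8d}{0:>8d}")
        + f"{0:>8d}{0:>8d}"
    ).encode("ascii")
    assert len(header) == 58

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text.encode("latin-1"))
        fh.write(data.tobytes())
    return path


# ---------------------------------------------------------------------------
# CSV conversion
# ---------------------------------------------------------------------------


def write_csv(table: EventTable, path: str | Path) -> Path:
    """Write an event table as CSV: header of channel names, one row per event.

    Values are written at full precision (shortest decimal that round-trips
    the float64), comma-separated with ``.`` decimals, matching the dotted
    channel-name convention (``FITC.A``), so no quoting is required.
    """
    path = Path(path)
    header = ",".join(table.channels)
    with open(path, "w", newline="\n") as fh:
        fh.write(header + "\n")
        for row in table.events:
            fh.write(",".join(repr(float(v)) for v in row) + "\n")
    return path


def read_csv_events(path: str | Path, sample_id: str | None = None) -> EventTable:
    """Read a per-event CSV (header of channel names, numeric body).

    Inverse of :func:`write_csv` on its outputs.  Negative values are kept
    as-is; nothing is clamped.  Raises :class:`ParseError` naming the row and
    column of the first non-numeric cell, or on ragged rows.
    """
    path = Path(path)
    try:
        # round_trip parsing so write_csv -> read_csv_events is lossless
        df = pd.read_csv(path, header=0, skip_blank_lines=True, float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    channels = [str(c) for c in df.columns]
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        series = df[col]
        if not pd.api.types.is_numeric_dtype(series):
            for row, cell in enumerate(series):
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise ParseError(
                        f"{path}: non-numeric value {cell!r} at row {row + 2}, "
                        f"column {channels[j]!r}"
                    ) from None
            series = series.astype(float)
        if series.isna().any():
            row = int(np.flatnonzero(series.isna().to_numpy())[0])
            raise ParseError(
                f"{path}: ragged/missing value at row {row + 2}, column {channels[j]!r}"
            )
        values[:, j] = series.to_numpy(dtype=float)
    return EventTable(sample_id or path.stem, channels, values)
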