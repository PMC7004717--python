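"""Reading and writing EEG traces and index streams.

All downstream code consumes only the two in-memory containers defined
here: :class:`EEGRecord` (a uniformly sampled single-channel trace in
microvolts) and :class:`IndexSeries` (a timestamped stream of index
values such as CAI, SpEn or an imported BIS export).

Conventions fixed at this boundary:

* time is seconds from recording start (``t0`` offset, default 0) —
  never sample indices;
* amplitude is microvolts everywhere;
* index CSVs are two comma-separated columns ``time_s,value`` with an
  optional single header row.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "EEGRecord",
    "IndexSeries",
    "ValidationError",
    "read_edf",
    "write_edf",
    "read_csv_signal",
    "read_index_csv",
    "write_index_csv",
]

#: index streams on the 0-100 monitor display scale; values outside that
#: range are rejected at construction for these names only.
DISPLAY_SCALE_NAMES = frozenset({"CAI", "SpEn", "BIS"})


class ValidationError(ValueError):
    """Raised when an input file or in-memory object violates a contract."""


@dataclass(frozen=True)
class EEGRecord:
    """A uniformly sampled single-channel EEG trace.

    Parameters
    ----------
    samples
        Amplitudes in microvolts.
    fs
        Sampling rate in Hz, > 0.
    channel_label
        Free-text channel name.
    t0
        Start time in seconds (offset convention, default 0).
    """

    samples: np.ndarray
    fs: float
    channel_label: str = "EEG"
    t0: float = 0.0

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 1 or samples.size < 1:
            raise ValidationError("EEGRecord needs a 1-D, non-empty sample array")
        if not np.all(np.isfinite(samples)):
            raise ValidationError("EEGRecord samples must all be finite")
        if not (self.fs > 0):
            raise ValidationError(f"sampling rate must be positive, got {self.fs}")

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.n_samples / self.fs

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs


@dataclass(frozen=True)
class IndexSeries:
    """A timestamped stream of index values on the method's native scale."""

    name: str
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if times.ndim != 1 or values.ndim != 1:
            raise ValidationError("times and values must be 1-D")
        if times.size != values.size:
            raise ValidationError(
                f"length mismatch: {times.size} times vs {values.size} values"
            )
        if times.size > 1 and not np.all(np.diff(times) > 0):
            raise ValidationError(f"{self.name}: times must be strictly increasing")
        if not np.all(np.isfinite(values)):
            raise ValidationError(f"{self.name}: values must be finite")
        if self.name in DISPLAY_SCALE_NAMES and values.size:
            lo, hi = values.min(), values.max()
            if lo < 0 or hi > 100:
                raise ValidationError(
                    f"{self.name} values must lie in [0, 100]; got range [{lo}, {hi}]"
                )

    def __len__(self) -> int:
        return int(self.times.size)


# ---------------------------------------------------------------------------
# CSV
# ---------------------------------------------------------------------------

def read_csv_signal(path: str | Path, fs: float) -> EEGRecord:
    """Read a one-column CSV of microvolt amplitudes sampled at ``fs`` Hz.

    An optional single header row is tolerated; any other non-numeric
    row raises :class:`ValidationError` naming the offending line.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    if not (fs > 0):
        raise ValidationError(f"sampling rate must be positive, got {fs}")
    values: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.strip()
            if not text:
                continue
            # tolerate a trailing comma / single-column CSV exports
            text = text.rstrip(",")
            try:
                values.append(float(text))
            except ValueError:
                if lineno == 1:  # header row
                    continue
                raise ValidationError(
                    f"{path}: non-numeric value {text!r} on line {lineno}"
                ) from None
    if not values:
        raise ValidationError(f"{path}: no numeric samples found")
    return EEGRecord(np.asarray(values), fs=fs, channel_label=path.stem)


def read_index_csv(path: str | Path, name: str) -> IndexSeries:
    """Read a two-column ``time_s,value`` CSV as an :class:`IndexSeries`.

    For the named monitors (CAI, SpEn, BIS) values outside [0, 100] are
    rejected, as are unsorted time stamps.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    times: list[float] = []
    values: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.strip()
            if not text:
                continue
            parts = text.split(",")
            if len(parts) != 2:
                raise ValidationError(
                    f"{path}: expected two columns on line {lineno}, got {len(parts)}"
                )
            try:
                t, v = float(parts[0]), float(parts[1])
            except ValueError:
                if lineno == 1:
                    continue
                raise ValidationError(
                    f"{path}: non-numeric row on line {lineno}: {text!r}"
                ) from None
            times.append(t)
            values.append(v)
    return IndexSeries(name, np.asarray(times), np.asarray(values))


def write_index_csv(series: IndexSeries, path: str | Path) -> None:
    """Write ``time_s,value`` CSV; inverse of :func:`read_index_csv`."""
    path = Path(path)
    with open(path, "w", newline="\n") as fh:
        fh.write("time_s,value\n")
        for t, v in zip(series.times, series.values):
            fh.write(f"{t:.10g},{v:.10g}\n")


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def read_edf(path: str | Path, channel: str | int | None = None) -> EEGRecord:
    """Read one channel of an EDF/EDF+ file as an :class:`EEGRecord`.

    Parameters
    ----------
    path
        EDF file path.
    channel
        Channel label or 0-based index.  May be omitted only when the
        file holds exactly one signal; otherwise the selector must
        resolve to exactly one channel.

    Notes
    -----
    Amplitudes are returned in microvolts using the header's physical
    calibration.  Reading is delegated to :mod:`mne`, which converts
    EDF physical dimensions to SI volts internally.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    import mne  # deferred: import is slow and only needed for EDF

    try:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:  # unreadable / truncated header
        raise ValidationError(f"{path}: cannot read EDF header ({exc})") from exc

    names = list(raw.ch_names)
    if channel is None:
        if len(names) != 1:
            raise ValidationError(
                f"{path}: {len(names)} channels present ({names}); "
                "a channel selector is required"
            )
        idx = 0
    elif isinstance(channel, int):
        if not 0 <= channel < len(names):
            raise ValidationError(
                f"{path}: channel index {channel} out of range 0..{len(names) - 1}"
            )
        idx = channel
    else:
        matches = [i for i, n in enumerate(names) if n == channel]
        if len(matches) != 1:
            raise ValidationError(
                f"{path}: channel selector {channel!r} matches {len(matches)} of {names}"
            )
        idx = matches[0]

    data = raw.get_data(picks=[idx])[0] * 1e6  # volts -> microvolts
    return EEGRecord(data, fs=float(raw.info["sfreq"]), channel_label=names[idx])


def write_edf(record: EEGRecord, path: str | Path) -> None:
    """Write a single-channel EDF file.

    A deliberately minimal writer: one signal, integer sampling rates,
    1-second data records, 16-bit samples scaled to the record's
    physical range.  Round-tripping through :func:`read_edf` preserves
    the sample count exactly and amplitudes within one quantization
    step, ``(max - min) / 65535``.

    Recordings whose length is not a whole number of seconds are padded
    with the final sample value to complete the last data record (EDF
    stores whole records only).
    """
    fs = record.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValidationError(f"EDF writer supports integer sampling rates, got {fs}")
    fs_i = int(round(fs))
    x = record.samples
    n_rec = int(np.ceil(x.size / fs_i))
    padded = np.concatenate([x, np.full(n_rec * fs_i - x.size, x[-1])])

    pmin, pmax = float(padded.min()), float(padded.max())
    if pmax - pmin < 1e-9:
        pmax = pmin + 1.0
    dmin, dmax = -32768, 32767
    gain = (dmax - dmin) / (pmax - pmin)
    digital = np.clip(np.rint((padded - pmin) * gain) + dmin, dmin, dmax).astype("<i2")

    def pad(text: str, width: int) -> bytes:
        b = text.encode("ascii")
        if len(b) > width:
            b = b[:width]
        return b.ljust(width)

    label = record.channel_label or "EEG"
    header = b"".join(
        [
            pad("0", 8),
            pad("X X X X", 80),  # patient id
            pad("Startdate X X X X", 80),  # recording id
            pad("01.01.00", 8),
            pad("00.00.00", 8),
            pad(str(256 * 2), 8),  # header bytes: main + 1 signal
            pad("", 44),
            pad(str(n_rec), 8),
            pad("1", 8),  # record duration, seconds
            pad("1", 4),  # number of signals
            # per-signal fields
            pad(label, 16),
            pad("", 80),  # transducer
            pad("uV", 8),
            pad(f"{pmin:.6g}", 8),
            pad(f"{pmax:.6g}", 8),
            pad(str(dmin), 8),
            pad(str(dmax), 8),
            pad("", 80),  # prefiltering
            pad(str(fs_i), 8),  # samples per record
            pad("", 32),
        ]
    )
    assert len(header) == 512
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(digital.tobytes())


def edf_quantization_step(record: EEGRecord) -> float:
    """Amplitude resolution :func:`write_edf` will use for this record."""
    lo, hi = float(record.samples.min()), float(record.samples.max())
    if hi - lo < 1e-9:
        hi = lo + 1.0
    return (hi - lo) / 65535.0
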