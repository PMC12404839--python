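"""Recordings, fixed-length segmentation, and segment I/O.

A recording is a channels-by-samples matrix with a sampling rate; a segment is
one channel's window of ``N`` consecutive samples, optionally carrying a class
label (+1 epileptic / -1 normal).  ``N`` is constant across a dataset — the
zerotree codec's header assumes it.
"""

from __future__ import annotations

import csv
import io as _io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MultichannelRecording",
    "Segment",
    "read_recording",
    "segment_signal",
    "write_segments",
    "read_segments",
]


@dataclass
class MultichannelRecording:
    """A multichannel EEG recording.

    Parameters
    ----------
    samples
        Array of shape ``(n_channels, n_samples)``; all channels equal length.
    sampling_rate_hz
        Sampling frequency in Hz, strictly positive.
    channel_labels
        One label per channel; generated as ``ch1..chk`` when absent.
    """

    samples: np.ndarray
    sampling_rate_hz: float
    channel_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if self.samples.size == 0:
            raise ValueError("recording has no samples")
        if not self.channel_labels:
            self.channel_labels = [f"ch{i + 1}" for i in range(self.n_channels)]
        if len(self.channel_labels) != self.n_channels:
            raise ValueError("one label per channel required")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz


@dataclass
class Segment:
    """One channel's window of ``N`` samples.

    ``channel_index`` and ``segment_index`` are 1-based in user-facing output.
    ``label`` is +1 (epileptic), -1 (normal) or ``None`` (unlabelled).
    """

    values: np.ndarray
    channel_index: int = 1
    segment_index: int = 1
    label: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size == 0:
            raise ValueError("segment must be non-empty")
        if self.channel_index < 1 or self.segment_index < 1:
            raise ValueError("indices are 1-based")
        if self.label is not None and self.label not in (-1, 1):
            raise ValueError("label must be -1, +1 or None")

    @property
    def n(self) -> int:
        return self.values.size


def read_recording(
    path: str | Path,
    format: str | None = None,
    sampling_rate_hz: float | None = None,
) -> MultichannelRecording:
    """Read an EEG recording from an EDF file or a delimited text file.

    Delimited text is one row per time point, one column per channel, with an
    optional header row; the separator (comma/tab/semicolon/whitespace) is
    auto-detected.  ``sampling_rate_hz`` is required for text input and ignored
    for EDF (the EDF header carries it).  Channel order is preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "delimited-text"
    if format == "edf":
        return _read_edf(path)
    if format == "delimited-text":
        if sampling_rate_hz is None:
            raise ValueError("sampling_rate_hz is required for delimited text")
        return _read_delimited(path, sampling_rate_hz)
    raise ValueError(f"unknown format {format!r}")


def _read_edf(path: Path) -> MultichannelRecording:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data()
    return MultichannelRecording(
        samples=data,
        sampling_rate_hz=float(raw.info["sfreq"]),
        channel_labels=list(raw.ch_names),
    )


def _read_delimited(path: Path, sampling_rate_hz: float) -> MultichannelRecording:
    text = path.read_text()
    if not text.strip():
        raise ValueError(f"empty file: {path}")
    first = text.lstrip().splitlines()[0]
    sep = None
    for cand in (",", "\t", ";"):
        if cand in first:
            sep = cand
            break
    df = pd.read_csv(
        _io.StringIO(text),
        sep=sep if sep is not None else r"\s+",
        header=0 if _looks_like_header(first, sep) else None,
    )
    arr = df.to_numpy(dtype=float)
    labels = [str(c) for c in df.columns] if _looks_like_header(first, sep) else []
    return MultichannelRecording(
        samples=arr.T, sampling_rate_hz=sampling_rate_hz, channel_labels=labels
    )


def _looks_like_header(first_line: str, sep: str | None) -> bool:
    tokens = first_line.split(sep) if sep else first_line.split()
    for tok in tokens:
        try:
            float(tok)
        except ValueError:
            return True
    return False


def segment_signal(rec: MultichannelRecording, window_s: float = 50.0) -> list[Segment]:
    """Cut each channel into consecutive non-overlapping windows.

    ``N = floor(window_s * sampling_rate_hz)`` samples per segment; a trailing
    partial window is discarded (the codec header requires a fixed ``N``).
    Segments are ordered channel-major with 1-based indices.
    """
    n = int(math.floor(window_s * rec.sampling_rate_hz))
    if n < 2:
        raise ValueError("window must span at least 2 samples")
    if n > rec.n_samples:
        raise ValueError(
            f"window of {n} samples longer than recording of {rec.n_samples}"
        )
    n_seg = rec.n_samples // n
    out: list[Segment] = []
    for ch in range(rec.n_channels):
        for s in range(n_seg):
            out.append(
                Segment(
                    values=rec.samples[ch, s * n : (s + 1) * n].copy(),
                    channel_index=ch + 1,
                    segment_index=s + 1,
                )
            )
    return out


# Segment tables are delimited text: three metadata columns then the N sample
# values per row.  Floats are written with repr (shortest round-trip form) so
# write/read is bit-exact.

def write_segments(path: str | Path, segments: Sequence[Segment]) -> None:
    """Write segments to a CSV file (lossless round-trip with read_segments)."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        n = segments[0].n if segments else 0
        w.writerow(["channel_index", "segment_index", "label"] + [f"v{i + 1}" for i in range(n)])
        for seg in segments:
            if seg.n != n:
                raise ValueError("all segments must share the same length N")
            lab = "" if seg.label is None else str(seg.label)
            w.writerow([seg.channel_index, seg.segment_index, lab] + [repr(float(v)) for v in seg.values])


def read_segments(path: str | Path) -> list[Segment]:
    """Read segments written by :func:`write_segments`."""
    path = Path(path)
    out: list[Segment] = []
    with path.open(newline="") as fh:
        r = csv.reader(fh)
        try:
            header = next(r)
        except StopIteration:
            raise ValueError(f"malformed segment file (no header): {path}")
        if header[:3] != ["channel_index", "segment_index", "label"]:
            raise ValueError(f"malformed segment file header: {path}")
        for row in r:
            if not row:
                continue
            label: int | None = None
            if row[2] != "":
                label = int(row[2])
                if label not in (-1, 1):
                    raise ValueError(f"label outside {{-1,+1}}: {label}")
            out.append(
                Segment(
                    values=np.array([float(v) for v in row[3:]], dtype=float),
                    channel_index=int(row[0]),
                    segment_index=int(row[1]),
                    label=label,
                )
            )
    return out
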