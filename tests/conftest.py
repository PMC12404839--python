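"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pytest

from ezweeg.wavelet import WaveletCoeffs, band_sizes


def make_pyramid(
    n: int, levels: int, rng: np.random.Generator, lo: int = -200, hi: int = 200
) -> WaveletCoeffs:
    """Random integer-valued coefficient pyramid with consistent band sizes."""
    sizes = band_sizes(n, levels)
    vals = rng.integers(lo, hi + 1, size=sum(sizes)).astype(float)
    off = np.cumsum([0] + sizes)
    return WaveletCoeffs(
        approx=vals[off[0] : off[1]],
        details=[vals[off[j] : off[j + 1]] for j in range(1, levels + 1)],
        original_length=n,
    )


def oracle_dominant_pass(bands, sig, t):
    """Brute-force dominant pass: explicit descendant enumeration per node.

    Independent of the production codec: zerotree roots are found by walking
    every descendant and testing it against the threshold directly
    (already-significant descendants count as zero).  Returns symbol codes in
    scan order (0 POS, 1 NEG, 2 ZTR, 3 IZ).
    """
    sizes = [len(b) for b in bands]

    def descendants(b, k):
        out, stack = [], [(b, k)]
        while stack:
            bb, kk = stack.pop()
            if bb == 0:
                ch = [(1, kk)] if kk < sizes[1] else []
            elif bb + 1 < len(sizes):
                ch = [(bb + 1, c) for c in (2 * kk, 2 * kk + 1) if c < sizes[bb + 1]]
            else:
                ch = []
            out += ch
            stack += ch
        return out

    skip: set = set()
    syms = []
    for b in range(len(sizes)):
        for k in range(sizes[b]):
            if sig[b][k] or (b, k) in skip:
                continue
            c = bands[b][k]
            if abs(c) >= t:
                syms.append(0 if c > 0 else 1)
            elif all(
                sig[bb][kk] or abs(bands[bb][kk]) < t for bb, kk in descendants(b, k)
            ):
                syms.append(2)
                skip.update(descendants(b, k))
            else:
                syms.append(3)
    return syms


def write_minimal_edf(path: Path, data: np.ndarray, sfreq: int) -> None:
    """Write a minimal EDF file (16-bit records) for reader tests.

    ``data`` is an integer array of shape (n_channels, n_samples) with values
    in [-2048, 2047]; ``n_samples`` must be a multiple of ``sfreq`` (1-second
    data records).  Synthetic fixture — generated at test time, never stored.
    """
    data = np.asarray(data, dtype=np.int16)
    n_ch, n_samp = data.shape
    assert n_samp % sfreq == 0
    n_rec = n_samp // sfreq

    def pad(s: str, width: int) -> bytes:
        return s.encode("ascii").ljust(width)

    hdr = b"".join(
        [
            pad("0", 8),
            pad("X X X X", 80),
            pad("Startdate 01-JAN-2024 X X X", 80),
            pad("01.01.24", 8),
            pad("00.00.00", 8),
            pad(str(256 * (n_ch + 1)), 8),
            pad("", 44),
            pad(str(n_rec), 8),
            pad("1", 8),
            pad(str(n_ch), 4),
        ]
    )
    labels = [f"EEG ch{i + 1}" for i in range(n_ch)]
    hdr += b"".join(pad(lb, 16) for lb in labels)
    hdr += b"".join(pad("", 80) for _ in range(n_ch))  # transducer
    hdr += b"".join(pad("uV", 8) for _ in range(n_ch))
    hdr += b"".join(pad("-2048", 8) for _ in range(n_ch))  # phys min
    hdr += b"".join(pad("2047", 8) for _ in range(n_ch))  # phys max
    hdr += b"".join(pad("-2048", 8) for _ in range(n_ch))  # dig min
    hdr += b"".join(pad("2047", 8) for _ in range(n_ch))  # dig max
    hdr += b"".join(pad("", 80) for _ in range(n_ch))  # prefilter
    hdr += b"".join(pad(str(sfreq), 8) for _ in range(n_ch))
    hdr += b"".join(pad("", 32) for _ in range(n_ch))
    body = b""
    for r in range(n_rec):
        for ch in range(n_ch):
            body += data[ch, r * sfreq : (r + 1) * sfreq].astype("<i2").tobytes()
    path.write_bytes(hdr + body)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
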