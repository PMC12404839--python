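"""Embedded zerotree wavelet (EZW) codec for 1-D coefficient pyramids.

Shapiro-style progressive coding adapted to one dimension.  The coefficient
tree links each approximation coefficient ``approx[i]`` to the coarsest detail
coefficient ``d_L[i]``, and detail coefficient ``k`` at level ``j`` to
coefficients ``2k`` and ``2k+1`` at the next finer level; the finest level has
no children.

Coding alternates two pass types at thresholds ``T0, T0/2, ..., 1``:

* **dominant pass** — scans not-yet-significant coefficients in subband order
  (coarse to fine) and emits one of four symbols: ``POS``/``NEG`` when
  ``|c| >= T``; ``ZTR`` (zerotree root) when the coefficient and every
  not-yet-significant descendant are below ``T`` (descendants are then skipped
  for the rest of the pass); ``IZ`` (isolated zero) otherwise.  Coefficients
  with no descendants and ``|c| < T`` are zerotree roots vacuously.
* **refinement pass** — emits one bit per coefficient found significant in an
  *earlier* pass, in order of becoming significant, halving that coefficient's
  amplitude-uncertainty interval (bit 1 = upper half, using ``>=`` at the
  midpoint).

A coefficient found significant at threshold ``T`` starts with the interval
``[T, 2T)`` and reconstruction value ``sign * 1.5T``.  On integer-valued
(quantized) coefficients a stream run to completion (``T`` down to 1) is
lossless: every interval narrows to unit width, whose single integer the
decoder returns exactly.  Any prefix of the stream decodes to the best
estimate available at that point (the embedded property).

Rate accounting: symbols cost 2 bits, refinement bits 1 bit, the optional
cluster preamble 8 bits; the logical header (initial-threshold exponent plus
decomposition depth) is 8 bits and is amortized separately — the bit rate of
a stream with ``b`` payload bits over ``N`` samples is ``(b + 8) / N``.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field

import numpy as np

from ezweeg.wavelet import WaveletCoeffs, band_sizes

__all__ = [
    "POS",
    "NEG",
    "ZTR",
    "IZ",
    "SYMBOL_NAMES",
    "CoderState",
    "EZWBitstream",
    "Pass",
    "initial_threshold",
    "dominant_pass",
    "refinement_pass",
    "encode",
    "decode",
    "bits_per_sample",
    "RAW_PREAMBLE",
]

POS, NEG, ZTR, IZ = 0, 1, 2, 3
SYMBOL_NAMES = ("POS", "NEG", "ZTR", "IZ")

HEADER_BITS = 8
PREAMBLE_BITS = 8
SYMBOL_BITS = 2

#: preamble value marking a raw (unclustered) segment
RAW_PREAMBLE = 0


# ---------------------------------------------------------------------------
# tree geometry


def _child_slices(sizes: list[int]) -> None:
    pass


def _band_arrays(coeffs: WaveletCoeffs) -> list[np.ndarray]:
    bands = coeffs.bands()
    flat = np.concatenate(bands)
    rounded = np.round(flat)
    if not np.allclose(flat, rounded, atol=1e-9):
        raise ValueError("EZW coding requires integer-valued (quantized) coefficients")
    out = []
    for b in bands:
        out.append(np.round(b).astype(np.int64))
    return out


def _offsets(sizes: list[int]) -> np.ndarray:
    return np.concatenate([[0], np.cumsum(sizes)])


def descendants(band: int, idx: int, sizes: list[int]) -> list[tuple[int, int]]:
    """All (band, index) descendants of a node — explicit enumeration.

    ``band`` 0 is the approximation band; the last band is the finest detail
    level.  Used by the tree-pruned passes' tests as well as the decoder's
    documentation of the parent/child rule.
    """
    out: list[tuple[int, int]] = []
    stack = [(band, idx)]
    while stack:
        b, k = stack.pop()
        if b == 0:
            children = [(1, k)] if k < sizes[1] else []
        elif b + 1 < len(sizes):
            children = [(b + 1, c) for c in (2 * k, 2 * k + 1) if c < sizes[b + 1]]
        else:
            children = []
        for c in children:
            out.append(c)
            stack.append(c)
    return out


# ---------------------------------------------------------------------------
# coder state


@dataclass
class CoderState:
    """Shared encoder/decoder significance state.

    Flat arrays are indexed by global coefficient position (bands concatenated
    coarse to fine).  ``order`` lists positions in the order they became
    significant; ``found_pass[pos]`` is the pass index at which that happened.
    ``lo``/``hi`` bound the coefficient magnitude's current uncertainty
    interval ``[lo, hi)``.
    """

    total: int
    significant: np.ndarray = field(init=False)
    sign: np.ndarray = field(init=False)
    lo: np.ndarray = field(init=False)
    hi: np.ndarray = field(init=False)
    found_pass: np.ndarray = field(init=False)
    order: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.significant = np.zeros(self.total, dtype=bool)
        self.sign = np.zeros(self.total, dtype=np.int8)
        self.lo = np.zeros(self.total, dtype=float)
        self.hi = np.zeros(self.total, dtype=float)
        self.found_pass = np.full(self.total, -1, dtype=np.int64)

    def mark(self, pos: int, sign: int, t: float, pass_index: int) -> None:
        self.significant[pos] = True
        self.sign[pos] = sign
        self.lo[pos] = t
        self.hi[pos] = 2 * t
        self.found_pass[pos] = pass_index
        self.order.append(pos)

    def reconstruction(self, integer: bool = True) -> np.ndarray:
        """Magnitude estimates: interval midpoint, or the exact integer once
        the interval has narrowed to unit width."""
        mid = (self.lo + self.hi) / 2.0
        if integer:
            exact = self.hi - self.lo <= 1.0 + 1e-12
            mid = np.where(exact, self.lo, mid)
        values = np.where(self.significant, self.sign * mid, 0.0)
        return values


def initial_threshold(coeffs: WaveletCoeffs) -> int:
    """Largest power of two not exceeding ``max |c|`` (0 for an all-zero pyramid)."""
    m = int(np.max(np.abs(np.round(coeffs.to_array()))))
    if m == 0:
        return 0
    return 1 << (m.bit_length() - 1)


# ---------------------------------------------------------------------------
# dominant pass (vectorized per band)


def _descendant_max(eff: list[np.ndarray]) -> list[np.ndarray]:
    """Per node, max effective magnitude over all descendants (bottom-up)."""
    n_bands = len(eff)
    dm: list[np.ndarray] = [np.full(b.size, -1, dtype=np.int64) for b in eff]
    for j in range(n_bands - 2, 0, -1):
        child = np.maximum(eff[j + 1], dm[j + 1])
        pad = 2 * eff[j].size - child.size
        if pad:
            child = np.concatenate([child, np.full(pad, -1, dtype=np.int64)])
        dm[j] = child.reshape(-1, 2).max(axis=1)
    if n_bands > 1:
        dm[0] = np.maximum(eff[1], dm[1])
        if eff[1].size < eff[0].size:  # cannot happen with periodization; guard anyway
            dm[0] = np.pad(dm[0], (0, eff[0].size - eff[1].size), constant_values=-1)
    return dm


def _dominant_symbols(
    bands: list[np.ndarray], sig_bands: list[np.ndarray], t: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Candidate positions and their symbols for one dominant pass.

    Returns, per band, ``(indices, symbols)`` of the coefficients scanned this
    pass (not yet significant, not inside a zerotree), in scan order.
    Already-significant coefficients count as zero when forming zerotrees.
    """
    absb = [np.abs(b) for b in bands]
    eff = [np.where(s, 0, a) for a, s in zip(absb, sig_bands)]
    dm = _descendant_max(eff)
    out: list[tuple[np.ndarray, np.ndarray]] = []
    skip = np.zeros(bands[0].size, dtype=bool)
    for j, band in enumerate(bands):
        cand = ~sig_bands[j] & ~skip
        sym = np.empty(band.size, dtype=np.int8)
        signif = absb[j] >= t
        sym[signif & (band > 0)] = POS
        sym[signif & (band < 0)] = NEG
        ztr = ~signif & (dm[j] < t)
        sym[ztr] = ZTR
        sym[~signif & ~ztr] = IZ
        idx = np.nonzero(cand)[0]
        out.append((idx, sym[idx]))
        if j + 1 < len(bands):
            blocked = skip | (cand & (sym == ZTR))
            if j == 0:
                skip = blocked[: bands[1].size].copy()
            else:
                skip = np.repeat(blocked, 2)[: bands[j + 1].size]
    return out


def dominant_pass(
    coeffs: WaveletCoeffs, t: int, state: CoderState, pass_index: int = 0
) -> tuple[list[str], list[int]]:
    """Run one dominant pass at threshold ``t``, updating ``state``.

    Returns the emitted symbol names in scan order and the global positions of
    the coefficients that became significant.
    """
    if t < 1:
        raise ValueError("threshold must be >= 1")
    bands = _band_arrays(coeffs)
    sizes = [b.size for b in bands]
    offs = _offsets(sizes)
    sig_bands = [state.significant[offs[j] : offs[j + 1]].copy() for j in range(len(bands))]
    per_band = _dominant_symbols(bands, sig_bands, t)
    symbols: list[str] = []
    newly: list[int] = []
    for j, (idx, sym) in enumerate(per_band):
        for k, s in zip(idx, sym):
            symbols.append(SYMBOL_NAMES[s])
            if s in (POS, NEG):
                pos = int(offs[j] + k)
                state.mark(pos, +1 if s == POS else -1, t, pass_index)
                newly.append(pos)
    return symbols, newly


def refinement_pass(
    coeffs: WaveletCoeffs, state: CoderState, pass_index: int
) -> list[int]:
    """Emit one refinement bit per coefficient found significant in an earlier
    pass (``found_pass < pass_index``), in order of becoming significant."""
    flat_abs = np.abs(_flat_int(coeffs))
    bits: list[int] = []
    for pos in state.order:
        if state.found_pass[pos] >= pass_index:
            continue
        mid = (state.lo[pos] + state.hi[pos]) / 2.0
        bit = 1 if flat_abs[pos] >= mid else 0
        bits.append(bit)
        if bit:
            state.lo[pos] = mid
        else:
            state.hi[pos] = mid
    return bits


def _flat_int(coeffs: WaveletCoeffs) -> np.ndarray:
    return np.concatenate(_band_arrays(coeffs))


# ---------------------------------------------------------------------------
# bitstream


@dataclass
class Pass:
    """One coding round: the dominant symbols, then the refinement bits."""

    dominant_symbols: np.ndarray  # int8 codes over {POS, NEG, ZTR, IZ}
    refinement_bits: np.ndarray  # uint8 over {0, 1}

    @property
    def bits(self) -> int:
        return SYMBOL_BITS * len(self.dominant_symbols) + len(self.refinement_bits)


@dataclass
class EZWBitstream:
    """An embedded bitstream: header + ordered dominant/refinement passes.

    ``t0`` is the initial threshold (a power of two; 0 marks an all-zero
    pyramid, coded as a header-only stream).  ``total_bits`` is the payload
    bit count ``b`` (symbols, refinement bits and the optional 8-bit cluster
    preamble); the logical 8-bit header is amortized in
    :func:`bits_per_sample` as ``(b + 8) / N``.
    """

    t0: int
    n_samples: int
    levels: int
    wavelet_name: str
    passes: list[Pass] = field(default_factory=list)
    cluster_preamble: int | None = None
    quant_step: float | None = None

    @property
    def total_bits(self) -> int:
        b = sum(p.bits for p in self.passes)
        if self.cluster_preamble is not None:
            b += PREAMBLE_BITS
        return b

    def truncated(self, n_passes: int) -> "EZWBitstream":
        """Prefix of the stream containing only the first ``n_passes`` rounds."""
        return EZWBitstream(
            t0=self.t0,
            n_samples=self.n_samples,
            levels=self.levels,
            wavelet_name=self.wavelet_name,
            passes=self.passes[:n_passes],
            cluster_preamble=self.cluster_preamble,
            quant_step=self.quant_step,
        )

    # -- serialized container (.ezw1d) ------------------------------------
    # magic 'EZW1' | u8 version | u8 flags (bit0: preamble, bit1: quant_step)
    # u8 t0_exponent (255 = empty stream) | u8 levels | u32 N |
    # u8 name_len + wavelet name ascii | [u16 preamble] | [f64 quant_step] |
    # u16 n_passes | per pass: u32 n_symbols, packed 2-bit symbols,
    #               u32 n_refbits, packed bits.

    MAGIC = b"EZW1"

    def to_bytes(self) -> bytes:
        out = bytearray(self.MAGIC)
        flags = (self.cluster_preamble is not None) | ((self.quant_step is not None) << 1)
        texp = 255 if self.t0 == 0 else int(self.t0).bit_length() - 1
        out += struct.pack("<BBBBI", 1, flags, texp, self.levels, self.n_samples)
        name = self.wavelet_name.encode("ascii")
        out += struct.pack("<B", len(name)) + name
        if self.cluster_preamble is not None:
            out += struct.pack("<H", self.cluster_preamble)
        if self.quant_step is not None:
            out += struct.pack("<d", self.quant_step)
        out += struct.pack("<H", len(self.passes))
        for p in self.passes:
            sym = np.asarray(p.dominant_symbols, dtype=np.uint8)
            out += struct.pack("<I", sym.size)
            out += np.packbits(
                ((sym[:, None] >> np.array([1, 0])) & 1).astype(np.uint8).ravel()
            ).tobytes()
            bits = np.asarray(p.refinement_bits, dtype=np.uint8)
            out += struct.pack("<I", bits.size)
            out += np.packbits(bits).tobytes()
        return bytes(out)

    @classmethod
    def from_bytes(cls, data: bytes) -> "EZWBitstream":
        if data[:4] != cls.MAGIC:
            raise ValueError("not an ezw1d stream (bad magic)")
        off = 4
        version, flags, texp, levels, n = struct.unpack_from("<BBBBI", data, off)
        off += struct.calcsize("<BBBBI")
        if version != 1:
            raise ValueError(f"unsupported stream version {version}")
        (name_len,) = struct.unpack_from("<B", data, off)
        off += 1
        wavelet_name = data[off : off + name_len].decode("ascii")
        off += name_len
        preamble = None
        if flags & 1:
            (preamble,) = struct.unpack_from("<H", data, off)
            off += 2
        quant_step = None
        if flags & 2:
            (quant_step,) = struct.unpack_from("<d", data, off)
            off += 8
        (n_passes,) = struct.unpack_from("<H", data, off)
        off += 2
        passes = []
        for _ in range(n_passes):
            (n_sym,) = struct.unpack_from("<I", data, off)
            off += 4
            nbytes = (2 * n_sym + 7) // 8
            raw = np.frombuffer(data[off : off + nbytes], dtype=np.uint8)
            bits2 = np.unpackbits(raw)[: 2 * n_sym].reshape(-1, 2)
            sym = (bits2[:, 0] * 2 + bits2[:, 1]).astype(np.int8)
            off += nbytes
            (n_ref,) = struct.unpack_from("<I", data, off)
            off += 4
            nbytes = (n_ref + 7) // 8
            ref = np.unpackbits(np.frombuffer(data[off : off + nbytes], dtype=np.uint8))[:n_ref]
            off += nbytes
            passes.append(Pass(dominant_symbols=sym, refinement_bits=ref.astype(np.uint8)))
        return cls(
            t0=0 if texp == 255 else (1 << texp),
            n_samples=n,
            levels=levels,
            wavelet_name=wavelet_name,
            passes=passes,
            cluster_preamble=preamble,
            quant_step=quant_step,
        )


def bits_per_sample(stream: EZWBitstream) -> float:
    """Bit rate ``(b + 8) / N``: payload bits plus the 8-bit header, per sample."""
    if stream.n_samples <= 0:
        raise ValueError("N must be positive")
    return (stream.total_bits + HEADER_BITS) / stream.n_samples


# ---------------------------------------------------------------------------
# encoder / decoder


def encode(
    coeffs: WaveletCoeffs,
    max_bits: int | None = None,
    cluster_preamble: int | None = None,
) -> EZWBitstream:
    """Encode an integer-valued pyramid into an embedded bitstream.

    ``max_bits`` bounds the total bits (8-bit header + preamble + payload);
    the encoder emits symbols and refinement bits greedily and stops before
    the budget would be exceeded.  ``None`` means lossless mode: all passes
    down to threshold 1 are emitted and the decoder reproduces the
    coefficients exactly.
    """
    bands = _band_arrays(coeffs)
    total = sum(b.size for b in bands)
    offs = _offsets([b.size for b in bands])
    flat = np.concatenate(bands)
    flat_abs = np.abs(flat)

    overhead = HEADER_BITS + (PREAMBLE_BITS if cluster_preamble is not None else 0)
    if max_bits is not None and max_bits < overhead:
        raise ValueError(f"bit budget {max_bits} smaller than {overhead}-bit header")

    t0 = initial_threshold(coeffs)
    stream = EZWBitstream(
        t0=t0,
        n_samples=coeffs.original_length,
        levels=coeffs.levels,
        wavelet_name=coeffs.wavelet_name,
        cluster_preamble=cluster_preamble,
        quant_step=coeffs.quant_step,
    )
    if t0 == 0:
        return stream

    state = CoderState(total)
    used = overhead
    budget = np.inf if max_bits is None else max_bits
    t = t0
    pass_index = 0
    while t >= 1 and used < budget:
        # dominant ------------------------------------------------------
        sig_bands = [state.significant[offs[j] : offs[j + 1]] for j in range(len(bands))]
        per_band = _dominant_symbols(bands, [s.copy() for s in sig_bands], t)
        sym_list: list[np.ndarray] = []
        stop = False
        for j, (idx, sym) in enumerate(per_band):
            room = len(idx) if np.isinf(budget) else int((budget - used) // SYMBOL_BITS)
            if len(idx) > room:
                idx, sym = idx[:room], sym[:room]
                stop = True
            used += SYMBOL_BITS * len(idx)
            sym_list.append(sym)
            found = idx[(sym == POS) | (sym == NEG)]
            for k in found:
                pos = int(offs[j] + k)
                state.mark(pos, +1 if flat[pos] > 0 else -1, t, pass_index)
            if stop:
                break
        dominant = (
            np.concatenate(sym_list).astype(np.int8) if sym_list else np.zeros(0, dtype=np.int8)
        )

        # refinement ----------------------------------------------------
        ref_bits: list[int] = []
        if not stop:
            for pos in state.order:
                if state.found_pass[pos] >= pass_index:
                    continue
                if used + 1 > budget:
                    stop = True
                    break
                mid = (state.lo[pos] + state.hi[pos]) / 2.0
                bit = 1 if flat_abs[pos] >= mid else 0
                ref_bits.append(bit)
                used += 1
                if bit:
                    state.lo[pos] = mid
                else:
                    state.hi[pos] = mid

        stream.passes.append(
            Pass(
                dominant_symbols=dominant,
                refinement_bits=np.asarray(ref_bits, dtype=np.uint8),
            )
        )
        if stop:
            break
        t //= 2
        pass_index += 1
    return stream


def decode(stream: EZWBitstream, return_state: bool = False):
    """Reconstruct coefficient estimates by replaying the stream's passes.

    A truncated stream yields the best estimate available at that prefix; a
    complete stream over integer coefficients is reproduced exactly.
    """
    sizes = band_sizes(stream.n_samples, stream.levels)
    offs = _offsets(sizes)
    total = int(offs[-1])
    state = CoderState(total)

    if stream.t0 != 0:
        t = float(stream.t0)
        for pass_index, p in enumerate(stream.passes):
            if t < 1:
                raise ValueError("more passes than thresholds: corrupt stream")
            _replay_dominant(p.dominant_symbols, sizes, offs, state, t, pass_index)
            _replay_refinement(p.refinement_bits, state, pass_index)
            t /= 2

    flat = state.reconstruction(integer=True)
    bands = [flat[offs[j] : offs[j + 1]] for j in range(len(sizes))]
    coeffs = WaveletCoeffs.from_bands(
        bands,
        wavelet_name=stream.wavelet_name,
        original_length=stream.n_samples,
        quant_step=stream.quant_step,
    )
    if return_state:
        return coeffs, state
    return coeffs


def _replay_dominant(
    symbols: np.ndarray,
    sizes: list[int],
    offs: np.ndarray,
    state: CoderState,
    t: float,
    pass_index: int,
) -> None:
    pos_stream = 0
    n_sym = len(symbols)
    skip = np.zeros(sizes[0], dtype=bool)
    for j in range(len(sizes)):
        sig = state.significant[offs[j] : offs[j + 1]]
        cand = np.nonzero(~sig & ~skip)[0]
        take = min(len(cand), n_sym - pos_stream)
        ztr_band = np.zeros(sizes[j], dtype=bool)
        for i in range(take):
            k = int(cand[i])
            s = int(symbols[pos_stream + i])
            if s == POS or s == NEG:
                state.mark(int(offs[j] + k), +1 if s == POS else -1, t, pass_index)
            elif s == ZTR:
                ztr_band[k] = True
        pos_stream += take
        if j + 1 < len(sizes):
            blocked = skip | ztr_band
            if j == 0:
                skip = blocked[: sizes[1]].copy()
            else:
                skip = np.repeat(blocked, 2)[: sizes[j + 1]]
        if pos_stream >= n_sym:
            break


def _replay_refinement(bits: np.ndarray, state: CoderState, pass_index: int) -> None:
    i = 0
    n = len(bits)
    for pos in state.order:
        if state.found_pass[pos] >= pass_index:
            continue
        if i >= n:
            break
        mid = (state.lo[pos] + state.hi[pos]) / 2.0
        if bits[i]:
            state.lo[pos] = mid
        else:
            state.hi[pos] = mid
        i += 1
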