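"""Per-column codecs for sorted BUS blocks.

Five codecs, one per stored column:

* barcode  — delta against the previous record (non-negative because the
  column is sorted), then FRLE0;
* UMI      — delta against the previous record *of the same cell*, the raw
  value at a barcode change, then FRLE0;
* EC       — a NewPFD (patched frame-of-reference) variant: fixed b-bit slots
  relative to the sub-block minimum k, outliers escaped as Fibonacci-coded
  exceptions;
* count    — FRLE1 (counts are strictly positive and mostly 1);
* flags    — FRLE0 (flags are mostly 0).

RLE0 collapses maximal runs of zeros into (marker, length) pairs and leaves
every other value literal; RLE1 does the same for ones.  FRLE0/FRLE1 are the
Fibonacci encodings of those token streams.  Fibonacci codes cannot encode
zero, so FRLE0 pre-increments literal values by one; run lengths are already
>= 1 and run markers become fib(1), so neither needs an increment, and FRLE1
operates on strictly positive values so it needs no increment at all.

The exact bit layout of every codec is specified in docs/FORMAT.md.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil
from typing import Iterator, Sequence

import numpy as np

from .bitstream import BitReader, BitWriter
from .errors import CorruptionError, NotSortedError

__all__ = [
    "NewpfdParams",
    "NewpfdSubblock",
    "rle_encode",
    "rle_decode",
    "frle0_encode",
    "frle0_decode",
    "frle1_encode",
    "frle1_decode",
    "delta_barcodes",
    "undelta_barcodes",
    "delta_umis",
    "undelta_umis",
    "newpfd_encode",
    "newpfd_decode",
    "newpfd_subblocks",
]


@dataclass(frozen=True)
class NewpfdParams:
    """NewPFD tuning: sub-block size and the in-range fraction f.

    For each sub-block B the slot width b is the number of bits of the
    ceil(f*|B|)-th smallest offset (x - min(B)); at least that many values
    are then guaranteed to fit their slots.
    """

    n_pfd: int = 512
    f: float = 0.9

    def __post_init__(self) -> None:
        if self.n_pfd < 1:
            raise ValueError(f"n_pfd must be >= 1, got {self.n_pfd}")
        if not 0 < self.f <= 1:
            raise ValueError(f"f must be in (0, 1], got {self.f}")


@dataclass
class NewpfdSubblock:
    """Decoded structure of one NewPFD sub-block (for auditing/inspection)."""

    k: int
    b: int
    exceptions: list[tuple[int, int]]  # (position, high bits >= 1)
    values: list[int]


# ---------------------------------------------------------------------------
# Run-length encoding (token level)

def rle_encode(values: Sequence[int], target: int) -> list:
    """RLE0/RLE1 token stream: maximal runs of ``target`` become ``(target, L)``
    pairs, all other values pass through literally."""
    if target not in (0, 1):
        raise ValueError(f"target must be 0 or 1, got {target}")
    vals = list(values)
    if target == 1 and any(v < 1 for v in vals):
        raise ValueError("RLE1 requires strictly positive values")
    tokens: list = []
    i, n = 0, len(vals)
    while i < n:
        v = vals[i]
        if v == target:
            j = i
            while j < n and vals[j] == target:
                j += 1
            tokens.append((target, j - i))
            i = j
        else:
            tokens.append(v)
            i += 1
    return tokens


def rle_decode(tokens: Sequence) -> list[int]:
    out: list[int] = []
    for tok in tokens:
        if isinstance(tok, tuple):
            target, length = tok
            out.extend([target] * length)
        else:
            out.append(tok)
    return out


# ---------------------------------------------------------------------------
# Fibonacci run-length codecs

def frle0_encode(values: Sequence[int], bits: BitWriter) -> None:
    """FRLE0: runs of zeros -> fib(1), fib(L); literal v -> fib(v + 1)."""
    vals = values.tolist() if isinstance(values, np.ndarray) else list(values)
    i, n = 0, len(vals)
    wf = bits.write_fibonacci
    while i < n:
        v = vals[i]
        if v == 0:
            j = i
            while j < n and vals[j] == 0:
                j += 1
            wf(1)
            wf(j - i)
            i = j
        else:
            if v < 0:
                raise ValueError(f"FRLE0 requires non-negative values, got {v}")
            wf(v + 1)
            i += 1


def frle0_decode(bits: BitReader, n: int) -> list[int]:
    out: list[int] = []
    rf = bits.read_fibonacci
    while len(out) < n:
        c = rf()
        if c == 1:  # zero-run marker
            out.extend([0] * rf())
        else:
            out.append(c - 1)
    if len(out) > n:
        raise CorruptionError(f"FRLE0 stream decoded {len(out)} values, expected {n}")
    return out


def frle1_encode(values: Sequence[int], bits: BitWriter) -> None:
    """FRLE1: runs of ones -> fib(1), fib(L); literal v (>= 2) -> fib(v)."""
    vals = values.tolist() if isinstance(values, np.ndarray) else list(values)
    i, n = 0, len(vals)
    wf = bits.write_fibonacci
    while i < n:
        v = vals[i]
        if v == 1:
            j = i
            while j < n and vals[j] == 1:
                j += 1
            wf(1)
            wf(j - i)
            i = j
        else:
            if v < 1:
                raise ValueError(f"FRLE1 requires strictly positive values, got {v}")
            wf(v)
            i += 1


def frle1_decode(bits: BitReader, n: int) -> list[int]:
    out: list[int] = []
    rf = bits.read_fibonacci
    while len(out) < n:
        c = rf()
        if c == 1:  # one-run marker
            out.extend([1] * rf())
        else:
            out.append(c)
    if len(out) > n:
        raise CorruptionError(f"FRLE1 stream decoded {len(out)} values, expected {n}")
    return out


# ---------------------------------------------------------------------------
# Delta transforms

def delta_barcodes(barcodes: np.ndarray) -> np.ndarray:
    """Differences of adjacent barcodes; the first entry is kept raw so each
    block decodes independently of its predecessors."""
    bc = np.asarray(barcodes, dtype=np.uint64)
    if len(bc) == 0:
        return bc.copy()
    bad = np.flatnonzero(bc[1:] < bc[:-1])
    if bad.size:
        i = int(bad[0]) + 1
        raise NotSortedError(f"barcode decreases at record {i}", index=i)
    out = np.empty_like(bc)
    out[0] = bc[0]
    np.subtract(bc[1:], bc[:-1], out=out[1:])
    return out


def undelta_barcodes(deltas: np.ndarray) -> np.ndarray:
    return np.cumsum(np.asarray(deltas, dtype=np.uint64), dtype=np.uint64)


def delta_umis(umis: np.ndarray, barcodes: np.ndarray) -> np.ndarray:
    """UMI deltas taken only between adjacent records of the same cell; at a
    barcode change the raw UMI value is used."""
    u = np.asarray(umis, dtype=np.uint64)
    bc = np.asarray(barcodes, dtype=np.uint64)
    if len(u) != len(bc):
        raise ValueError("umis and barcodes must have equal length")
    if len(u) == 0:
        return u.copy()
    same = bc[1:] == bc[:-1]
    bad = np.flatnonzero(same & (u[1:] < u[:-1]))
    if bad.size:
        i = int(bad[0]) + 1
        raise NotSortedError(f"UMI decreases within a barcode at record {i}", index=i)
    out = np.empty_like(u)
    out[0] = u[0]
    out[1:] = np.where(same, u[1:] - u[:-1], u[1:])
    return out


def undelta_umis(deltas: np.ndarray, barcodes: np.ndarray) -> np.ndarray:
    """Inverse of :func:`delta_umis` given the already-decoded barcode column."""
    d = np.asarray(deltas, dtype=np.uint64)
    bc = np.asarray(barcodes, dtype=np.uint64)
    n = len(d)
    if n == 0:
        return d.copy()
    c = np.cumsum(d, dtype=np.uint64)  # exact modulo 2**64; differences are exact
    starts = np.empty(n, dtype=bool)
    starts[0] = True
    starts[1:] = bc[1:] != bc[:-1]
    start_idx = np.flatnonzero(starts)
    base_per_group = np.empty(len(start_idx), dtype=np.uint64)
    base_per_group[0] = 0
    base_per_group[1:] = c[start_idx[1:] - 1]
    lengths = np.diff(np.append(start_idx, n))
    return c - np.repeat(base_per_group, lengths)


# ---------------------------------------------------------------------------
# NewPFD

_B_CAP = 32


def _subblock_b(offsets: list[int], f: float) -> int:
    """Minimal slot width covering the ceil(f*|B|) smallest offsets."""
    rank = ceil(f * len(offsets))
    b = sorted(offsets)[rank - 1].bit_length()
    return min(b, _B_CAP)


def newpfd_encode(values: Sequence[int], params: NewpfdParams, bits: BitWriter) -> None:
    """Encode non-negative integers in NewPFD sub-blocks of ``params.n_pfd``.

    Per sub-block: fib(b+1), fib(k+1), fib(#exceptions+1); per exception a
    position gap (+1) and its high bits (x-k) >> b, all Fibonacci coded; then
    |B| fixed b-bit slots holding the low bits of (x-k).
    """
    vals = values.tolist() if isinstance(values, np.ndarray) else list(values)
    n_pfd = params.n_pfd
    for s in range(0, len(vals), n_pfd):
        block = vals[s : s + n_pfd]
        k = min(block)
        if k < 0:
            raise ValueError(f"NewPFD requires non-negative values, got {k}")
        offsets = [x - k for x in block]
        b = _subblock_b(offsets, params.f)
        mask = (1 << b) - 1
        exceptions = [(pos, off >> b) for pos, off in enumerate(offsets) if off >> b]
        bits.write_fibonacci(b + 1)
        bits.write_fibonacci(k + 1)
        bits.write_fibonacci(len(exceptions) + 1)
        prev = 0
        for pos, high in exceptions:
            bits.write_fibonacci(pos - prev + 1)
            bits.write_fibonacci(high)
            prev = pos
        if b:
            wb = bits.write_bits
            for off in offsets:
                wb(off & mask, b)


def newpfd_subblocks(
    bits: BitReader, n: int, params: NewpfdParams
) -> Iterator[NewpfdSubblock]:
    """Yield the decoded structure of each sub-block of an n-value stream."""
    remaining = n
    while remaining > 0:
        m = min(remaining, params.n_pfd)
        b = bits.read_fibonacci() - 1
        k = bits.read_fibonacci() - 1
        n_exc = bits.read_fibonacci() - 1
        exceptions: list[tuple[int, int]] = []
        prev = 0
        for _ in range(n_exc):
            pos = prev + bits.read_fibonacci() - 1
            if pos >= m:
                raise CorruptionError(
                    f"NewPFD exception position {pos} beyond sub-block of {m} values"
                )
            high = bits.read_fibonacci()
            exceptions.append((pos, high))
            prev = pos
        if b:
            rb = bits.read_bits
            values = [k + rb(b) for _ in range(m)]
        else:
            values = [k] * m
        for pos, high in exceptions:
            values[pos] += high << b
        yield NewpfdSubblock(k=k, b=b, exceptions=exceptions, values=values)
        remaining -= m


def newpfd_decode(bits: BitReader, n: int, params: NewpfdParams) -> list[int]:
    out: list[int] = []
    for sub in newpfd_subblocks(bits, n, params):
        out.extend(sub.values)
    return out
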