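"""Bit-level I/O and the Fibonacci universal code.

All bit streams in this project use a single convention: bits are packed
MSB-first within each byte, for both fixed-width slots and Fibonacci
codewords.  A Fibonacci codeword for a positive integer n is the Zeckendorf
representation of n over the Fibonacci sequence F1=1, F2=2, F3=3, F4=5, ...
emitted lowest index first and terminated by one extra 1 bit, so every
codeword ends in "11" and contains no other adjacent pair of 1 bits.
Fibonacci codes cannot represent zero; callers pre-increment values that may
be zero.
"""

from __future__ import annotations

from bisect import bisect_right
from functools import lru_cache

from .errors import TruncatedStreamError

__all__ = [
    "FIBS",
    "MAX_FIBONACCI_VALUE",
    "fibonacci_codeword",
    "fibonacci_encode",
    "BitWriter",
    "BitReader",
]

# F1=1, F2=2, ...; extended comfortably past 2**64 so that values up to
# 2**64 (u64 values after a +1 pre-increment) have a codeword.
FIBS: list[int] = [1, 2]
while FIBS[-1] <= 1 << 66:
    FIBS.append(FIBS[-1] + FIBS[-2])

MAX_FIBONACCI_VALUE = 1 << 64


@lru_cache(maxsize=1 << 16)
def fibonacci_codeword(n: int) -> tuple[int, int]:
    """Return ``(code, width)`` for n >= 1: the codeword as an MSB-first integer.

    The first emitted bit (coefficient of F1) is the most significant bit of
    ``code``; the terminator 1 is the least significant.
    """
    if n < 1:
        raise ValueError(f"Fibonacci codes exist only for n >= 1, got {n}")
    if n > MAX_FIBONACCI_VALUE:
        raise ValueError(f"value {n} exceeds the supported range (<= 2**64)")
    m = bisect_right(FIBS, n) - 1  # largest index with FIBS[m] <= n
    width = m + 2  # coefficients for F1..F(m+1) plus the terminator bit
    code = 1  # terminator
    rem = n
    i = m
    while rem:
        if FIBS[i] <= rem:
            rem -= FIBS[i]
            code |= 1 << (width - 1 - i)
        i -= 1
    return code, width


def fibonacci_encode(n: int) -> str:
    """The Fibonacci codeword of ``n`` as a bit string, e.g. 4 -> ``"1011"``."""
    code, width = fibonacci_codeword(n)
    return format(code, f"0{width}b")


class BitWriter:
    """Append-only MSB-first bit buffer."""

    __slots__ = ("_bytes", "_cur", "_ncur")

    def __init__(self) -> None:
        self._bytes = bytearray()
        self._cur = 0  # pending bits, right-aligned
        self._ncur = 0  # number of pending bits (< 8)

    @property
    def bit_length(self) -> int:
        return 8 * len(self._bytes) + self._ncur

    def _append(self, value: int, width: int) -> None:
        cur = (self._cur << width) | value
        n = self._ncur + width
        out = self._bytes
        while n >= 8:
            n -= 8
            out.append((cur >> n) & 0xFF)
        self._cur = cur & ((1 << n) - 1)
        self._ncur = n

    def write_bits(self, value: int, width: int) -> None:
        """Append exactly ``width`` bits of ``value``, most significant first."""
        if not 0 <= width <= 64:
            raise ValueError(f"width must be in 0..64, got {width}")
        if value < 0 or value >> width:
            raise ValueError(f"value {value} does not fit in {width} bits")
        if width:
            self._append(value, width)

    def write_fibonacci(self, n: int) -> None:
        code, width = fibonacci_codeword(n)
        self._append(code, width)

    def align_to_byte(self) -> None:
        """Pad with zero bits to the next byte boundary (no-op if aligned)."""
        if self._ncur:
            self._append(0, 8 - self._ncur)

    def getvalue(self) -> bytes:
        """The buffer contents; a trailing partial byte is zero-padded."""
        if self._ncur:
            return bytes(self._bytes) + bytes([self._cur << (8 - self._ncur)])
        return bytes(self._bytes)


class BitReader:
    """MSB-first cursor over a byte string, symmetric with :class:`BitWriter`."""

    __slots__ = ("_data", "_pos", "_end")

    def __init__(self, data: bytes, bit_length: int | None = None) -> None:
        self._data = data
        self._pos = 0
        self._end = 8 * len(data) if bit_length is None else bit_length

    @property
    def position(self) -> int:
        return self._pos

    @property
    def bits_remaining(self) -> int:
        return self._end - self._pos

    def read_bits(self, width: int) -> int:
        if not 0 <= width <= 64:
            raise ValueError(f"width must be in 0..64, got {width}")
        if width == 0:
            return 0
        pos = self._pos
        end = pos + width
        if end > self._end:
            raise TruncatedStreamError(
                f"requested {width} bits with only {self._end - pos} remaining"
            )
        first = pos >> 3
        last = (end - 1) >> 3
        chunk = int.from_bytes(self._data[first : last + 1], "big")
        shift = ((last + 1) << 3) - end
        self._pos = end
        return (chunk >> shift) & ((1 << width) - 1)

    def read_fibonacci(self) -> int:
        """Consume one Fibonacci codeword (through its terminating "11")."""
        data = self._data
        pos = self._pos
        end = self._end
        value = 0
        prev = False
        i = 0
        while pos < end:
            bit = (data[pos >> 3] >> (7 - (pos & 7))) & 1
            pos += 1
            if bit:
                if prev:
                    self._pos = pos
                    return value
                value += FIBS[i]
                prev = True
            else:
                prev = False
            i += 1
        raise TruncatedStreamError("bit stream ended inside a Fibonacci codeword")

    def align_to_byte(self) -> None:
        self._pos = (self._pos + 7) & ~7
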